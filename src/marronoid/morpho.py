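"""Morphometric indices: spination index and relative leg length.

Measurements come in a long-format CSV (specimen, species, structure,
measurement_mm). Structures follow a naming convention:

* ``front_segment_*`` — front-leg segments measured between condyles
  (coxa, trochanter and pretarsus excluded);
* ``spine_*``         — front-leg spines (macrosetae) seen in prolateral
  view, base socket to tip; all spines counted, including permanently
  erect dorsal/lateral ones;
* ``hind_segment_*``  — posterior-leg segments;
* ``carapace_width``, ``body_length``.

The spination index is sum(spine lengths) / sum(front-leg segment lengths)
— a dimensionless proxy for the "capture basket". Relative leg length is
sum(hind segments) / carapace width. Both are invariant to the length unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MorphoRecord",
    "spination_index",
    "relative_leg_length",
    "records_from_long",
    "species_trait_table",
]


@dataclass
class MorphoRecord:
    specimen: str
    species: str
    front_segments_mm: list[float]
    spine_lengths_mm: list[float] = field(default_factory=list)
    hind_segments_mm: list[float] = field(default_factory=list)
    carapace_width_mm: float | None = None
    body_length_mm: float | None = None

    def __post_init__(self) -> None:
        for group in (self.front_segments_mm, self.spine_lengths_mm,
                      self.hind_segments_mm):
            if any(x <= 0 for x in group):
                raise ValueError("all measured lengths must be positive")


def spination_index(rec: MorphoRecord) -> float:
    """Sum of spine lengths over sum of front-leg segment lengths;
    0 for a spineless leg."""
    if not rec.front_segments_mm:
        raise ValueError(f"{rec.specimen}: no front-leg segments measured")
    return float(sum(rec.spine_lengths_mm) / sum(rec.front_segments_mm))


def relative_leg_length(rec: MorphoRecord) -> float:
    """Sum of hind-leg segment lengths over carapace width."""
    if not rec.hind_segments_mm:
        raise ValueError(f"{rec.specimen}: no hind-leg segments measured")
    if not rec.carapace_width_mm or rec.carapace_width_mm <= 0:
        raise ValueError(f"{rec.specimen}: missing or non-positive carapace width")
    return float(sum(rec.hind_segments_mm) / rec.carapace_width_mm)


def records_from_long(df: pd.DataFrame) -> list[MorphoRecord]:
    """Build records from the long measurement table."""
    need = {"specimen", "species", "structure", "measurement_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"measurement table needs columns {sorted(need)}")
    out = []
    for (spec, species), grp in df.groupby(["specimen", "species"], sort=False):
        by = grp.set_index("structure")["measurement_mm"]
        pick = lambda pre: [float(v) for s, v in by.items() if s.startswith(pre)]
        out.append(MorphoRecord(
            specimen=str(spec), species=str(species),
            front_segments_mm=pick("front_segment"),
            spine_lengths_mm=pick("spine"),
            hind_segments_mm=pick("hind_segment"),
            carapace_width_mm=float(by["carapace_width"]) if "carapace_width" in by else None,
            body_length_mm=float(by["body_length"]) if "body_length" in by else None,
        ))
    return out


def species_trait_table(records: list[MorphoRecord],
                        species_speeds: pd.DataFrame | None = None,
                        ecology: pd.DataFrame | None = None,
                        tree_tips: list[str] | None = None
                        ) -> tuple[pd.DataFrame, list[str]]:
    """One row per species: mean spination index (and relative leg length)
    across specimens, joined with species sprint speeds and ecological
    codings. Species absent from the tree are dropped and reported
    (second return value)."""
    rows = []
    for r in records:
        row = {"species": r.species, "spination": spination_index(r)}
        try:
            row["rel_leg_length"] = relative_leg_length(r)
        except ValueError:
            row["rel_leg_length"] = np.nan
        rows.append(row)
    tab = (pd.DataFrame(rows).groupby("species", sort=False)
           .mean(numeric_only=True).reset_index())
    if species_speeds is not None:
        tab = tab.merge(species_speeds[["species", "sprint_rel"]],
                        on="species", how="outer")
    if ecology is not None:
        tab = tab.merge(ecology, on="species", how="left")
    dropped: list[str] = []
    if tree_tips is not None:
        dropped = sorted(set(tab["species"]) - set(tree_tips))
        tab = tab[tab["species"].isin(tree_tips)].reset_index(drop=True)
    return tab, dropped
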