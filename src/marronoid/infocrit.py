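"""Small-sample corrected AIC and Akaike weights, shared by the discrete
(Mk) and continuous trait model sets."""

from __future__ import annotations

import numpy as np

__all__ = ["aicc", "aicc_weights"]


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1); n is the number of tips."""
    if n - k - 1 <= 0:
        return np.inf      # correction diverges; model unsupportable at this n
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(aicc_values) -> np.ndarray:
    """Akaike evidence weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2) with
    d_i = AICc_i - min AICc. Accepts raw AICc values or objects with an
    ``aicc`` attribute."""
    vals = np.array([getattr(a, "aicc", a) for a in aicc_values], dtype=float)
    d = vals - vals.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()
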