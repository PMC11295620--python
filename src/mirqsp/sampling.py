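"""Latin-hypercube sampling helpers shared by the analysis modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .parameters import ModelParameters

__all__ = ["lhs_unit", "lhs_param_overrides", "lhs_log_doses"]


def lhs_unit(n: int, d: int, seed: int) -> np.ndarray:
    """n x d Latin-hypercube sample on [0, 1)^d (one point per bin)."""
    return qmc.LatinHypercube(d=d, seed=seed).random(n)


def lhs_param_overrides(
    base: ModelParameters,
    names: list[str],
    n: int,
    range_frac: float,
    seed: int,
) -> pd.DataFrame:
    """LHS of parameter values within +/- range_frac of their baselines."""
    u = lhs_unit(n, len(names), seed)
    cols = {}
    for j, name in enumerate(names):
        b = getattr(base, name)
        cols[name] = b * (1.0 - range_frac + 2.0 * range_frac * u[:, j])
    return pd.DataFrame(cols)


def lhs_log_doses(
    bounds: dict[str, tuple[float, float]], n: int, seed: int
) -> pd.DataFrame:
    """LHS of dose vectors, uniform in log-dose within per-drug bounds."""
    drugs = list(bounds)
    u = lhs_unit(n, len(drugs), seed)
    cols = {}
    for j, drug in enumerate(drugs):
        lo, hi = bounds[drug]
        if not 0 < lo < hi:
            raise ValueError(f"invalid dose bounds for {drug}: {(lo, hi)}")
        cols[drug] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
    return pd.DataFrame(cols)
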