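"""Shared small statistics helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def fisher_2x2(table) -> tuple[float, float, bool]:
    """Two-sided Fisher exact test; degenerate margins give p = 1.

    Returns (odds_ratio, p_value, degenerate).
    """
    table = np.asarray(table)
    table = np.rint(table).astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0, True
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), False


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    pvals = np.asarray(pvals, dtype=float)
    out = np.full(len(pvals), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        out[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return out


def round_half_up(x: float) -> int:
    """Integer rounding with ties away from zero, as used in reporting."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
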