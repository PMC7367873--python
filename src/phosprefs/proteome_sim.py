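"""Synthetic phosphoproteome site tables.

Emulates the statistical structure of a TMT phosphoproteomics experiment
comparing untreated lysate with PP1c- and PP2Ac-treated lysate: a
pSer-dominated residue mix (~92% pSer), -5..+5 sequence windows drawn
from a proteome-like background, localization probabilities with a
class-I-dominant mixture, log-normal reporter intensities across three
batches with one channel per condition, sequence-dependent
dephosphorylation effects in log2 space, and left-censored (MNAR)
missingness following a logistic detection curve on log intensity.

The planted truth (per-site sensitivity pattern and log2 effects) is
returned alongside the table so downstream inference can be validated as
a parameter-recovery problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProteomeSimParams", "generate_sites", "CONDITIONS", "reporter_column"]

CONDITIONS = ("untreated", "PP1", "PP2A")
PAD = "_"

# average residue frequencies of a vertebrate proteome, used as the flank
# background
BACKGROUND_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}


def reporter_column(condition: str, batch: int) -> str:
    return f"Reporter intensity {condition} {batch}"


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)  # tolerate degenerate base rates
    return float(np.log(p / (1.0 - p)))


@dataclass(frozen=True)
class ProteomeSimParams:
    """Generator settings; defaults emulate the experimental conditions
    of the TMT dephosphorylation assay the table dialect models."""

    # residue mix at the phosphosite (pSer-dominated)
    p_ser: float = 0.92
    p_thr: float = 0.075
    # fraction of sites with localization probability > 0.75 (class I)
    frac_class1: float = 0.85
    # base sensitivity patterns (both / PP1-only / PP2A-only; rest inert)
    frac_both: float = 0.30
    frac_pp1_only: float = 0.17
    frac_pp2_only: float = 0.15
    # correlation of the two sensitivity draws beyond the base rates
    # (Gaussian copula)
    sensitivity_rho: float = 0.0
    # log2 effect of a sensitive site (treated minus untreated)
    effect_mean: float = -2.0
    effect_sd: float = 0.4
    # positional logit coefficients tilting sensitivity; key (0, "T") is
    # the phospho residue itself (pThr preference of both enzymes)
    coef_pp1: dict[tuple[int, str], float] = field(
        default_factory=lambda: {(-3, "R"): 0.8, (-1, "K"): 0.5, (0, "T"): 0.7}
    )
    coef_pp2: dict[tuple[int, str], float] = field(
        default_factory=lambda: {(-2, "E"): 0.5, (0, "T"): 0.7}
    )
    # log2 reporter-intensity model
    intensity_mean: float = 20.0
    intensity_sd: float = 2.0
    batch_sd: float = 0.3
    noise_sd: float = 0.3
    # logistic left-censoring on log2 intensity
    censor_mid: float = 17.0
    censor_scale: float = 0.8
    # nuisance rows
    frac_reverse: float = 0.01
    frac_contaminant: float = 0.01
    # probability that a window touches a protein terminus (padded)
    term_pad_prob: float = 0.02

    def __post_init__(self) -> None:
        probs = (
            self.p_ser, self.p_thr, self.frac_class1,
            self.frac_both, self.frac_pp1_only, self.frac_pp2_only,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p_ser + self.p_thr > 1:
            raise ValueError("p_ser + p_thr must be <= 1")
        if self.frac_both + self.frac_pp1_only + self.frac_pp2_only > 1:
            raise ValueError("sensitivity fractions must sum to <= 1")
        if self.effect_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("noise parameters must be positive")


def _draw_windows(
    centers: np.ndarray, params: ProteomeSimParams, rng: np.random.Generator
) -> np.ndarray:
    n = len(centers)
    residues = sorted(BACKGROUND_FREQS)
    freqs = np.array([BACKGROUND_FREQS[r] for r in residues])
    freqs = freqs / freqs.sum()
    flanks = rng.choice(residues, size=(n, 10), p=freqs)
    win = np.empty((n, 11), dtype="<U1")
    win[:, :5] = flanks[:, :5]
    win[:, 5] = centers
    win[:, 6:] = flanks[:, 5:]
    # occasional terminal padding
    padded = rng.random(n) < params.term_pad_prob
    for i in np.flatnonzero(padded):
        k = rng.integers(1, 4)
        if rng.random() < 0.5:
            win[i, :k] = PAD
        else:
            win[i, 11 - k :] = PAD
    return np.array(["".join(row) for row in win])


def _coef_score(
    windows: np.ndarray, coef: dict[tuple[int, str], float]
) -> np.ndarray:
    mat = np.array([list(w) for w in windows])
    score = np.zeros(len(windows))
    for (pos, res), c in coef.items():
        col = pos + 5
        if 0 <= col < 11:
            score += c * (mat[:, col] == res)
    return score


def generate_sites(
    n_sites: int,
    params: ProteomeSimParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a reduced MaxQuant-style sites table plus the truth.

    Returns ``(sites, truth)``.  ``sites`` columns: Protein, Position,
    Amino acid, Localization prob, Sequence window, Reverse, Potential
    contaminant, and nine reporter-intensity columns (three conditions x
    three batches; missing values are NaN).  ``truth`` carries the
    planted per-site sensitivity pattern and log2 effects.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    params = params or ProteomeSimParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    # phospho residue mix
    u = rng.random(n_sites)
    centers = np.where(
        u < params.p_ser, "S", np.where(u < params.p_ser + params.p_thr, "T", "Y")
    )
    windows = _draw_windows(centers, params, rng)

    # localization probability: class I mixture
    class1 = rng.random(n_sites) < params.frac_class1
    loc = np.where(
        class1,
        0.75 + 0.25 * rng.beta(5.0, 1.0, size=n_sites),
        rng.uniform(0.0, 0.75, size=n_sites),
    )

    # sequence-tilted sensitivity of each phosphatase
    base1 = params.frac_both + params.frac_pp1_only
    base2 = params.frac_both + params.frac_pp2_only
    s1 = _coef_score(windows, params.coef_pp1)
    s2 = _coef_score(windows, params.coef_pp2)
    p1 = 1.0 / (1.0 + np.exp(-(_logit(base1) + s1)))
    p2 = 1.0 / (1.0 + np.exp(-(_logit(base2) + s2)))
    rho = params.sensitivity_rho
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n_sites
    )
    from scipy.stats import norm

    sens1 = norm.cdf(z[:, 0]) < p1
    sens2 = norm.cdf(z[:, 1]) < p2
    pattern = np.select(
        [sens1 & sens2, sens1 & ~sens2, ~sens1 & sens2],
        ["both", "PP1", "PP2A"],
        default="none",
    )

    eff1 = np.where(
        sens1, rng.normal(params.effect_mean, params.effect_sd, n_sites), 0.0
    )
    eff2 = np.where(
        sens2, rng.normal(params.effect_mean, params.effect_sd, n_sites), 0.0
    )

    base_log2 = rng.normal(params.intensity_mean, params.intensity_sd, n_sites)
    data: dict[str, np.ndarray] = {}
    for b in range(1, 4):
        batch_shift = rng.normal(0.0, params.batch_sd)
        for cond, eff in (("untreated", 0.0), ("PP1", eff1), ("PP2A", eff2)):
            x = base_log2 + batch_shift + eff + rng.normal(0, params.noise_sd, n_sites)
            detect_p = 1.0 / (
                1.0 + np.exp(-(x - params.censor_mid) / params.censor_scale)
            )
            observed = rng.random(n_sites) < detect_p
            vals = np.where(observed, np.exp2(x), np.nan)
            data[reporter_column(cond, b)] = vals

    protein = np.array([f"P{i:05d}" for i in range(n_sites)])
    position = rng.integers(5, 1500, size=n_sites)
    sites = pd.DataFrame(
        {
            "Protein": protein,
            "Position": position,
            "Amino acid": centers,
            "Localization prob": loc,
            "Sequence window": windows,
            "Reverse": "",
            "Potential contaminant": "",
            **data,
        }
    )
    truth = pd.DataFrame(
        {
            "Protein": protein,
            "Position": position,
            "pattern": pattern,
            "effect_pp1": eff1,
            "effect_pp2": eff2,
            "base_log2": base_log2,
            "class1": class1,
        }
    )

    # nuisance rows: decoy (reverse) and contaminant entries
    n_rev = int(round(params.frac_reverse * n_sites))
    n_con = int(round(params.frac_contaminant * n_sites))
    extras = []
    for flag_col, m in (("Reverse", n_rev), ("Potential contaminant", n_con)):
        if m == 0:
            continue
        idx = rng.choice(n_sites, size=m, replace=False)
        block = sites.iloc[idx].copy().reset_index(drop=True)
        block["Protein"] = [f"{'REV' if flag_col == 'Reverse' else 'CON'}__{p}"
                            for p in block["Protein"]]
        block[flag_col] = "+"
        extras.append(block)
    if extras:
        sites = pd.concat([sites, *extras], ignore_index=True)
    return sites, truth
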