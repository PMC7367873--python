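"""Phosphoproteome differential-dephosphorylation inference and motif
analyses.

The chain mirrors a Perseus-style workflow on a TMT phosphosite table:
class I filtering (localization probability > 0.75), row-wise
within-batch median normalization, log2 transform, a valid-value filter,
Gaussian down-shifted imputation of left-censored missing values, and a
SAM-style s0-moderated two-sample t-test with permutation-based FDR.
Downstream readouts: one-way ANOVA + hierarchical clustering of response
patterns, phosphatase-sensitivity classes, pThr enrichment, positional
relative-abundance fold-change matrices (-5..+5), frequency matrices for
PSSM export, basic-motif flags (RxxpS), and interactome overlap
arithmetic.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust, fisher_2x2, round_half_up

__all__ = [
    "preprocess",
    "impute",
    "s0_ttest",
    "DiffTestResult",
    "anova_cluster",
    "AnovaClusterResult",
    "cluster_shares",
    "sensitivity_classes",
    "pthr_enrichment",
    "positional_fc_matrix",
    "PositionalFcMatrix",
    "differential_positional_matrix",
    "frequency_matrix",
    "write_pssm",
    "motif_flags",
    "overlap_report",
]

PAD = "_"
_REPORTER_RE = re.compile(r"^Reporter intensity (\S+) (\d+)$")


def reporter_layout(columns) -> dict[str, list[str]]:
    """Map condition -> ordered reporter column names."""
    layout: dict[str, list[str]] = {}
    for col in columns:
        m = _REPORTER_RE.match(col)
        if m:
            layout.setdefault(m.group(1), []).append(col)
    return layout


def preprocess(
    sites: pd.DataFrame,
    loc_min: float = 0.75,
    min_valid: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and normalize a sites table into a log2 matrix.

    Steps: drop reverse/contaminant rows; keep class I sites
    (localization probability strictly > ``loc_min``); within each batch
    divide the row's channels by the row's within-batch median intensity;
    log2-transform; keep rows with at least ``min_valid`` valid values in
    at least one condition group.

    Returns ``(matrix, meta)`` with aligned row indices; matrix columns
    are named ``<condition>_<batch>``.
    """
    layout = reporter_layout(sites.columns)
    if not layout:
        raise ValueError("no reporter-intensity columns found")
    df = sites
    for flag in ("Reverse", "Potential contaminant"):
        if flag in df.columns:
            df = df[df[flag] != "+"]
    if "Localization prob" in df.columns:
        df = df[df["Localization prob"] > loc_min]
    df = df.reset_index(drop=True)

    # batches present in the layout
    batches = sorted(
        {int(_REPORTER_RE.match(c).group(2)) for cols in layout.values() for c in cols}
    )
    norm_cols: dict[str, np.ndarray] = {}
    for b in batches:
        batch_cols = [c for cols in layout.values() for c in cols
                      if int(_REPORTER_RE.match(c).group(2)) == b]
        block = df[batch_cols].to_numpy(dtype=float)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            med = np.nanmedian(block, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            block = np.log2(block / med)
        for j, c in enumerate(batch_cols):
            cond = _REPORTER_RE.match(c).group(1)
            norm_cols[f"{cond}_{b}"] = block[:, j]
    matrix = pd.DataFrame(norm_cols, index=df.index)

    groups = condition_groups(matrix.columns)
    valid_ok = np.zeros(len(matrix), dtype=bool)
    for cols in groups.values():
        valid_ok |= matrix[cols].notna().sum(axis=1).to_numpy() >= min_valid
    matrix = matrix[valid_ok]
    meta = df.loc[matrix.index, [c for c in df.columns if not _REPORTER_RE.match(c)]]
    return matrix.reset_index(drop=True), meta.reset_index(drop=True)


def condition_groups(columns) -> dict[str, list[str]]:
    """Group ``<condition>_<batch>`` matrix columns by condition."""
    out: dict[str, list[str]] = {}
    for c in columns:
        cond = c.rsplit("_", 1)[0]
        out.setdefault(cond, []).append(c)
    return out


def impute(
    matrix: pd.DataFrame,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replace missing values column-wise from a down-shifted Gaussian.

    Per column with observed mean m and standard deviation s, missing
    entries are drawn from Normal(m - shift*s, (width*s)^2) — the
    standard treatment of left-censored (low-abundance) missingness.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = matrix.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        m, s = float(np.mean(obs)), float(np.std(obs, ddof=1))
        n_missing = int(np.isnan(x).sum())
        if n_missing:
            x[np.isnan(x)] = rng.normal(m - shift * s, width * s, size=n_missing)
        out[col] = x
    return out


@dataclass(frozen=True)
class DiffTestResult:
    """Per-row s0-moderated t-test results for one contrast."""

    table: pd.DataFrame  # log2_fc, d, q_value, significant
    s0: float
    fdr: float
    n_perm: int


def _d_stat(x1: np.ndarray, x2: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """SAM-style statistic d = (mean1 - mean2) / (pooled SE + s0)."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (m1 - m2) / (se + s0)
    d = np.where(np.isfinite(d), d, 0.0)
    return d, m1 - m2


def _permutation_splits(
    n1: int, n2: int, n_perm, rng: np.random.Generator
) -> list[np.ndarray]:
    """Column index arrays assigning group 1 under permuted labels."""
    n = n1 + n2
    # the identity split and (for balanced designs) its complement
    # reproduce the observed statistics exactly; keeping them in the null
    # would impose an FDR floor of 2/n_perm, so they are excluded
    identity = frozenset(range(n1))
    complement = frozenset(range(n1, n))

    def informative(split) -> bool:
        fs = frozenset(split)
        return fs != identity and (n1 != n2 or fs != complement)

    n_distinct = math.comb(n, n1)
    if n_perm == "all" or (isinstance(n_perm, int) and n_perm >= n_distinct):
        splits = [s for s in itertools.combinations(range(n), n1) if informative(s)]
        return [np.array(s) for s in splits]
    if n_distinct <= 100_000:
        all_splits = [
            s for s in itertools.combinations(range(n), n1) if informative(s)
        ]
        chosen = rng.choice(len(all_splits), size=min(n_perm, len(all_splits)),
                            replace=False)
        return [np.array(all_splits[i]) for i in chosen]
    out = []
    while len(out) < n_perm:
        s = rng.permutation(n)[:n1]
        if informative(s):
            out.append(np.array(sorted(s)))
    return out


def s0_ttest(
    matrix: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    s0: float = 0.1,
    n_perm: int | str = 250,
    fdr: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> DiffTestResult:
    """Two-sided s0-moderated t-test with permutation-estimated FDR.

    The statistic is d = (mean(group1) - mean(group2)) / (pooled SE + s0);
    the null distribution pools d over ``n_perm`` distinct group-label
    permutations (``"all"`` enumerates every split, feasible for small
    designs).  For each candidate threshold |d|, the q-value is the
    estimated FDR — the mean number of permuted |d| exceeding the
    threshold over the observed count — monotonized so that more extreme
    statistics never have larger q.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 members")
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = matrix[group1 + group2].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("matrix contains missing values; impute first")
    n1 = len(group1)
    d_obs, log2_fc = _d_stat(x[:, :n1], x[:, n1:], s0)

    splits = _permutation_splits(n1, len(group2), n_perm, rng)
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]

    null_counts = np.zeros(len(sorted_abs))
    for split in splits:
        rest = np.setdiff1d(np.arange(x.shape[1]), split)
        d_p, _ = _d_stat(x[:, split], x[:, rest], s0)
        # permuted |d| >= each observed threshold, via sorted search
        d_p_sorted = np.sort(np.abs(d_p))
        null_counts += len(d_p) - np.searchsorted(d_p_sorted, sorted_abs, side="left")
    expected_fp = null_counts / len(splits)
    observed_pos = np.arange(1, len(sorted_abs) + 1)
    fdr_at = np.minimum(expected_fp / observed_pos, 1.0)
    # q(t) = min FDR over thresholds at or below t (monotone step-up)
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty(len(q_sorted))
    q[order] = q_sorted

    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "d": d_obs,
            "q_value": q,
            "significant": q <= fdr,
        },
        index=matrix.index,
    )
    return DiffTestResult(table=table, s0=s0, fdr=fdr, n_perm=len(splits))


@dataclass(frozen=True)
class AnovaClusterResult:
    anova_p: np.ndarray
    adjusted_p: np.ndarray
    significant: np.ndarray
    z_matrix: pd.DataFrame
    labels: np.ndarray  # cluster id per significant row
    sizes: pd.Series  # cluster id -> size, descending


def anova_cluster(
    matrix: pd.DataFrame,
    fdr: float = 0.01,
    k: int = 3,
    linkage: str = "ward",
) -> AnovaClusterResult:
    """One-way ANOVA across conditions, BH filter, z-transform, and
    Euclidean hierarchical clustering of significant rows.

    Ward linkage is the default: on z-transformed response profiles it
    separates the both / PP1-only / PP2A-only patterns cleanly, whereas
    average linkage tends to chain them into one dominant cluster.
    """
    from sklearn.cluster import AgglomerativeClustering

    groups = condition_groups(matrix.columns)
    if len(groups) < 3:
        raise ValueError("need at least 3 conditions for one-way ANOVA")
    arrays = [matrix[cols].to_numpy(dtype=float) for cols in groups.values()]
    res = sps.f_oneway(*arrays, axis=1)
    pvals = np.asarray(res.pvalue)
    adj = bh_adjust(pvals)
    sig = adj < fdr
    if sig.sum() < k:
        raise ValueError(f"only {int(sig.sum())} significant rows; cannot form {k} clusters")
    x = matrix[sig].to_numpy(dtype=float)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)
    z_matrix = pd.DataFrame(z, index=matrix.index[sig], columns=matrix.columns)
    model = AgglomerativeClustering(n_clusters=k, metric="euclidean", linkage=linkage)
    labels = model.fit_predict(z)
    sizes = pd.Series(labels).value_counts()
    return AnovaClusterResult(
        anova_p=pvals,
        adjusted_p=adj,
        significant=sig,
        z_matrix=z_matrix,
        labels=labels,
        sizes=sizes,
    )


def cluster_shares(sizes) -> pd.DataFrame:
    """Percentage share of each cluster among the clustered rows.

    ``percent`` is exact; ``percent_rounded`` is half-up integer rounding
    as used when reporting shares such as 48/28/24%.
    """
    sizes = pd.Series(sizes)
    total = sizes.sum()
    pct = 100.0 * sizes / total
    return pd.DataFrame(
        {
            "size": sizes,
            "percent": pct,
            "percent_rounded": [round_half_up(p) for p in pct],
        }
    )


def sensitivity_classes(
    res_pp1: pd.DataFrame,
    res_pp2: pd.DataFrame,
    criterion: str = "significance",
    fc_cutoff: float = -1.0,
) -> pd.Series:
    """Per-site sensitivity class from two contrast results.

    ``criterion``: ``"fc"`` (log2 fold change strictly below
    ``fc_cutoff``), ``"significance"`` (the s0-test flag), or ``"both"``.
    Classes: ``both``, ``PP1``, ``PP2A``, ``insensitive``.
    """

    def sensitive(res: pd.DataFrame) -> np.ndarray:
        if criterion == "fc":
            return (res["log2_fc"] < fc_cutoff).to_numpy()
        if criterion == "significance":
            return res["significant"].to_numpy()
        if criterion == "both":
            return (
                (res["log2_fc"] < fc_cutoff) & res["significant"]
            ).to_numpy()
        raise ValueError(f"unknown criterion {criterion!r}")

    s1, s2 = sensitive(res_pp1), sensitive(res_pp2)
    out = np.select(
        [s1 & s2, s1 & ~s2, ~s1 & s2], ["both", "PP1", "PP2A"], default="insensitive"
    )
    return pd.Series(out, index=res_pp1.index, name="class")


def pthr_enrichment(
    sensitive: np.ndarray, residues: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher test of pThr share in sensitive vs insensitive
    sites.  Returns (odds_ratio, p, table)."""
    sensitive = np.asarray(sensitive, dtype=bool)
    is_t = np.asarray(residues) == "T"
    table = np.array(
        [
            [int((sensitive & is_t).sum()), int((sensitive & ~is_t).sum())],
            [int((~sensitive & is_t).sum()), int((~sensitive & ~is_t).sum())],
        ]
    )
    odds, p, _ = fisher_2x2(table)
    return odds, p, table


def _window_counts(windows, length: int = 11) -> pd.DataFrame:
    """Residue counts per position (-5..+5), excluding padding."""
    arr = np.array([list(w) for w in windows])
    if arr.shape[1] != length:
        raise ValueError(f"windows must have length {length}")
    half = length // 2
    rows = []
    for col in range(length):
        pos = col - half
        vals, counts = np.unique(arr[:, col], return_counts=True)
        for v, c in zip(vals, counts):
            if v == PAD:
                continue
            rows.append({"position": pos, "residue": v, "count": int(c)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PositionalFcMatrix:
    """Relative-abundance fold changes, sensitive vs insensitive sites."""

    table: pd.DataFrame
    # columns: position, residue, count_sensitive, count_insensitive,
    # rel_sensitive, rel_insensitive, fold_change, masked, p_value, adjusted_p

    def pivot(self, value: str = "fold_change") -> pd.DataFrame:
        return self.table.pivot(index="residue", columns="position", values=value)


def positional_fc_matrix(
    sensitive_windows,
    insensitive_windows,
    min_count: int = 25,
    with_tests: bool = True,
) -> PositionalFcMatrix:
    """Per-position relative-abundance fold change between the
    phosphatase-sensitive and insensitive window sets.

    Relative abundance is the residue count over the total (non-padding)
    count at the position within each set; cells with raw counts below
    ``min_count`` in either set are masked and carry no fold change.
    """
    if len(sensitive_windows) == 0 or len(insensitive_windows) == 0:
        raise ValueError("both window sets must be non-empty")
    cs = _window_counts(sensitive_windows).rename(columns={"count": "count_sensitive"})
    ci = _window_counts(insensitive_windows).rename(columns={"count": "count_insensitive"})
    tab = cs.merge(ci, on=["position", "residue"], how="outer").fillna(0)
    tab[["count_sensitive", "count_insensitive"]] = tab[
        ["count_sensitive", "count_insensitive"]
    ].astype(int)
    for side in ("sensitive", "insensitive"):
        totals = tab.groupby("position")[f"count_{side}"].transform("sum")
        tab[f"rel_{side}"] = tab[f"count_{side}"] / totals
    tab["masked"] = (tab["count_sensitive"] < min_count) | (
        tab["count_insensitive"] < min_count
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = tab["rel_sensitive"] / tab["rel_insensitive"]
    tab["fold_change"] = np.where(tab["masked"], np.nan, fc)
    if with_tests:
        pvals = np.full(len(tab), np.nan)
        tot_s = tab.groupby("position")["count_sensitive"].transform("sum").to_numpy()
        tot_i = tab.groupby("position")["count_insensitive"].transform("sum").to_numpy()
        for i in range(len(tab)):
            if tab["masked"].iat[i]:
                continue
            a, b = tab["count_sensitive"].iat[i], tab["count_insensitive"].iat[i]
            _, p, _ = fisher_2x2([[a, tot_s[i] - a], [b, tot_i[i] - b]])
            pvals[i] = p
        tab["p_value"] = pvals
        tab["adjusted_p"] = bh_adjust(pvals)
    return PositionalFcMatrix(table=tab.sort_values(["position", "residue"]).reset_index(drop=True))


def differential_positional_matrix(
    m1: PositionalFcMatrix,
    m2: PositionalFcMatrix,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Direct comparison of two positional fold-change matrices.

    Per cell: the ratio of the two fold changes, plus a two-sided Fisher
    test on the sensitive-set counts (this residue vs the summed counts
    of all other residues at the position, matrix 1 vs matrix 2),
    BH-adjusted; cells with adjusted p below ``alpha`` are flagged.
    """
    t1 = m1.table[
        ["position", "residue", "count_sensitive", "fold_change", "masked"]
    ].rename(columns={"count_sensitive": "n1", "fold_change": "fc1", "masked": "masked1"})
    t2 = m2.table[
        ["position", "residue", "count_sensitive", "fold_change", "masked"]
    ].rename(columns={"count_sensitive": "n2", "fold_change": "fc2", "masked": "masked2"})
    tab = t1.merge(t2, on=["position", "residue"], how="outer")
    if tab[["n1", "n2"]].isna().any().any():
        tab[["n1", "n2"]] = tab[["n1", "n2"]].fillna(0).astype(int)
    tab["masked"] = tab["masked1"].fillna(True) | tab["masked2"].fillna(True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["fc_ratio"] = tab["fc1"] / tab["fc2"]
    pvals = np.full(len(tab), np.nan)
    tot1 = tab.groupby("position")["n1"].transform("sum").to_numpy()
    tot2 = tab.groupby("position")["n2"].transform("sum").to_numpy()
    for i in range(len(tab)):
        if tab["masked"].iat[i]:
            continue
        a, b = tab["n1"].iat[i], tab["n2"].iat[i]
        _, p, _ = fisher_2x2([[a, tot1[i] - a], [b, tot2[i] - b]])
        pvals[i] = p
    tab["p_value"] = pvals
    tab["adjusted_p"] = bh_adjust(pvals)
    tab["flagged"] = tab["adjusted_p"] < alpha
    return tab.drop(columns=["masked1", "masked2"])


def frequency_matrix(windows, length: int = 11) -> pd.DataFrame:
    """Per-position residue probabilities of a window set (padding
    excluded); positions -5..+5 as columns, residues as rows."""
    counts = _window_counts(windows, length)
    wide = counts.pivot(index="residue", columns="position", values="count").fillna(0)
    return wide / wide.sum(axis=0)


def write_pssm(freq: pd.DataFrame, path) -> None:
    """Export a frequency matrix in a PSSM-compatible tab layout
    (residue rows, position columns)."""
    freq.to_csv(path, sep="\t", float_format="%.6f")


def motif_flags(window: str) -> tuple[bool, int]:
    """Basic-motif flags of an 11-residue window centered on the p-site.

    Returns ``(has_RxxpS, n_basic_upstream)``: Arg exactly at -3, and the
    number of Arg/Lys residues at -5..-1.
    """
    if len(window) != 11:
        raise ValueError("window must have 11 residues (p-site centered)")
    center = 5
    has_rxxps = window[center - 3] == "R"
    upstream = window[center - 5 : center]
    n_basic = sum(1 for r in upstream if r in "RK")
    return has_rxxps, n_basic


def overlap_report(
    interactors: set[str],
    dissociated: set[str],
    regulated_sites: pd.DataFrame,
) -> dict[str, float]:
    """Overlap arithmetic between an interactome and regulated p-sites.

    ``regulated_sites`` needs columns ``Protein`` and ``Sequence window``
    (11-mer) for proteins with at least one phosphatase-regulated p-site.
    A dissociated protein is counted in the RxxpS class if any of its
    regulated sites carries Arg at -3, else in the other-basic class if
    any site has Arg/Lys at -5..-1.  Percentages are half-up integer
    rounded.
    """
    if not interactors:
        raise ValueError("empty interactor set")
    dissociated = set(dissociated)
    n_inter = len(interactors)
    n_diss = len(dissociated)
    reg = regulated_sites[regulated_sites["Protein"].isin(dissociated)]
    rxxps_proteins: set[str] = set()
    basic_proteins: set[str] = set()
    for prot, sub in reg.groupby("Protein"):
        flags = [motif_flags(w) for w in sub["Sequence window"]]
        if any(f[0] for f in flags):
            rxxps_proteins.add(prot)
        elif any(f[1] >= 1 for f in flags):
            basic_proteins.add(prot)
    n_reg = reg["Protein"].nunique()
    n_rxxps = len(rxxps_proteins)
    n_basic = len(basic_proteins)
    return {
        "n_interactors": n_inter,
        "n_dissociated": n_diss,
        "pct_dissociated": round_half_up(100.0 * n_diss / n_inter),
        "n_with_regulated_site": n_reg,
        "n_rxxps": n_rxxps,
        "n_other_basic": n_basic,
        "pct_basic": (
            round_half_up(100.0 * (n_rxxps + n_basic) / n_diss) if n_diss else 0
        ),
    }
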