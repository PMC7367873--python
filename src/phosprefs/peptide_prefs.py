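"""Peptide-library dephosphorylation readouts.

Turns filtered PSM tables into substrate-preference statistics: the
global pThr-vs-pSer preference (Fisher exact), positional preference
matrices (per-cell dephosphorylation rate over the average library rate),
PP1c-vs-PP2Ac differential matrices with per-cell Fisher tests and
Benjamini-Hochberg correction, charge-combination summaries, and GRAVY
hydropathy scores.

The counting unit is the unique (sequence, phospho-residue) pair: a
library peptide either was or was not dephosphorylated, and PSM
multiplicity reflects abundance rather than conversion.  A PSM-count
mode is available through the ``weight`` column of the flag table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from ._stats import bh_adjust as _bh_with_nan
from ._stats import fisher_2x2 as _fisher_2x2
from .library_design import LibraryDesign

__all__ = [
    "KYTE_DOOLITTLE",
    "dephos_status",
    "background_composition",
    "FisherResult",
    "pthr_vs_pser_test",
    "PreferenceMatrix",
    "preference_matrix",
    "differential_matrix",
    "charge_combinations",
    "gravy",
]

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle index."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return float(np.mean([KYTE_DOOLITTLE[r] for r in sequence]))
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def dephos_status(
    filtered_treated: pd.DataFrame,
    design: LibraryDesign,
    unit: str = "sequence",
) -> pd.DataFrame:
    """Per-unique-sequence dephosphorylation flags for one treated sample.

    A unique (sequence, phospho residue) is flagged dephosphorylated iff
    its non-phospho form was identified in the treated sample.  Input is
    the output of the PSM filter for that sample.

    With ``unit="psm"`` a ``weight`` column carries the PSM count of each
    sequence, for the abundance-weighted counting mode.
    """
    if unit not in ("sequence", "psm"):
        raise ValueError("unit must be 'sequence' or 'psm'")
    df = filtered_treated
    grouped = df.groupby("sequence", sort=False)
    dephos = grouped["phospho_position"].agg(lambda p: bool((p < 0).any()))
    out = pd.DataFrame(
        {
            "sequence": dephos.index,
            "dephos": dephos.to_numpy(),
        }
    ).reset_index(drop=True)
    out["phospho_residue"] = out["sequence"].str[design.phospho_slot]
    if unit == "psm":
        out = out.merge(
            grouped.size().rename("weight").reset_index(), on="sequence"
        )
    else:
        out["weight"] = 1
    return out


def background_composition(
    filtered_untreated: pd.DataFrame, design: LibraryDesign
) -> pd.Series:
    """Unique-sequence counts of the phospho residue (S/T) in the
    untreated reference."""
    seqs = filtered_untreated["sequence"].drop_duplicates()
    return seqs.str[design.phospho_slot].value_counts()


@dataclass(frozen=True)
class FisherResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    share_pt_dephos: float | None = None
    share_pt_reference: float | None = None
    degenerate: bool = False


def pthr_vs_pser_test(
    flags: pd.DataFrame,
    background: pd.Series | None = None,
) -> FisherResult:
    """Two-sided Fisher exact test of pThr vs pSer dephosphorylation.

    Default contrast: dephosphorylated vs not-dephosphorylated unique
    sequences.  When *background* (untreated S/T counts) is given, the
    dephosphorylated set is instead tested against that reference
    composition.
    """
    is_t = flags["phospho_residue"] == "T"
    w = flags["weight"].to_numpy()
    d = flags["dephos"].to_numpy()
    dephos_t = int(w[d & is_t].sum())
    dephos_s = int(w[d & ~is_t].sum())
    if background is not None:
        other_t = int(background.get("T", 0))
        other_s = int(background.get("S", 0))
    else:
        other_t = int(w[~d & is_t].sum())
        other_s = int(w[~d & ~is_t].sum())
    table = np.array([[dephos_t, dephos_s], [other_t, other_s]])
    odds, p, degenerate = _fisher_2x2(table)
    n_dephos = dephos_t + dephos_s
    n_other = other_t + other_s
    return FisherResult(
        table=table,
        odds_ratio=odds,
        p_value=p,
        share_pt_dephos=dephos_t / n_dephos if n_dephos else None,
        share_pt_reference=other_t / n_other if n_other else None,
        degenerate=degenerate,
    )


def _position_residue_counts(
    flags: pd.DataFrame, design: LibraryDesign
) -> pd.DataFrame:
    """Long table of (position label, residue, n_dephos, n_total) over the
    design's randomized slots."""
    rows = []
    seqs = flags["sequence"].to_numpy()
    w = flags["weight"].to_numpy(dtype=float)
    d = flags["dephos"].to_numpy(dtype=bool)
    for slot in design.randomized_slots():
        label = design.position_label(slot)
        residues = np.array([s[slot] for s in seqs])
        for res in sorted(design.slots[slot]):
            mask = residues == res
            rows.append(
                {
                    "position": label,
                    "residue": res,
                    "n_dephos": float(w[mask & d].sum()),
                    "n_total": float(w[mask].sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PreferenceMatrix:
    """Long-format positional preference grid plus the scalar library rate."""

    table: pd.DataFrame  # position, residue, n_dephos, n_total, rate, fold_change, p_value, adjusted_p
    library_rate: float

    def pivot(self, value: str = "fold_change") -> pd.DataFrame:
        return self.table.pivot(index="residue", columns="position", values=value)


def preference_matrix(
    flags: pd.DataFrame,
    design: LibraryDesign,
    with_tests: bool = True,
) -> PreferenceMatrix:
    """Positional dephosphorylation preference of one phosphatase.

    Per (position, residue): rate = dephosphorylated / total among
    sequences carrying that residue at that position; fold change = rate
    over the average library dephosphorylation rate (1 = no preference).
    Optional per-cell Fisher test of the cell vs all other residues at
    the position (dephosphorylated vs not), BH-adjusted across cells.
    """
    w = flags["weight"].to_numpy(dtype=float)
    total = w.sum()
    if total == 0:
        raise ValueError("no sequences")
    library_rate = float(w[flags["dephos"].to_numpy(dtype=bool)].sum() / total)
    if library_rate == 0:
        raise ValueError("no dephosphorylation events")
    tab = _position_residue_counts(flags, design)
    with np.errstate(invalid="ignore", divide="ignore"):
        tab["rate"] = np.where(tab["n_total"] > 0, tab["n_dephos"] / tab["n_total"], np.nan)
    tab["fold_change"] = tab["rate"] / library_rate
    if with_tests:
        pvals = np.full(len(tab), np.nan)
        for pos, idx in tab.groupby("position").groups.items():
            sub = tab.loc[idx]
            tot_d = sub["n_dephos"].sum()
            tot_n = sub["n_total"].sum()
            for i in idx:
                a = tab.at[i, "n_dephos"]
                n = tab.at[i, "n_total"]
                if n == 0:
                    continue
                table = np.array(
                    [
                        [a, n - a],
                        [tot_d - a, (tot_n - n) - (tot_d - a)],
                    ]
                )
                _, p, _ = _fisher_2x2(table)
                pvals[tab.index.get_loc(i)] = p
        tab["p_value"] = pvals
        tab["adjusted_p"] = _bh_with_nan(pvals)
    return PreferenceMatrix(table=tab, library_rate=library_rate)


def differential_matrix(
    flags_pp1: pd.DataFrame,
    flags_pp2: pd.DataFrame,
    design: LibraryDesign,
    fc_threshold: float = 1.2,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """PP1-vs-PP2 differential preference grid for one library class.

    Per cell: the ratio of dephosphorylated counts PP1/PP2, median-
    normalized over the grid's defined cells to control for global
    rate differences; per-cell two-sided Fisher test of this residue
    against the summed counts of all other residues at the position
    (PP1 vs PP2), BH-adjusted across cells.  Cells with normalized fold
    change > ``fc_threshold`` (or < 1/``fc_threshold``) and adjusted
    p < ``alpha`` are flagged PP1- (PP2-) preferred.
    """
    c1 = _position_residue_counts(flags_pp1, design).rename(
        columns={"n_dephos": "dephos_pp1", "n_total": "total_pp1"}
    )
    c2 = _position_residue_counts(flags_pp2, design).rename(
        columns={"n_dephos": "dephos_pp2", "n_total": "total_pp2"}
    )
    tab = c1.merge(c2, on=["position", "residue"])
    if tab["dephos_pp1"].sum() == 0 or tab["dephos_pp2"].sum() == 0:
        raise ValueError("a grid has no dephosphorylated counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(
            (tab["dephos_pp2"] > 0) & (tab["dephos_pp1"] > 0),
            tab["dephos_pp1"] / tab["dephos_pp2"],
            np.nan,
        )
    tab["raw_ratio"] = raw
    # median taken in log space: identical to the plain median for an odd
    # number of defined cells, geometric mean of the middle pair otherwise,
    # which makes swapping the phosphatases an exact cell-wise reciprocal
    with np.errstate(invalid="ignore", divide="ignore"):
        median = float(np.exp(np.nanmedian(np.log(raw))))
    tab["fold_change"] = raw / median

    pvals = np.full(len(tab), np.nan)
    for pos, idx in tab.groupby("position").groups.items():
        sub = tab.loc[idx]
        t1 = sub["dephos_pp1"].sum()
        t2 = sub["dephos_pp2"].sum()
        for i in idx:
            a1 = tab.at[i, "dephos_pp1"]
            a2 = tab.at[i, "dephos_pp2"]
            table = np.array([[a1, t1 - a1], [a2, t2 - a2]])
            _, p, _ = _fisher_2x2(table)
            pvals[tab.index.get_loc(i)] = p
    tab["p_value"] = pvals
    tab["adjusted_p"] = _bh_with_nan(pvals)
    fc = tab["fold_change"]
    sig = tab["adjusted_p"] < alpha
    tab["pp1_preferred"] = (fc > fc_threshold) & sig
    tab["pp2_preferred"] = (fc < 1.0 / fc_threshold) & sig
    return tab


def charge_combinations(
    flags: pd.DataFrame,
    design: LibraryDesign,
    residues: tuple[str, ...] = ("K", "R", "E"),
    labels: tuple[int, ...] = (-4, -3, -2, -1),
    max_count: int = 2,
) -> pd.DataFrame:
    """Dephosphorylation fraction by residue-count class.

    For each residue of interest, sequences are binned by how many copies
    they carry at the given position labels (counts capped at
    ``max_count``); each class is Fisher-tested (two-sided) against the
    zero-count class, BH-adjusted per residue.  Classes with no members
    are omitted.
    """
    slots = [design.slot_of_label(l) for l in labels]
    rand = set(design.randomized_slots())
    slots = [s for s in slots if s in rand]
    if not slots:
        raise ValueError("design does not randomize the requested positions")
    seqs = flags["sequence"].to_numpy()
    w = flags["weight"].to_numpy(dtype=float)
    d = flags["dephos"].to_numpy(dtype=bool)
    seq_mat = np.array([list(s) for s in seqs])
    rows = []
    for res in residues:
        counts = (seq_mat[:, slots] == res).sum(axis=1)
        counts = np.minimum(counts, max_count)
        ref_mask = counts == 0
        ref = (w[ref_mask & d].sum(), w[ref_mask & ~d].sum())
        pvals, recs = [], []
        for c in range(0, max_count + 1):
            mask = counts == c
            n_total = float(w[mask].sum())
            if n_total == 0:
                continue
            n_dephos = float(w[mask & d].sum())
            if c == 0:
                p = np.nan
            else:
                table = np.array(
                    [[n_dephos, n_total - n_dephos], [ref[0], ref[1]]]
                )
                _, p, _ = _fisher_2x2(table)
            recs.append(
                {
                    "residue": res,
                    "count": c,
                    "n_dephos": n_dephos,
                    "n_total": n_total,
                    "fraction": n_dephos / n_total,
                    "p_value": p,
                }
            )
            pvals.append(p)
        adj = _bh_with_nan(np.array(pvals, dtype=float))
        for rec, a in zip(recs, adj):
            rec["adjusted_p"] = a
            rows.append(rec)
    return pd.DataFrame(rows)
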