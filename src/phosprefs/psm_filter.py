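"""Empirical PSM classification and FDR-based score filtering.

Because the synthesis fully determines the theoretical peptide space, a
PSM can be classified as empirically correct or wrong without decoys:
wrong length, a sequence outside the design, a phosphate on a position
other than the synthesized slot, or a non-phospho identification in an
untreated sample are all impossible by construction.  The FDR at a score
threshold s is FP(s) / (TP(s) + FP(s)) over records with score >= s, and
filtering retains empirically correct records at the smallest threshold
whose FDR is at or below the target (5% by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_design import LibraryDesign

__all__ = [
    "CATEGORIES",
    "CORRECT_CATEGORIES",
    "classify_psm",
    "classify_table",
    "FdrCurve",
    "fdr_curve",
    "cutoff_at_fdr",
    "apply_filter",
    "filter_report",
]

CATEGORIES = (
    "correct_phospho",
    "correct_dephospho",
    "wrong_length",
    "wrong_sequence",
    "wrong_phospho_position",
    "missing_phospho",
)
CORRECT_CATEGORIES = ("correct_phospho", "correct_dephospho")


def classify_psm(
    sequence: str,
    phospho_position: int,
    treatment: str,
    design: LibraryDesign,
) -> str:
    """Empirical category of one PSM against its library design.

    Precedence: length, then sequence membership, then phosphate
    placement.  A design-matching non-phospho record (position -1) is
    ``correct_dephospho`` in a treated sample but ``missing_phospho``
    (wrong) in the untreated reference, where nothing was
    dephosphorylated.
    """
    if len(sequence) != design.length:
        return "wrong_length"
    if not design.matches_sequence(sequence):
        return "wrong_sequence"
    if phospho_position < 0:
        return "missing_phospho" if treatment == "untreated" else "correct_dephospho"
    if phospho_position != design.phospho_slot:
        return "wrong_phospho_position"
    return "correct_phospho"


def classify_table(
    psms: pd.DataFrame,
    designs: dict[str, LibraryDesign],
    flag_cross_library: bool = True,
) -> pd.DataFrame:
    """Vectorized classification; adds ``category`` (and ``cross_library``).

    A record whose sequence fails its own design but matches another
    design of the union is flagged cross-library; such records are
    excluded from per-library FDR curves rather than silently kept.
    """
    orig_index = psms.index
    psms = psms.reset_index(drop=True)
    unknown = set(psms["library"]) - set(designs)
    if unknown:
        raise KeyError(f"unknown library name(s): {sorted(unknown)}")
    category = np.empty(len(psms), dtype=object)
    cross = np.zeros(len(psms), dtype=bool)
    for lib, idx in psms.groupby("library", sort=False).groups.items():
        design = designs[lib]
        sub = psms.loc[idx]
        seqs = sub["sequence"].to_numpy()
        ppos = sub["phospho_position"].to_numpy()
        untreated = (sub["treatment"] == "untreated").to_numpy()

        length_ok = np.array([len(s) == design.length for s in seqs])
        member = np.zeros(len(seqs), dtype=bool)
        if length_ok.any():
            ok_idx = np.flatnonzero(length_ok)
            seq_mat = np.array([list(seqs[i]) for i in ok_idx])
            m = np.ones(len(ok_idx), dtype=bool)
            for slot, allowed in enumerate(design.slots):
                m &= np.isin(seq_mat[:, slot], sorted(allowed))
            member[ok_idx] = m

        cat = np.where(~length_ok, "wrong_length", "wrong_sequence")
        nophos = ppos < 0
        cat = np.where(
            member & nophos & untreated, "missing_phospho", cat
        )
        cat = np.where(member & nophos & ~untreated, "correct_dephospho", cat)
        cat = np.where(
            member & ~nophos & (ppos != design.phospho_slot),
            "wrong_phospho_position",
            cat,
        )
        cat = np.where(
            member & ~nophos & (ppos == design.phospho_slot), "correct_phospho", cat
        )
        category[np.asarray(idx)] = cat

        if flag_cross_library:
            others = [d for name, d in designs.items() if name != lib]
            if others:
                wrong_seq = np.asarray(idx)[cat == "wrong_sequence"]
                for i in wrong_seq:
                    s = psms.at[i, "sequence"]
                    cross[i] = any(d.matches_sequence(s) for d in others)

    psms["category"] = category
    psms["cross_library"] = cross
    psms.index = orig_index  # keep row identity for joins with the input
    return psms


@dataclass(frozen=True)
class FdrCurve:
    """FDR as a function of score threshold.

    ``thresholds`` are the distinct observed scores (ascending); at each,
    TP and FP count records with score >= threshold among empirically
    correct and wrong records respectively.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray

    @property
    def fdr(self) -> np.ndarray:
        total = self.tp + self.fp
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.fp / total, np.nan)

    def fdr_at(self, score: float) -> float | None:
        """FDR at an arbitrary threshold (counts of records >= score);
        None when no record survives."""
        i = np.searchsorted(self.thresholds, score, side="left")
        if i >= len(self.thresholds):
            return None
        return float(self.fdr[i])


def fdr_curve(classified: pd.DataFrame, exclude_cross_library: bool = True) -> FdrCurve:
    """FDR-vs-score curve over a set of classified records."""
    if classified.empty:
        raise ValueError("no records")
    df = classified
    if exclude_cross_library and "cross_library" in df.columns:
        df = df[~df["cross_library"]]
    scores = df["score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    correct = df["category"].isin(CORRECT_CATEGORIES).to_numpy()
    order = np.argsort(scores)
    scores, correct = scores[order], correct[order]
    thresholds, first_idx = np.unique(scores, return_index=True)
    # records with score >= threshold = suffix counts from first_idx
    n = len(scores)
    cum_correct = np.concatenate([[0], np.cumsum(correct)])
    tp = cum_correct[n] - cum_correct[first_idx]
    fp = (n - first_idx) - tp
    return FdrCurve(thresholds=thresholds, tp=tp.astype(int), fp=fp.astype(int))


def cutoff_at_fdr(curve: FdrCurve, alpha: float = 0.05) -> float | None:
    """Smallest observed score whose FDR is <= alpha; None if no
    threshold qualifies."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fdr = curve.fdr
    ok = np.flatnonzero(~np.isnan(fdr) & (fdr <= alpha))
    if len(ok) == 0:
        return None
    return float(curve.thresholds[ok[0]])


def apply_filter(
    classified: pd.DataFrame,
    cutoff: float,
    exclude_cross_library: bool = True,
) -> pd.DataFrame:
    """Retain empirically correct records with score >= cutoff (ties at
    the cutoff are retained)."""
    if cutoff is None:
        raise ValueError("cutoff is undefined")
    df = classified
    if exclude_cross_library and "cross_library" in df.columns:
        df = df[~df["cross_library"]]
    keep = df["category"].isin(CORRECT_CATEGORIES) & (df["score"] >= cutoff)
    return df[keep]


def filter_report(
    psms: pd.DataFrame,
    designs: dict[str, LibraryDesign],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (library, treatment) FDR filtering, mirroring sample-specific
    FDR-based cutoffs.

    Returns ``(retained, report)`` where the report lists the threshold,
    TP/FP at that threshold, and retained record / unique-sequence counts
    per (library, treatment).
    """
    classified = classify_table(psms, designs)
    retained_parts: list[pd.DataFrame] = []
    rows = []
    for (lib, treatment), sub in classified.groupby(["library", "treatment"], sort=False):
        curve = fdr_curve(sub)
        cutoff = cutoff_at_fdr(curve, alpha)
        if cutoff is None:
            rows.append(
                {
                    "library": lib,
                    "treatment": treatment,
                    "cutoff": np.nan,
                    "tp": 0,
                    "fp": 0,
                    "fdr": np.nan,
                    "n_records": 0,
                    "n_unique_sequences": 0,
                }
            )
            continue
        kept = apply_filter(sub, cutoff)
        i = int(np.searchsorted(curve.thresholds, cutoff))
        rows.append(
            {
                "library": lib,
                "treatment": treatment,
                "cutoff": cutoff,
                "tp": int(curve.tp[i]),
                "fp": int(curve.fp[i]),
                "fdr": float(curve.fdr[i]),
                "n_records": len(kept),
                "n_unique_sequences": kept["sequence"].nunique(),
            }
        )
        retained_parts.append(kept)
    retained = (
        pd.concat(retained_parts) if retained_parts else classified.iloc[0:0]
    )
    return retained, pd.DataFrame(rows)
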