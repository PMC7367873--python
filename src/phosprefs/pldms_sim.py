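"""Synthetic phosphopeptide-library dephosphorylation + MS identification.

Generates the data the downstream PLDMS analysis consumes: a pool of
library peptides drawn under an isokinetic composition, sequence-dependent
dephosphorylation under first-order kinetics stopped at a target global
conversion (30-50% in the assay this emulates), and a PSM table with
controlled identification errors whose scores form two location-shifted
populations (correct vs erroneous), mimicking search-engine ion scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library_design import IsokineticComposition, LibraryDesign, validate_composition

__all__ = [
    "GroundTruthPeptideModel",
    "IdentificationErrorModel",
    "TreatmentResult",
    "sample_pool",
    "dephos_probability",
    "simulate_treatment",
    "emit_psms",
    "simulate_library_experiment",
    "blind",
]

TREATMENTS = ("untreated", "PP1", "PP2A")

#: truth classes written to the simulation-only column
CORRECT_CLASSES = ("true_phospho", "true_dephospho")


@dataclass(frozen=True)
class GroundTruthPeptideModel:
    """Positional log-rate model for peptide dephosphorylation.

    The first-order rate of a peptide is
    ``k = k0 * exp(sum_i w[(label_i, residue_i)] + tau * 1[pThr])``
    with ``w`` defaulting to 0 for unlisted (position, residue) cells.
    ``tau`` is the log-rate bonus of phosphothreonine over phosphoserine.
    """

    w: dict[tuple[int, str], float] = field(default_factory=dict)
    tau: float = 0.0
    k0: float = 1.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")

    def log_rates(self, sequences: np.ndarray, phospho_slot: int) -> np.ndarray:
        """Vectorized log k for an array of equal-length sequences."""
        seq_mat = np.array([list(s) for s in sequences])
        out = np.full(len(sequences), math.log(self.k0))
        for (label, res), weight in self.w.items():
            slot = label + phospho_slot
            if 0 <= slot < seq_mat.shape[1]:
                out += weight * (seq_mat[:, slot] == res)
        if self.tau:
            out += self.tau * (seq_mat[:, phospho_slot] == "T")
        return out

    def rate(self, sequence: str, phospho_slot: int = 4) -> float:
        return float(np.exp(self.log_rates(np.array([sequence]), phospho_slot))[0])


@dataclass(frozen=True)
class IdentificationErrorModel:
    """Rates and score distributions of erroneous identifications.

    Error classes (rates are per emitted pool record, each class drawn
    independently as extra records):

    - ``rate_wrong_length``: a truncated 9-mer is reported.
    - ``rate_wrong_sequence``: a residue is replaced by one outside the
      design alphabet, so the sequence matches no theoretical peptide.
    - ``rate_wrong_phospho``: the phosphate is localized to a position
      other than the synthesized phospho slot.
    - ``rate_missing_phospho``: a non-phospho record in the untreated
      sample (where no dephosphorylated peptide can exist).
    - ``rate_matching_error``: a mis-assignment that still matches another
      theoretical sequence of the design; invisible to empirical
      classification, it is what limits the realized FDR after filtering.

    Scores are Gaussian: correct identifications at ``score_correct_loc``,
    erroneous ones at the lower ``score_wrong_loc``.
    """

    rate_wrong_length: float = 0.03
    rate_wrong_sequence: float = 0.05
    rate_wrong_phospho: float = 0.10
    rate_missing_phospho: float = 0.05
    rate_matching_error: float = 0.01
    score_correct_loc: float = 45.0
    score_wrong_loc: float = 25.0
    score_scale: float = 8.0
    detection_prob: float = 0.95
    residual_phospho_prob: float = 0.05

    def __post_init__(self) -> None:
        rates = (
            self.rate_wrong_length,
            self.rate_wrong_sequence,
            self.rate_wrong_phospho,
            self.rate_missing_phospho,
            self.rate_matching_error,
        )
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1:
            raise ValueError("error-class rates must be in [0,1] and sum to <= 1")
        if self.score_correct_loc <= self.score_wrong_loc:
            raise ValueError("correct-score location must exceed erroneous location")

    def noiseless(self) -> "IdentificationErrorModel":
        return replace(
            self,
            rate_wrong_length=0.0,
            rate_wrong_sequence=0.0,
            rate_wrong_phospho=0.0,
            rate_missing_phospho=0.0,
            rate_matching_error=0.0,
            detection_prob=1.0,
            residual_phospho_prob=0.0,
        )


@dataclass(frozen=True)
class TreatmentResult:
    """Dephosphorylation outcome of one simulated incubation."""

    flags: np.ndarray  # bool per pool peptide
    t: float  # solved incubation time
    realized_fraction: float


def sample_pool(
    design: LibraryDesign,
    composition: IsokineticComposition,
    n_peptides: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a peptide pool: randomized slots i.i.d. from the composition,
    the phospho residue 50/50 pSer/pThr.

    Returns a frame with columns ``sequence`` and ``phospho_residue``.
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    fractions = validate_composition(composition, design)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    residues = sorted(fractions)
    probs = np.array([fractions[r] for r in residues])
    probs = probs / probs.sum()

    cols: list[np.ndarray] = []
    rand_slots = set(design.randomized_slots())
    for i, allowed in enumerate(design.slots):
        if i == design.phospho_slot:
            phos = sorted(allowed)
            cols.append(rng.choice(phos, size=n_peptides))
        elif i in rand_slots:
            cols.append(rng.choice(residues, size=n_peptides, p=probs))
        else:
            cols.append(np.full(n_peptides, next(iter(allowed))))
    seq_mat = np.stack(cols, axis=1)
    sequences = np.array(["".join(row) for row in seq_mat])
    return pd.DataFrame(
        {
            "sequence": sequences,
            "phospho_residue": seq_mat[:, design.phospho_slot],
        }
    )


def dephos_probability(
    sequence: str | np.ndarray,
    model: GroundTruthPeptideModel,
    t: float,
    phospho_slot: int = 4,
):
    """First-order conversion probability ``p = 1 - exp(-t * k)``."""
    if t < 0:
        raise ValueError("incubation time must be non-negative")
    scalar = isinstance(sequence, str)
    seqs = np.array([sequence]) if scalar else np.asarray(sequence)
    p = 1.0 - np.exp(-t * np.exp(model.log_rates(seqs, phospho_slot)))
    return float(p[0]) if scalar else p


def simulate_treatment(
    pool: pd.DataFrame,
    model: GroundTruthPeptideModel,
    target_fraction: float = 0.4,
    seed: int | np.random.Generator = 0,
    phospho_slot: int = 4,
) -> TreatmentResult:
    """Solve the incubation time so the expected pool-average conversion
    equals *target_fraction*, then draw per-peptide Bernoulli flags.

    Mirrors stopping the reaction once 30-50% of the library is
    dephosphorylated.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = np.exp(model.log_rates(pool["sequence"].to_numpy(), phospho_slot))

    def mean_p(t: float) -> float:
        return float(np.mean(1.0 - np.exp(-t * k)))

    lo, hi = 0.0, 1.0
    while mean_p(hi) < target_fraction:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the target conversion")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    p = 1.0 - np.exp(-t * k)
    flags = rng.random(len(p)) < p
    return TreatmentResult(flags=flags, t=t, realized_fraction=float(flags.mean()))


def _mutate_outside_alphabet(
    sequences: np.ndarray, design: LibraryDesign, rng: np.random.Generator
) -> np.ndarray:
    """Replace one randomized-slot residue by one no slot of the design
    allows, guaranteeing the result matches no theoretical sequence."""
    rand_slots = design.randomized_slots()
    forbidden = sorted(set("ACDEFGHIKLMNPQRSTVWY") - design.randomized_alphabet())
    if not forbidden:  # fully degenerate alphabet; fall back to length error
        return np.array([s[:-1] for s in sequences])
    slots = rng.choice(rand_slots, size=len(sequences))
    subs = rng.choice(forbidden, size=len(sequences))
    out = []
    for s, i, r in zip(sequences, slots, subs):
        out.append(s[:i] + r + s[i + 1 :])
    return np.array(out)


def _mutate_within_alphabet(
    sequences: np.ndarray, design: LibraryDesign, rng: np.random.Generator
) -> np.ndarray:
    """Replace one randomized-slot residue by a different residue of the
    same slot's alphabet: the result is another valid theoretical
    sequence (an undetectable mis-assignment)."""
    rand_slots = design.randomized_slots()
    slots = rng.choice(rand_slots, size=len(sequences))
    out = []
    for s, i in zip(sequences, slots):
        choices = sorted(design.slots[i] - {s[i]})
        out.append(s[:i] + rng.choice(choices) + s[i + 1 :])
    return np.array(out)


def emit_psms(
    pool: pd.DataFrame,
    flags: np.ndarray,
    err: IdentificationErrorModel,
    design: LibraryDesign,
    treatment: str,
    sample: str | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Emit a PSM table for one treated (or untreated) sample.

    Correct records are the phospho form when the peptide survived, and
    the non-phospho form when it was dephosphorylated in a treated sample.
    Erroneous records of each class are appended with scores drawn from
    the (lower) erroneous score distribution.  The ``truth_class`` column
    is simulation-only; drop it with :func:`blind`.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if len(flags) != len(pool):
        raise ValueError("flags not aligned with pool")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sample = sample or f"{design.name}_{treatment}"
    flags = np.asarray(flags, dtype=bool)
    sequences = pool["sequence"].to_numpy()
    n = len(sequences)
    pslot = design.phospho_slot

    frames: list[pd.DataFrame] = []

    def block(seqs, ppos, truth, correct_scores):
        loc = err.score_correct_loc if correct_scores else err.score_wrong_loc
        return pd.DataFrame(
            {
                "sequence": seqs,
                "phospho_position": ppos,
                "score": rng.normal(loc, err.score_scale, size=len(seqs)),
                "library": design.name,
                "sample": sample,
                "treatment": treatment,
                "truth_class": truth,
            }
        )

    detected = rng.random(n) < err.detection_prob
    dephos = flags & (treatment != "untreated")
    phos_seqs = sequences[detected & ~dephos]
    frames.append(block(phos_seqs, pslot, "true_phospho", True))
    deph_seqs = sequences[detected & dephos]
    if len(deph_seqs):
        frames.append(block(deph_seqs, -1, "true_dephospho", True))
        residual = deph_seqs[rng.random(len(deph_seqs)) < err.residual_phospho_prob]
        if len(residual):
            frames.append(block(residual, pslot, "true_phospho", True))

    def n_errors(rate: float) -> int:
        return int(rng.binomial(n, rate)) if rate > 0 else 0

    m = n_errors(err.rate_wrong_length)
    if m:
        src = rng.choice(sequences, size=m)
        frames.append(block(np.array([s[:-1] for s in src]), pslot, "wrong_length", False))
    m = n_errors(err.rate_wrong_sequence)
    if m:
        src = rng.choice(sequences, size=m)
        frames.append(
            block(_mutate_outside_alphabet(src, design, rng), pslot, "wrong_sequence", False)
        )
    m = n_errors(err.rate_wrong_phospho)
    if m:
        src = rng.choice(sequences, size=m)
        other_slots = [i for i in range(design.length) if i != pslot]
        frames.append(
            block(src, rng.choice(other_slots, size=m), "wrong_phospho_position", False)
        )
    if treatment == "untreated":
        m = n_errors(err.rate_missing_phospho)
        if m:
            src = rng.choice(sequences, size=m)
            frames.append(block(src, -1, "missing_phospho", False))
    m = n_errors(err.rate_matching_error)
    if m:
        src = rng.choice(sequences, size=m)
        frames.append(
            block(_mutate_within_alphabet(src, design, rng), pslot, "matching_error", False)
        )

    out = pd.concat(frames, ignore_index=True)
    out["phospho_position"] = out["phospho_position"].astype(int)
    return out


def blind(psms: pd.DataFrame) -> pd.DataFrame:
    """Drop the simulation-only ground-truth column."""
    return psms.drop(columns=["truth_class"], errors="ignore")


def simulate_library_experiment(
    design: LibraryDesign,
    composition: IsokineticComposition,
    model_pp1: GroundTruthPeptideModel,
    model_pp2: GroundTruthPeptideModel,
    n_peptides: int = 100_000,
    target_fraction: float = 0.4,
    err: IdentificationErrorModel | None = None,
    seed: int = 0,
    collapse_species: bool = True,
) -> dict[str, pd.DataFrame]:
    """Full experiment for one library: untreated reference plus PP1 and
    PP2A treatments, all from one seed with deterministic sub-streams.

    With ``collapse_species`` (default) the sampled pool is collapsed to
    unique sequences before treatment: every synthesized sequence is
    present in many copies, and what the readout resolves is whether a
    sequence's dephosphorylated form appears, not the fate of individual
    molecules.  Sampling first and collapsing second still leaves rare
    sequences underrepresented, as in a real synthesis.
    """
    err = err or IdentificationErrorModel()
    root = np.random.SeedSequence(seed)
    s_pool, s_pp1, s_pp2, s_e0, s_e1, s_e2 = [
        np.random.default_rng(s) for s in root.spawn(6)
    ]
    pool = sample_pool(design, composition, n_peptides, s_pool)
    if collapse_species:
        pool = pool.drop_duplicates("sequence", ignore_index=True)
    none_flags = np.zeros(len(pool), dtype=bool)
    out = {
        "untreated": emit_psms(pool, none_flags, err, design, "untreated", seed=s_e0)
    }
    for treatment, model, s_t, s_e in (
        ("PP1", model_pp1, s_pp1, s_e1),
        ("PP2A", model_pp2, s_pp2, s_e2),
    ):
        res = simulate_treatment(pool, model, target_fraction, s_t)
        out[treatment] = emit_psms(pool, res.flags, err, design, treatment, seed=s_e)
    return out
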