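"""Randomized phosphopeptide library designs and isokinetic compositions.

A library design describes a 10-mer peptide template with a single
phosphorylated Ser/Thr at "position 0" (the fifth residue), flanking
positions labelled -4..-1 and +1..+5, and a subset of positions randomized
over a design alphabet.  The module enumerates the theoretical peptide
space of a design, deduplicates unions of designs, and validates the
isokinetic amino-acid mixtures used to achieve near-uniform incorporation
at the randomized positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pt_mass

__all__ = [
    "STANDARD_RESIDUES",
    "LibraryDesign",
    "IsokineticComposition",
    "PeptideForm",
    "enumerate_library",
    "union_unique",
    "alphabet_overlap",
    "expected_uniform_fraction",
    "monoisotopic_mass",
    "validate_composition",
    "builtin_designs",
    "builtin_compositions",
    "design_from_dict",
    "export_tsv",
    "export_fasta",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: monoisotopic mass of HPO3, the mass shift of a phosphorylated residue
PHOSPHO_MASS = 79.96633

# x1 alphabet: the 14 residues randomized in the N-terminal libraries.
# Leu was chosen over Ile to avoid isobaric ambiguity in database search.
X1_ALPHABET = frozenset("AEFGHKLPQRSTVY")
# x2 alphabet: the 14 residues randomized in the C-terminal library.
X2_ALPHABET = frozenset("ADEFGKLNPQRSTV")


class InvalidDesignError(ValueError):
    """Raised when a library design violates its structural invariants."""


@dataclass(frozen=True)
class LibraryDesign:
    """A 10-slot phosphopeptide library template.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"x1_1"``.
    slots:
        Ten entries; each is a frozenset of allowed residues.  A fixed
        position is a singleton set.  The phospho slot lists the permitted
        unmodified residues (S and/or T).
    phospho_slot:
        0-based index of the phosphorylated position (4 in all built-in
        designs, displayed as "position 0").
    """

    name: str
    slots: tuple[frozenset[str], ...]
    phospho_slot: int = 4

    def __post_init__(self) -> None:
        if len(self.slots) != 10:
            raise InvalidDesignError(
                f"{self.name}: expected 10 slots, got {len(self.slots)}"
            )
        if not 0 <= self.phospho_slot < 10:
            raise InvalidDesignError(f"{self.name}: phospho slot out of range")
        for i, s in enumerate(self.slots):
            if not s:
                raise InvalidDesignError(f"{self.name}: slot {i} has no residues")
            if i == self.phospho_slot:
                if not s <= {"S", "T"}:
                    raise InvalidDesignError(
                        f"{self.name}: phospho slot residues must be within {{S,T}}"
                    )
            elif not s <= STANDARD_RESIDUES:
                raise InvalidDesignError(
                    f"{self.name}: slot {i} contains non-standard residues"
                )

    @property
    def phospho_residues(self) -> frozenset[str]:
        return self.slots[self.phospho_slot]

    @property
    def length(self) -> int:
        return len(self.slots)

    def position_label(self, slot: int) -> int:
        """Signed position label relative to the phospho slot (0)."""
        return slot - self.phospho_slot

    def slot_of_label(self, label: int) -> int:
        return label + self.phospho_slot

    def randomized_slots(self) -> tuple[int, ...]:
        """Indices of slots with more than one allowed residue, excluding
        the phospho slot (its S/T variation is a phospho-residue choice,
        not a sequence randomization)."""
        return tuple(
            i
            for i, s in enumerate(self.slots)
            if i != self.phospho_slot and len(s) > 1
        )

    def randomized_alphabet(self) -> frozenset[str]:
        out: set[str] = set()
        for i in self.randomized_slots():
            out |= self.slots[i]
        return frozenset(out)

    def n_theoretical(self) -> int:
        """Number of theoretical phosphopeptides: product of slot
        cardinalities (the phospho slot contributing |{S,T} subset|)."""
        n = 1
        for s in self.slots:
            n *= len(s)
        return n

    def matches_sequence(self, sequence: str) -> bool:
        """True if *sequence* is a member of this design's theoretical space."""
        if len(sequence) != self.length:
            return False
        return all(res in allowed for res, allowed in zip(sequence, self.slots))


@dataclass(frozen=True)
class PeptideForm:
    """One theoretical peptide, phosphorylated or not."""

    sequence: str
    phosphorylated: bool = True
    phospho_position: int | None = 4
    source_designs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.phosphorylated:
            if self.phospho_position is None:
                raise ValueError("phosphorylated form requires a phospho position")
            if not 0 <= self.phospho_position < len(self.sequence):
                raise ValueError("phospho position outside sequence")
            if self.sequence[self.phospho_position] not in "ST":
                raise ValueError(
                    "phosphorylated residue must be S or T, got "
                    f"{self.sequence[self.phospho_position]!r}"
                )

    @property
    def phospho_residue(self) -> str | None:
        if self.phospho_position is None:
            return None
        return self.sequence[self.phospho_position]

    def key(self) -> tuple[str, int | None]:
        """Identity for deduplication: (sequence, phospho position)."""
        return (self.sequence, self.phospho_position if self.phosphorylated else None)

    def dephosphorylated(self) -> "PeptideForm":
        return PeptideForm(
            self.sequence, False, None, source_designs=self.source_designs
        )


@dataclass(frozen=True)
class IsokineticComposition:
    """Mol-percent of each residue in an isokinetic coupling mixture."""

    name: str
    percents: Mapping[str, float]

    def residues(self) -> frozenset[str]:
        return frozenset(self.percents)

    def total(self) -> float:
        return float(sum(self.percents.values()))


def enumerate_library(design: LibraryDesign) -> list[PeptideForm]:
    """All theoretical phosphorylated forms of a design.

    The result has exactly ``design.n_theoretical()`` elements: the
    Cartesian product over slot alternatives, with S/T variation at the
    phospho slot counted as distinct phosphopeptides.
    """
    alternatives = [sorted(s) for s in design.slots]
    src = frozenset([design.name])
    return [
        PeptideForm("".join(combo), True, design.phospho_slot, src)
        for combo in itertools.product(*alternatives)
    ]


def union_unique(designs: Sequence[LibraryDesign]) -> tuple[int, dict[tuple[str, int | None], PeptideForm]]:
    """Deduplicated union of several enumerated designs.

    Forms are keyed on (sequence, phospho position); a form shared between
    designs is retained once with the union of its source design names.
    Returns ``(count, {key: form})``.
    """
    if not designs:
        raise ValueError("need at least one design")
    merged: dict[tuple[str, int | None], PeptideForm] = {}
    for design in designs:
        for form in enumerate_library(design):
            key = form.key()
            prev = merged.get(key)
            if prev is None:
                merged[key] = form
            else:
                merged[key] = PeptideForm(
                    form.sequence,
                    form.phosphorylated,
                    form.phospho_position,
                    prev.source_designs | form.source_designs,
                )
    return len(merged), merged


def alphabet_overlap(
    a: LibraryDesign, b: LibraryDesign
) -> tuple[int, frozenset[str], frozenset[str]]:
    """Shared / unique randomized-alphabet residues of two designs."""
    aa, bb = a.randomized_alphabet(), b.randomized_alphabet()
    if not aa or not bb:
        raise InvalidDesignError("both designs must have randomized slots")
    return len(aa & bb), aa - bb, bb - aa


def expected_uniform_fraction(
    design: LibraryDesign, slot: int, rounded: bool = True, allow_fixed: bool = False
) -> float:
    """Percent per residue expected at a randomized slot under perfectly
    uniform incorporation (100 / alphabet size; 7% for the 14-residue
    alphabets).  ``rounded`` applies half-up integer rounding as used in
    reporting; ``allow_fixed`` permits single-residue slots (100%)."""
    if slot == design.phospho_slot:
        raise ValueError("the phospho slot is not a randomized position")
    if len(design.slots[slot]) < 2 and not allow_fixed:
        raise ValueError(f"slot {slot} is not a randomized position")
    pct = 100.0 / len(design.slots[slot])
    if rounded:
        import math

        return float(math.floor(pct + 0.5))
    return pct


def monoisotopic_mass(form: PeptideForm) -> float:
    """Monoisotopic mass in Da: residue masses + water, + HPO3 if
    phosphorylated."""
    if not form.sequence:
        raise ValueError("empty sequence")
    total = 0.0
    for res in form.sequence:
        if res not in _pt_mass.std_aa_mass or res not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {res!r}")
        total += _pt_mass.std_aa_mass[res]
    total += _pt_mass.calculate_mass(formula="H2O")
    if form.phosphorylated:
        total += _pt_mass.calculate_mass(formula="HPO3")
    return total


def distinct_masses(forms: Iterable[PeptideForm], decimals: int = 4) -> int:
    """Number of distinct monoisotopic masses among forms, after rounding."""
    return len({round(monoisotopic_mass(f), decimals) for f in forms})


def validate_composition(
    comp: IsokineticComposition,
    design: LibraryDesign | None = None,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Validate a mixture and return mol fractions summing to 1.

    Checks: all entries non-negative, percentages sum to 100 within *tol*,
    and (when a design is given) the residue set equals the design's
    randomized alphabet.
    """
    for res, pct in comp.percents.items():
        if res not in STANDARD_RESIDUES:
            raise ValueError(f"{comp.name}: unknown residue {res!r}")
        if pct < 0:
            raise ValueError(f"{comp.name}: negative percentage for {res}")
    total = comp.total()
    if abs(total - 100.0) > tol:
        raise ValueError(f"{comp.name}: percentages sum to {total}, expected 100")
    if design is not None and comp.residues() != design.randomized_alphabet():
        raise ValueError(
            f"{comp.name}: residue set does not match the randomized alphabet "
            f"of design {design.name}"
        )
    return {res: pct / total for res, pct in comp.percents.items()}


def _nterm_design(name: str, fixed_label: int) -> LibraryDesign:
    """One N-terminal library: Ala fixed at one of -4..-1, the other three
    N-terminal positions randomized over the x1 alphabet, then pS/pT and
    the AAAAK C-terminus."""
    slots: list[frozenset[str]] = []
    for label in (-4, -3, -2, -1):
        slots.append(frozenset("A") if label == fixed_label else X1_ALPHABET)
    slots.append(frozenset("ST"))
    slots.extend([frozenset("A")] * 4)
    slots.append(frozenset("K"))
    return LibraryDesign(name, tuple(slots), phospho_slot=4)


def _cterm_design() -> LibraryDesign:
    """The C-terminal library: AAAA N-terminus, pS/pT, +1..+3 randomized
    over the x2 alphabet, then Ala-Lys."""
    slots: list[frozenset[str]] = [frozenset("A")] * 4
    slots.append(frozenset("ST"))
    slots.extend([X2_ALPHABET] * 3)
    slots.append(frozenset("A"))
    slots.append(frozenset("K"))
    return LibraryDesign("Cterm", tuple(slots), phospho_slot=4)


def builtin_designs() -> dict[str, LibraryDesign]:
    """The five built-in designs: x1_1..x1_4 (Ala fixed at -4, -3, -2, -1
    respectively) and Cterm."""
    out = {
        "x1_1": _nterm_design("x1_1", -4),
        "x1_2": _nterm_design("x1_2", -3),
        "x1_3": _nterm_design("x1_3", -2),
        "x1_4": _nterm_design("x1_4", -1),
    }
    out["Cterm"] = _cterm_design()
    return out


# Optimized isokinetic mixtures (mol %), one per design alphabet class.
X1_COMPOSITION = IsokineticComposition(
    "x1",
    {
        "A": 4.6, "R": 6.8, "E": 7.4, "Q": 11.0, "G": 9.9, "H": 4.8,
        "L": 3.4, "K": 8.6, "F": 3.4, "P": 5.9, "S": 7.6, "T": 13.2,
        "Y": 5.6, "V": 7.8,
    },
)
X2_COMPOSITION = IsokineticComposition(
    "x2",
    {
        "A": 4.3, "R": 6.3, "N": 10.2, "D": 6.8, "E": 6.8, "Q": 10.2,
        "G": 9.2, "L": 3.1, "K": 8.0, "F": 3.1, "P": 5.5, "S": 7.0,
        "T": 12.3, "V": 7.2,
    },
)


def builtin_compositions() -> dict[str, IsokineticComposition]:
    return {"x1": X1_COMPOSITION, "x2": X2_COMPOSITION}


def design_from_dict(spec: Mapping) -> LibraryDesign:
    """Build a design from a declarative mapping (e.g. parsed YAML).

    Expected keys: ``name``, ``phospho_slot`` (default 4), and ``slots`` —
    a list of 10 strings, each listing the allowed residues of a slot.
    """
    slots = tuple(frozenset(str(s)) for s in spec["slots"])
    return LibraryDesign(
        str(spec["name"]), slots, phospho_slot=int(spec.get("phospho_slot", 4))
    )


def load_designs(path) -> dict[str, LibraryDesign]:
    """Read designs from a YAML file: a list of design mappings."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    designs = [design_from_dict(d) for d in raw]
    return {d.name: d for d in designs}


def export_tsv(forms: Iterable[PeptideForm], path) -> None:
    """Write enumerated forms as TSV: sequence, phospho_position,
    phospho_residue, source_design."""
    with open(path, "w") as fh:
        fh.write("sequence\tphospho_position\tphospho_residue\tsource_design\n")
        for f in forms:
            pos = f.phospho_position if f.phosphorylated else -1
            res = f.phospho_residue or "-"
            src = ";".join(sorted(f.source_designs))
            fh.write(f"{f.sequence}\t{pos}\t{res}\t{src}\n")


def export_fasta(forms: Iterable[PeptideForm], path) -> None:
    """Write forms as FASTA; the phospho position is encoded in the header
    (``pos=-1`` marks a non-phosphorylated form)."""
    with open(path, "w") as fh:
        for i, f in enumerate(forms):
            pos = f.phospho_position if f.phosphorylated else -1
            src = ";".join(sorted(f.source_designs)) or "na"
            fh.write(f">form{i}|phospho_pos={pos}|src={src}\n{f.sequence}\n")
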