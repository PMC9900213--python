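"""Core domain types shared by every pipeline stage.

Coordinates are 0-based and half-open everywhere inside the package;
file readers convert from 1-based inclusive conventions at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted in sequences; 'X' marks an unknown residue
SEQUENCE_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
#: peptide windows additionally allow '-' as a terminal pad
PEPTIDE_ALPHABET = SEQUENCE_ALPHABET | {"-"}

PHOSPHOACCEPTORS = frozenset("STY")

#: in-string marker for a residue hidden by the kinase-masking augmentation;
#: maps to the <mask> vocabulary token at encoding time
MASK_CHAR = "#"

WINDOW_SIZE = 11
WINDOW_FLANK = 5  # residues on each side of the phosphoacceptor


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


def _check_sequence(seq: str, *, what: str) -> None:
    if not seq:
        raise ValidationError(f"{what}: sequence is empty")
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ValidationError(
            f"{what}: illegal residue letter(s) {sorted(bad)!r}; "
            f"allowed are the 20 amino acids plus 'X'"
        )


@dataclass(frozen=True)
class KinaseRecord:
    """A kinase with its catalytic-domain interval inside the full sequence."""

    kinase_id: str
    full_sequence: str
    domain_start: int
    domain_end: int
    gene: str = ""
    family: str = ""
    group: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        _check_sequence(self.full_sequence, what=f"kinase {self.kinase_id}")
        if not (0 <= self.domain_start < self.domain_end <= len(self.full_sequence)):
            raise ValidationError(
                f"kinase {self.kinase_id}: domain interval "
                f"[{self.domain_start}, {self.domain_end}) invalid for sequence of "
                f"length {len(self.full_sequence)}"
            )

    @property
    def domain_sequence(self) -> str:
        return self.full_sequence[self.domain_start : self.domain_end]


@dataclass(frozen=True)
class SubstrateRecord:
    """A full-length substrate protein."""

    substrate_id: str
    sequence: str
    organism: str = ""

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, what=f"substrate {self.substrate_id}")


@dataclass(frozen=True)
class PeptideWindow:
    """An 11-mer around a candidate phosphosite, '-'-padded at termini.

    ``site_position`` is the 0-based index of the center residue within the
    source protein.
    """

    residues: str
    source_substrate_id: str
    site_position: int

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_SIZE:
            raise ValidationError(
                f"peptide window must have length {WINDOW_SIZE}, "
                f"got {len(self.residues)} ({self.residues!r})"
            )
        bad = set(self.residues) - PEPTIDE_ALPHABET
        if bad:
            raise ValidationError(f"peptide window {self.residues!r}: illegal letters {sorted(bad)!r}")
        if self.residues[WINDOW_FLANK] not in PHOSPHOACCEPTORS:
            raise ValidationError(
                f"peptide window {self.residues!r}: center residue "
                f"{self.residues[WINDOW_FLANK]!r} is not S/T/Y"
            )
        core = self.residues.strip("-")
        if "-" in core:
            raise ValidationError(
                f"peptide window {self.residues!r}: '-' pads may only appear at the termini"
            )


class PairLabel(str, Enum):
    POSITIVE = "positive"
    HARD_NEGATIVE = "hard_negative"
    EASY_NEGATIVE = "easy_negative"


@dataclass(frozen=True)
class LabeledPair:
    """A (kinase, peptide) example with its curation label."""

    kinase_id: str
    peptide: PeptideWindow
    label: PairLabel


@dataclass
class AnnotationRow:
    kinase_id: str
    substrate_id: str
    site_position: int  # 0-based internally
    residue: str


@dataclass
class PhosphoAnnotationTable:
    """Validated kinase-specific phosphosite annotations.

    Only rows whose stated residue matches the substrate sequence at the
    stated position are kept; the rest are counted in ``n_rejected`` and
    listed in ``rejection_report``.
    """

    rows: list[AnnotationRow] = field(default_factory=list)
    n_rejected: int = 0
    rejection_report: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def kinase_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.kinase_id, None)
        return list(seen)

    def sites(self) -> set[tuple[str, int]]:
        return {(r.substrate_id, r.site_position) for r in self.rows}


def validate_annotation_rows(
    rows: Iterable[AnnotationRow], substrates: Iterable[SubstrateRecord]
) -> PhosphoAnnotationTable:
    """Keep rows whose residue letter matches the substrate at that site.

    Mirrors the cross-referencing verification applied when site tables from
    several databases are merged: disagreeing rows are dropped and reported,
    never silently corrected.
    """
    by_id = {s.substrate_id: s for s in substrates}
    table = PhosphoAnnotationTable()
    for row in rows:
        sub = by_id.get(row.substrate_id)
        if sub is None:
            table.n_rejected += 1
            table.rejection_report.append(
                f"{row.kinase_id}\t{row.substrate_id}\t{row.site_position}: unknown substrate id"
            )
            continue
        if not (0 <= row.site_position < len(sub.sequence)):
            table.n_rejected += 1
            table.rejection_report.append(
                f"{row.kinase_id}\t{row.substrate_id}\t{row.site_position}: position out of range"
            )
            continue
        actual = sub.sequence[row.site_position]
        if actual != row.residue or actual not in PHOSPHOACCEPTORS:
            table.n_rejected += 1
            table.rejection_report.append(
                f"{row.kinase_id}\t{row.substrate_id}\t{row.site_position}: "
                f"stated {row.residue!r}, sequence has {actual!r}"
            )
            continue
        table.rows.append(row)
    return table
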