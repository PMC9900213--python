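"""Readers and writers for the FASTA/TSV formats the pipeline touches.

All tabular site coordinates on disk are 1-based inclusive (the convention
of most published site tables) unless a file is written by this package
with a ``# coords: 0-based`` header line; internally everything is 0-based
half-open.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .records import (
    AnnotationRow,
    KinaseRecord,
    LabeledPair,
    PairLabel,
    PeptideWindow,
    PhosphoAnnotationTable,
    SubstrateRecord,
    ValidationError,
    validate_annotation_rows,
)

ZERO_BASED_HEADER = "# coords: 0-based half-open"


class FastaParseError(ValueError):
    pass


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    entries = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append((rec.id, str(rec.seq).upper()))
    except (ValueError, FileNotFoundError) as exc:  # pragma: no cover - passthrough
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    if not entries:
        raise FastaParseError(f"no FASTA records found in {path}")
    return entries


def read_kinase_fasta(
    path: str | Path,
    coords: Mapping[str, tuple[int, int]] | None = None,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
) -> list[KinaseRecord]:
    """Read kinases from FASTA, attaching domain intervals when given.

    ``coords`` maps kinase id -> (domain_start, domain_end), 0-based
    half-open. Without coordinates the whole sequence is taken as the
    domain. ``metadata`` may carry gene/family/group/organism per id.
    """
    entries = _parse_fasta(path)
    ids = {name for name, _ in entries}
    if coords:
        missing = sorted(set(coords) - ids)
        if missing:
            raise ValidationError(
                f"coordinate table references ids absent from FASTA: {missing}"
            )
    records = []
    for name, seq in entries:
        start, end = (coords or {}).get(name, (0, len(seq)))
        meta = (metadata or {}).get(name, {})
        try:
            records.append(
                KinaseRecord(
                    kinase_id=name,
                    full_sequence=seq,
                    domain_start=start,
                    domain_end=end,
                    gene=meta.get("gene", ""),
                    family=meta.get("family", ""),
                    group=meta.get("group", ""),
                    organism=meta.get("organism", ""),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"record {name!r}: {exc}") from exc
    return records


def read_substrate_fasta(path: str | Path) -> list[SubstrateRecord]:
    return [SubstrateRecord(substrate_id=name, sequence=seq) for name, seq in _parse_fasta(path)]


def read_domain_coords(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a kinase_id/start/end TSV of domain intervals.

    1-based inclusive by default; a leading ``# coords: 0-based half-open``
    line switches to the internal convention verbatim.
    """
    text = Path(path).read_text()
    zero_based = text.startswith(ZERO_BASED_HEADER)
    df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#", dtype={"kinase_id": str})
    coords = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if not zero_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        coords[str(row.kinase_id)] = (start, end)
    return coords


def read_kinase_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Optional per-kinase gene/family/group/organism TSV keyed by kinase_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    meta: dict[str, dict[str, str]] = {}
    for row in df.to_dict("records"):
        kid = row.pop("kinase_id")
        meta[kid] = row
    return meta


def read_annotation_table(
    path: str | Path, substrates: Sequence[SubstrateRecord]
) -> PhosphoAnnotationTable:
    """Read and validate a kinase-specific phosphosite TSV.

    Columns: kinase_id, substrate_id, site_position, residue. Positions are
    1-based on disk unless the file carries the 0-based header. Rows whose
    residue disagrees with the substrate sequence (or reference an unknown
    substrate) are rejected with a report, not corrected.
    """
    text = Path(path).read_text()
    zero_based = text.startswith(ZERO_BASED_HEADER)
    df = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        comment="#",
        dtype={"kinase_id": str, "substrate_id": str, "residue": str},
    )
    offset = 0 if zero_based else 1
    rows = [
        AnnotationRow(
            kinase_id=str(r.kinase_id),
            substrate_id=str(r.substrate_id),
            site_position=int(r.site_position) - offset,
            residue=str(r.residue),
        )
        for r in df.itertuples(index=False)
    ]
    return validate_annotation_rows(rows, substrates)


def write_annotation_table(table: PhosphoAnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(ZERO_BASED_HEADER + "\n")
        fh.write("kinase_id\tsubstrate_id\tsite_position\tresidue\n")
        for r in table.rows:
            fh.write(f"{r.kinase_id}\t{r.substrate_id}\t{r.site_position}\t{r.residue}\n")


PAIR_COLUMNS = ["kinase_id", "peptide", "label", "substrate_id", "site_position"]


def write_pairs_tsv(pairs: Sequence[LabeledPair], path: str | Path) -> None:
    if not pairs:
        raise ValueError("refusing to write an empty pair list")
    with open(path, "w") as fh:
        fh.write(ZERO_BASED_HEADER + "\n")
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.kinase_id}\t{p.peptide.residues}\t{p.label.value}\t"
                f"{p.peptide.source_substrate_id}\t{p.peptide.site_position}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[LabeledPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("kinase_id\t"):
                continue
            kid, residues, label, sid, pos = line.rstrip("\n").split("\t")
            pairs.append(
                LabeledPair(
                    kinase_id=kid,
                    peptide=PeptideWindow(
                        residues=residues, source_substrate_id=sid, site_position=int(pos)
                    ),
                    label=PairLabel(label),
                )
            )
    return pairs


def write_fasta(records: Iterable[KinaseRecord | SubstrateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, KinaseRecord):
                fh.write(f">{rec.kinase_id}\n{rec.full_sequence}\n")
            else:
                fh.write(f">{rec.substrate_id}\n{rec.sequence}\n")


def write_domain_coords(records: Iterable[KinaseRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(ZERO_BASED_HEADER + "\n")
        fh.write("kinase_id\tstart\tend\n")
        for rec in records:
            fh.write(f"{rec.kinase_id}\t{rec.domain_start}\t{rec.domain_end}\n")


def write_kinase_metadata(records: Iterable[KinaseRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kinase_id\tgene\tfamily\tgroup\torganism\n")
        for rec in records:
            fh.write(f"{rec.kinase_id}\t{rec.gene}\t{rec.family}\t{rec.group}\t{rec.organism}\n")
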