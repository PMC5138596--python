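"""Protein sequence and label I/O.

Defines the canonical 20-letter amino-acid alphabet and its fixed ordering
(A, C, D, ..., Y), which every feature module indexes against, plus FASTA
reading/writing with explicit policies for non-canonical residues and a
two-class label table joining positive (R-gene) and negative sets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Alphabet:
    """The canonical amino-acid alphabet in its fixed, immutable ordering."""

    RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
    INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(RESIDUES)}
    SIZE: int = 20

    #: Wildcard standing for "unknown residue": excluded from all feature
    #: counts; composition denominators still use the full sequence length.
    WILDCARD: str = "X"

    @classmethod
    def is_canonical(cls, residue: str) -> bool:
        return residue in cls.INDEX


#: Residues that occur in real UniProt entries but are outside the canonical
#: alphabet: ambiguity codes, rare residues, stop marks and gap characters.
NON_CANONICAL = set("BJOUZ*-.")

POSITIVE_LABEL = "R-gene"
NEGATIVE_LABEL = "non-R-gene"


class SanitizePolicy(str, enum.Enum):
    """What to do with non-canonical residues on read."""

    STRICT = "strict"          # any non-canonical residue is an error
    DROP_RECORD = "drop_record"  # exclude the whole record, count it
    MAP_TO_X = "map_to_x"      # replace by the wildcard 'X'


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; names the offending line."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence, the unit of every pipeline stage."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = {c for c in self.sequence if not (Alphabet.is_canonical(c) or c == Alphabet.WILDCARD)}
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical residue(s) {sorted(bad)}; "
                "sanitize on read"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LabelTable:
    """Mapping record id -> class label (positive R-gene / negative)."""

    labels: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, record_id: str) -> str:
        return self.labels[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.labels

    def is_positive(self, record_id: str) -> bool:
        return self.labels[record_id] == POSITIVE_LABEL

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tlabel\n")
            for rid, lab in self.labels.items():
                fh.write(f"{rid}\t{lab}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabelTable":
        labels: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("id\t"):
                raise ValueError(f"{path}: expected headered 2-column TSV (id, label)")
            for line in fh:
                if not line.strip():
                    continue
                rid, lab = line.rstrip("\n").split("\t")
                if rid in labels:
                    raise ValueError(f"{path}: duplicate id {rid!r}")
                labels[rid] = lab
        return cls(labels)


def _sanitize(seq: str, policy: SanitizePolicy, record_id: str) -> str | None:
    """Return a sanitized upper-case sequence, None if the record is dropped."""
    seq = seq.upper()
    bad = sorted({c for c in seq if not Alphabet.is_canonical(c)})
    if not bad:
        return seq
    if policy is SanitizePolicy.STRICT:
        raise ValueError(
            f"record {record_id!r}: non-canonical residue {bad[0]!r} under strict policy"
        )
    if policy is SanitizePolicy.DROP_RECORD:
        return None
    return "".join(c if Alphabet.is_canonical(c) else Alphabet.WILDCARD for c in seq)


def read_fasta(
    path: str | Path,
    sanitize_policy: SanitizePolicy | str = SanitizePolicy.MAP_TO_X,
) -> list[ProteinRecord]:
    """Read protein records from a FASTA file, in file order.

    Parameters
    ----------
    path
        FASTA file; records may be wrapped at any width.
    sanitize_policy
        How non-canonical residues (B, J, O, U, X treated as already-wildcard,
        Z, ``*``, gaps) are handled: ``strict`` raises, ``drop_record``
        silently excludes offending records, ``map_to_x`` (default) replaces
        each offending residue with the wildcard ``X``.

    Raises
    ------
    FastaFormatError
        If the file is empty, contains sequence data before the first header
        (the error names the line number), or has duplicate record ids.
    """
    policy = SanitizePolicy(sanitize_policy)
    path = Path(path)
    _check_fasta_shape(path)

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = _sanitize(str(rec.seq), policy, rec.id)
        if seq is None:
            continue
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def _check_fasta_shape(path: Path) -> None:
    """Pre-scan for structural FASTA errors with line numbers."""
    saw_header = False
    saw_any = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            saw_any = True
            if stripped.startswith(">"):
                saw_header = True
            elif not saw_header:
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before the first '>' header"
                )
    if not saw_any:
        raise FastaFormatError(f"{path}: empty FASTA file")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as canonical FASTA, sequences wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def _ids_from_file(path: Path) -> list[str]:
    """Record ids from a FASTA file, or one id per line for plain lists."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        ids = []
        with open(path) as fh:
            for line in fh:
                if line.startswith(">"):
                    ids.append(line[1:].split()[0])
        return ids
    ids = []
    with open(path) as fh:
        for line in fh:
            token = line.split("\t")[0].strip()
            if token and token != "id":
                ids.append(token)
    return ids


def load_labels(pos_path: str | Path, neg_path: str | Path) -> LabelTable:
    """Build the union label table from a positive and a negative set.

    Each path may be a FASTA file or a plain id list (one per line).
    An id present in both files is a conflict and raises.
    """
    pos_ids = _ids_from_file(Path(pos_path))
    neg_ids = _ids_from_file(Path(neg_path))

    labels: dict[str, str] = {}
    for ids, label, origin in ((pos_ids, POSITIVE_LABEL, pos_path), (neg_ids, NEGATIVE_LABEL, neg_path)):
        for rid in ids:
            if rid in labels:
                if labels[rid] != label:
                    raise ValueError(f"id {rid!r} appears in both positive and negative sets")
                raise ValueError(f"{origin}: duplicate id {rid!r}")
            labels[rid] = label
    return LabelTable(labels)
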