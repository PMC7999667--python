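"""Sequence input/output and alphabet validation.

Every other module consumes the two record types defined here. Sequences
are restricted to the 20 canonical one-letter amino-acid codes; ambiguous
codes (B, J, O, U, X, Z) and gaps are rejected by default because the
PseAAC property scales are only defined for the canonical residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


class SequenceValidationError(ValueError):
    """A sequence contains a symbol outside the canonical 20-letter alphabet."""


class FastaParseError(ValueError):
    """The FASTA file is structurally malformed."""


def validate_sequence(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase ``sequence`` and verify it uses only canonical residues.

    Raises :class:`SequenceValidationError` naming the offending position
    (1-based) and symbol. An empty sequence is also rejected.
    """
    seq = sequence.upper()
    if not seq:
        raise SequenceValidationError(f"{context}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _CANONICAL_SET:
            raise SequenceValidationError(
                f"{context}: non-canonical residue {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A short amino-acid sequence used as a training instance or k-mer."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, context=self.id or "peptide"))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein, e.g. one UniProt entry."""

    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence, context=self.accession))

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(
    path: Union[str, Path],
    *,
    on_invalid: str = "reject",
) -> list[ProteinRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file of proteins.

    The header token before the first whitespace becomes the accession and
    the remainder the name. Sequences are uppercased. File order is kept.

    Parameters
    ----------
    on_invalid:
        ``"reject"`` (default) raises on any non-canonical residue;
        ``"drop"`` skips the offending record with a warning.
    """
    if on_invalid not in ("reject", "drop"):
        raise ValueError(f"on_invalid must be 'reject' or 'drop', got {on_invalid!r}")
    path = Path(path)
    _check_fasta_shape(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        name = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(ProteinRecord(accession=accession, name=name, sequence=str(rec.seq)))
        except SequenceValidationError:
            if on_invalid == "reject":
                raise
            logger.warning("dropping record %s: non-canonical residue", accession)
    return records


def _check_fasta_shape(path: Path) -> None:
    # Biopython silently ignores text before the first '>'; we treat it as
    # a structural error so truncated files are caught early.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(f"{path}: sequence data before any FASTA header at line {lineno}")
            return


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path], *, width: int = 60) -> None:
    """Write protein records to FASTA; round-trips accessions and sequences."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.name) for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_peptide_list(path: Union[str, Path]) -> tuple[list[Peptide], int]:
    """Read a peptide list; returns ``(peptides, n_duplicates_removed)``.

    Two dialects are auto-detected from the first non-empty line: plain
    one-sequence-per-line, or two-column ``id<TAB>sequence`` TSV. Duplicate
    sequences are collapsed to their first occurrence, mirroring how
    curated positive sets keep each peptide sequence once.
    """
    path = Path(path)
    lines: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line.strip():
                lines.append((lineno, line))
    if not lines:
        return [], 0
    tsv = "\t" in lines[0][1]
    peptides: list[Peptide] = []
    seen: set[str] = set()
    n_dup = 0
    for lineno, line in lines:
        if tsv:
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>sequence'")
            pid, seq = parts[0].strip(), parts[1].strip()
        else:
            pid, seq = f"pep{len(peptides) + n_dup + 1}", line.strip()
        try:
            pep = Peptide(id=pid, sequence=seq)
        except SequenceValidationError as exc:
            raise SequenceValidationError(f"{path}: line {lineno}: {exc}") from exc
        if pep.sequence in seen:
            n_dup += 1
            continue
        seen.add(pep.sequence)
        peptides.append(pep)
    if n_dup:
        logger.info("read_peptide_list: removed %d duplicate sequence(s)", n_dup)
    return peptides, n_dup
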