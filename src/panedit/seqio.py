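"""Sequence I/O and validated CDS / protein records.

Mitochondrial coding sequences are stored in the RNA alphabet (any T on
input is normalised to U, since the same analysis is applied to maxicircle
genes and to edited mRNAs) together with the metadata every downstream
stage needs: species, gene, reading-frame offset and editing status.
Codon-position indexing lives here because walks, composition tests and
editing inference all share it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = set("ACGUN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class EditingStatus(str, Enum):
    PAN_EDITED = "pan_edited"
    PARTIALLY_EDITED = "partially_edited"
    NONEDITED = "nonedited"
    UNKNOWN = "unknown"


class SequenceValidationError(ValueError):
    """Raised when a record contains characters outside its alphabet."""


class FastaParseError(ValueError):
    """Raised on structurally malformed FASTA input."""


@dataclass
class CdsRecord:
    """One coding sequence (RNA alphabet) with its provenance labels.

    ``frame_offset`` is the 0-based index of the first codon's first base;
    codon-position indexing only uses positions >= frame_offset.
    """

    id: str
    seq: str
    species: str = "unknown"
    gene: str = "unknown"
    editing_status: EditingStatus = EditingStatus.UNKNOWN
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        bad = [(i, c) for i, c in enumerate(self.seq) if c not in RNA_ALPHABET]
        if bad:
            i, c = bad[0]
            raise SequenceValidationError(
                f"record {self.id!r}: illegal character {c!r} at position {i + 1}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise SequenceValidationError(
                f"record {self.id!r}: frame_offset must be 0-2, got {self.frame_offset}"
            )
        if isinstance(self.editing_status, str):
            self.editing_status = EditingStatus(self.editing_status)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An amino acid sequence over the 20-letter alphabet plus X."""

    id: str
    seq: str
    source_cds_id: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise SequenceValidationError(f"record {self.id!r}: empty protein sequence")
        bad = [(i, c) for i, c in enumerate(self.seq) if c not in PROTEIN_ALPHABET]
        if bad:
            i, c = bad[0]
            raise SequenceValidationError(
                f"record {self.id!r}: illegal character {c!r} at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _parse_header(header: str) -> tuple[str, str, str, str]:
    """Parse the optional pipe-delimited dialect ``id|species|gene|status``."""
    parts = header.split("|")
    if len(parts) == 4:
        return parts[0], parts[1], parts[2], parts[3]
    return header, "unknown", "unknown", "unknown"


def read_fasta(path: str | Path, alphabet: str = "rna") -> list[CdsRecord] | list[ProteinRecord]:
    """Read a FASTA file into validated records.

    Parameters
    ----------
    path : path to a (possibly multi-record, wrapped or unwrapped) FASTA file.
    alphabet : ``"rna"`` for :class:`CdsRecord` (T normalised to U) or
        ``"protein"`` for :class:`ProteinRecord`.

    Headers in the ``id|species|gene|status`` dialect populate the metadata
    fields; any other header leaves them ``"unknown"``.
    """
    path = Path(path)
    if alphabet not in ("rna", "protein"):
        raise ValueError(f"alphabet must be 'rna' or 'protein', got {alphabet!r}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), 1) if line.strip()
        )
        raise FastaParseError(f"{path}: line {first_bad}: expected '>' header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, species, gene, status = _parse_header(rec.description or rec.id)
        if alphabet == "rna":
            try:
                status_enum = EditingStatus(status)
            except ValueError:
                status_enum = EditingStatus.UNKNOWN
            records.append(
                CdsRecord(
                    id=rid,
                    seq=str(rec.seq),
                    species=species,
                    gene=gene,
                    editing_status=status_enum,
                )
            )
        else:
            records.append(ProteinRecord(id=rid, seq=str(rec.seq)))
    return records


def write_fasta(records, path: str | Path) -> None:
    """Write records back to FASTA, preserving the pipe-delimited dialect."""
    out = []
    for r in records:
        if isinstance(r, CdsRecord):
            header = f"{r.id}|{r.species}|{r.gene}|{r.editing_status.value}"
        else:
            header = r.id
        out.append(SeqRecord(Seq(r.seq), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta-2line")


def codon_position_indices(record: CdsRecord) -> tuple[list[int], list[int], list[int]]:
    """0-based indices of codon positions 1, 2 and 3.

    The codon span runs from ``frame_offset`` to the largest multiple-of-3
    endpoint; a trailing partial codon is dropped with a logged warning.
    """
    usable = len(record.seq) - record.frame_offset
    if usable < 3:
        raise ValueError(
            f"record {record.id!r}: no complete codon after frame offset "
            f"{record.frame_offset} (length {len(record.seq)})"
        )
    n_codons = usable // 3
    end = record.frame_offset + 3 * n_codons
    if end != len(record.seq):
        dropped = len(record.seq) - end
        warnings.warn(
            f"record {record.id!r}: trailing partial codon of {dropped} base(s) dropped",
            stacklevel=2,
        )
    start = record.frame_offset
    return (
        list(range(start, end, 3)),
        list(range(start + 1, end, 3)),
        list(range(start + 2, end, 3)),
    )


def codon_position_of(index: int, frame_offset: int = 0) -> int:
    """Codon position (1, 2 or 3) of a 0-based coordinate, trailing codon included."""
    if index < frame_offset:
        raise ValueError(f"index {index} precedes frame offset {frame_offset}")
    return (index - frame_offset) % 3 + 1


def records_to_tsv(records, path: str | Path) -> None:
    """Export record metadata as TSV (id, species, gene, status, length)."""
    import pandas as pd

    rows = []
    for r in records:
        if isinstance(r, CdsRecord):
            rows.append(
                dict(id=r.id, species=r.species, gene=r.gene,
                     editing_status=r.editing_status.value, length=len(r))
            )
        else:
            rows.append(dict(id=r.id, species="", gene="", editing_status="", length=len(r)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
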