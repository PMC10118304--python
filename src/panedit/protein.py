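"""Translation, hydrophobic / order-disorder composition, surveys and
coevolution pair summaries.

The hydrophobic amino acid set used throughout is {F, L, I, V, M, W, Y}.
Translation defaults to the mold/protozoan mitochondrial genetic code
(NCBI table 4), in which UGA reads as tryptophan, as it does in
kinetoplastid mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np
from Bio.Data import CodonTable

from .seqio import CdsRecord, ProteinRecord

HYDROPHOBIC_SET = frozenset("FLIVMWY")

#: Default order-/disorder-promoting classification (configurable).
ORDER_DISORDER_MAP = {
    **{aa: "order" for aa in "WCFIYVLN"},
    **{aa: "disorder" for aa in "ARGQSPEK"},
    **{aa: "ambiguous" for aa in "DHMT"},
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InternalStopError(ValueError):
    """An in-frame stop codon occurred before the final codon."""


@dataclass
class CompositionTable:
    """Per-amino-acid frequencies and class-aggregated totals."""

    frequencies: dict[str, float]
    class_totals: dict[str, float]
    x_fraction: float


@dataclass
class SurveyRanking:
    """Hydrophobic-fraction ranking of a protein set."""

    ids: list[str]
    fractions: list[float]
    mean: float
    sd: float
    #: dense rank (1 = most hydrophobic; ties share a rank)
    ranks: dict[str, int]
    query_ranks: dict[str, int]


@dataclass
class CoevolutionSummary:
    """Close-range high-scoring site pairs and their hydrophobic content."""

    n_pairs: int
    hydrophobic_pair_fraction: float | None
    threshold: float
    max_dist: int


def translate(
    record: CdsRecord, code_table: int = 4, allow_internal_stops: bool = False
) -> ProteinRecord:
    """Codon-by-codon translation of a CDS.

    N-containing codons yield X; a terminal stop codon is dropped; an
    internal stop raises :class:`InternalStopError` unless
    ``allow_internal_stops`` is set (it then yields X). A trailing partial
    codon is ignored.
    """
    table = CodonTable.unambiguous_rna_by_id[code_table]
    seq = record.seq[record.frame_offset:]
    n_codons = len(seq) // 3
    aas = []
    for k in range(n_codons):
        codon = seq[3 * k: 3 * k + 3]
        if "N" in codon:
            aas.append("X")
            continue
        if codon in table.stop_codons:
            if k == n_codons - 1:
                break
            if allow_internal_stops:
                aas.append("X")
                continue
            raise InternalStopError(
                f"record {record.id!r}: internal stop codon {codon} at codon {k + 1}"
            )
        aas.append(table.forward_table[codon])
    return ProteinRecord(id=f"{record.id}_protein", seq="".join(aas), source_cds_id=record.id)


def hydrophobic_fraction(
    protein: ProteinRecord, hydrophobic_set=HYDROPHOBIC_SET
) -> float:
    """Fraction of residues in ``hydrophobic_set``; X excluded from the denominator."""
    counted = [aa for aa in protein.seq if aa != "X"]
    if not counted:
        raise ValueError(f"record {protein.id!r}: all residues are X")
    return sum(1 for aa in counted if aa in hydrophobic_set) / len(counted)


def survey_rank(
    proteins: list[ProteinRecord], queries: list[str] | None = None,
    hydrophobic_set=HYDROPHOBIC_SET,
) -> SurveyRanking:
    """Rank a protein set by hydrophobic fraction (dense ranks, descending).

    Ties share a rank. The mean and population SD of the fraction vector
    are reported so a query can be placed relative to the survey.
    """
    if len(proteins) < 2:
        raise ValueError("survey needs at least 2 proteins")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        dup = [i for i, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate protein ids: {dup}")
    fractions = [hydrophobic_fraction(p, hydrophobic_set) for p in proteins]
    order = sorted(set(fractions), reverse=True)
    rank_of_fraction = {f: r for r, f in enumerate(order, start=1)}
    ranks = {pid: rank_of_fraction[f] for pid, f in zip(ids, fractions)}
    queries = queries or []
    missing = [q for q in queries if q not in ranks]
    if missing:
        raise ValueError(f"query ids not in survey: {missing}")
    return SurveyRanking(
        ids=ids,
        fractions=fractions,
        mean=float(np.mean(fractions)),
        sd=float(np.std(fractions)),
        ranks=ranks,
        query_ranks={q: ranks[q] for q in queries},
    )


def composition_by_class(
    protein: ProteinRecord, classification: dict[str, str] | None = None
) -> CompositionTable:
    """Per-letter frequencies plus order/disorder class totals.

    ``classification`` must cover all 20 amino acids; X is excluded from
    the frequency denominator and reported separately.
    """
    if classification is None:
        classification = ORDER_DISORDER_MAP
    missing = [aa for aa in AMINO_ACIDS if aa not in classification]
    if missing:
        raise ValueError(f"classification does not cover: {missing}")
    counted = [aa for aa in protein.seq if aa != "X"]
    unknown = [aa for aa in counted if aa not in AMINO_ACIDS]
    if unknown:
        raise ValueError(f"record {protein.id!r}: unknown letters {sorted(set(unknown))}")
    n = len(counted)
    counts = Counter(counted)
    freqs = {aa: counts.get(aa, 0) / n for aa in AMINO_ACIDS} if n else {aa: 0.0 for aa in AMINO_ACIDS}
    class_totals: dict[str, float] = {}
    for aa, f in freqs.items():
        cls = classification[aa]
        class_totals[cls] = class_totals.get(cls, 0.0) + f
    return CompositionTable(
        frequencies=freqs,
        class_totals=class_totals,
        x_fraction=(len(protein.seq) - n) / len(protein.seq),
    )


def read_score_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited square numeric matrix (e.g. coevolution scores)."""
    m = np.loadtxt(path)
    m = np.atleast_2d(m)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix is {m.shape[0]}x{m.shape[1]}, expected square")
    return m


def coevolution_pair_summary(
    matrix: np.ndarray,
    protein: ProteinRecord,
    threshold: float = 0.8,
    max_dist: int = 5,
    hydrophobic_set=HYDROPHOBIC_SET,
) -> CoevolutionSummary:
    """Count close-in-sequence site pairs scoring above threshold.

    Unordered pairs (i < j) with sequence separation j - i <= ``max_dist``
    (inclusive) and score strictly > ``threshold`` are counted;
    ``hydrophobic_pair_fraction`` is the fraction of those pairs where both
    residues are hydrophobic (None when no pair qualifies).
    """
    matrix = np.asarray(matrix, dtype=float)
    L = len(protein.seq)
    if matrix.shape != (L, L):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match protein length {L}"
        )
    if not np.allclose(matrix, matrix.T, atol=1e-6):
        raise ValueError("score matrix is not symmetric (tolerance 1e-6)")
    n_pairs = 0
    n_hydrophobic = 0
    for i in range(L):
        for j in range(i + 1, min(i + max_dist, L - 1) + 1):
            if matrix[i, j] > threshold:
                n_pairs += 1
                if protein.seq[i] in hydrophobic_set and protein.seq[j] in hydrophobic_set:
                    n_hydrophobic += 1
    return CoevolutionSummary(
        n_pairs=n_pairs,
        hydrophobic_pair_fraction=(n_hydrophobic / n_pairs) if n_pairs else None,
        threshold=threshold,
        max_dist=max_dist,
    )
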