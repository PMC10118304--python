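"""Inference of inserted/deleted Us from cryptogene / edited-mRNA pairs.

U-insertion/deletion editing never touches the non-U bases, so the non-U
characters of a cryptogene and of its fully edited mRNA must be the same
string in the same order. Matching them one-to-one gives an anchored
alignment; each inter-anchor region is then a run of Us in both sequences
whose length difference is the net number of Us inserted (or deleted)
there. This replaces manual cryptogene/mRNA comparison and feeds the
per-codon-position insertion counts and their homogeneity test.

Within a run, which Us are "genomic" and which were inserted is not
identifiable from sequence alone; by the ``genomic_left`` convention the
retained genomic Us occupy the 5'-most slots and inserted Us the 3'-most.
The alternative convention is computed for sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .composition import TestResult, homogeneity_test
from .seqio import CdsRecord, codon_position_of


class EditingIncompatibleError(ValueError):
    """The two sequences differ in their non-U content and cannot be an editing pair."""


@dataclass
class EditingRun:
    """One inter-anchor U run with its insertion/deletion call."""

    #: [start, end) span of the run in the edited mRNA (0-based half-open)
    edited_span: tuple[int, int]
    #: [start, end) span of the run in the cryptogene
    crypto_span: tuple[int, int]
    crypto_u: int
    edited_u: int

    @property
    def n_inserted(self) -> int:
        return max(self.edited_u - self.crypto_u, 0)

    @property
    def n_deleted(self) -> int:
        return max(self.crypto_u - self.edited_u, 0)

    def inserted_edited_indices(self, placement: str = "genomic_left") -> list[int]:
        """Edited-mRNA coordinates of the inserted Us under a placement convention."""
        start, end = self.edited_span
        if placement == "genomic_left":
            return list(range(end - self.n_inserted, end))
        if placement == "genomic_right":
            return list(range(start, start + self.n_inserted))
        raise ValueError(f"unknown placement {placement!r}")


@dataclass
class EditingAlignment:
    """Anchored cryptogene <-> edited-mRNA alignment."""

    cryptogene_id: str
    edited_id: str
    #: matched non-U character pairs as (cryptogene index, edited index)
    anchors: list[tuple[int, int]]
    runs: list[EditingRun]
    edited_frame_offset: int = 0
    edited_length: int = 0

    @property
    def total_inserted(self) -> int:
        return sum(r.n_inserted for r in self.runs)

    @property
    def total_deleted(self) -> int:
        return sum(r.n_deleted for r in self.runs)

    def to_dict(self) -> dict:
        return {
            "cryptogene_id": self.cryptogene_id,
            "edited_id": self.edited_id,
            "total_inserted": self.total_inserted,
            "total_deleted": self.total_deleted,
            "anchors": [list(a) for a in self.anchors],
            "runs": [
                {
                    "edited_span": list(r.edited_span),
                    "crypto_span": list(r.crypto_span),
                    "crypto_u": r.crypto_u,
                    "edited_u": r.edited_u,
                    "n_inserted": r.n_inserted,
                    "n_deleted": r.n_deleted,
                }
                for r in self.runs
            ],
        }


def anchor_align(cryptogene: CdsRecord, edited: CdsRecord) -> EditingAlignment:
    """Anchor the non-U characters of both sequences and call U indels per run.

    Raises :class:`EditingIncompatibleError` (reporting the first mismatch
    in both coordinate systems, 1-based) when the U-deleted sequences
    differ, i.e. the pair cannot be related by pure U editing.
    """
    c_anchor = [i for i, ch in enumerate(cryptogene.seq) if ch != "U"]
    e_anchor = [i for i, ch in enumerate(edited.seq) if ch != "U"]
    n = min(len(c_anchor), len(e_anchor))
    for k in range(n):
        ci, ei = c_anchor[k], e_anchor[k]
        if cryptogene.seq[ci] != edited.seq[ei]:
            raise EditingIncompatibleError(
                f"non-U sequences differ at anchor {k + 1}: "
                f"{cryptogene.seq[ci]!r} at cryptogene position {ci + 1} vs "
                f"{edited.seq[ei]!r} at edited position {ei + 1}"
            )
    if len(c_anchor) != len(e_anchor):
        k = n  # first unpaired anchor
        if len(c_anchor) > len(e_anchor):
            raise EditingIncompatibleError(
                f"cryptogene has {len(c_anchor) - n} extra non-U base(s), first at "
                f"cryptogene position {c_anchor[k] + 1} (edited position {len(edited.seq)})"
            )
        raise EditingIncompatibleError(
            f"edited mRNA has {len(e_anchor) - n} extra non-U base(s), first at "
            f"edited position {e_anchor[k] + 1} (cryptogene position {len(cryptogene.seq)})"
        )

    anchors = list(zip(c_anchor, e_anchor))
    runs: list[EditingRun] = []
    # inter-anchor regions: before the first anchor, between consecutive
    # anchors, and after the last one; each is all-U in both sequences.
    c_bounds = [-1] + c_anchor + [len(cryptogene.seq)]
    e_bounds = [-1] + e_anchor + [len(edited.seq)]
    for k in range(len(c_bounds) - 1):
        c_start, c_end = c_bounds[k] + 1, c_bounds[k + 1]
        e_start, e_end = e_bounds[k] + 1, e_bounds[k + 1]
        crypto_u = c_end - c_start
        edited_u = e_end - e_start
        if crypto_u == 0 and edited_u == 0:
            continue
        runs.append(
            EditingRun(
                edited_span=(e_start, e_end),
                crypto_span=(c_start, c_end),
                crypto_u=crypto_u,
                edited_u=edited_u,
            )
        )
    return EditingAlignment(
        cryptogene_id=cryptogene.id,
        edited_id=edited.id,
        anchors=anchors,
        runs=runs,
        edited_frame_offset=edited.frame_offset,
        edited_length=len(edited.seq),
    )


def inserted_by_codon_position(
    alignment: EditingAlignment, placement: str = "genomic_left"
) -> tuple[int, int, int]:
    """Count inserted Us per codon position of their edited-mRNA coordinate.

    Within each run the genomic (retained) Us occupy the 5'-most slots
    under ``genomic_left`` (3'-most under ``genomic_right``); the remaining
    slots are the inserted Us and take the codon position of their edited
    coordinate (trailing partial codon included).
    """
    if placement not in ("genomic_left", "genomic_right"):
        raise ValueError(f"unknown placement {placement!r}")
    frame = alignment.edited_frame_offset
    if not 0 <= frame <= 2:
        raise ValueError(f"invalid frame offset {frame}")
    counts = [0, 0, 0]
    for run in alignment.runs:
        for e in run.inserted_edited_indices(placement):
            counts[codon_position_of(e, frame) - 1] += 1
    return tuple(counts)


def inserted_homogeneity_test(counts) -> TestResult:
    """Homogeneity chi-square of inserted-U counts across codon positions.

    Equal expected counts per position (df = 2); delegates to
    :func:`panedit.composition.homogeneity_test` with equal site weights.
    """
    return homogeneity_test(
        tuple(counts), (1, 1, 1), test_name="inserted-U homogeneity across codon positions"
    )


def editing_report(pairs: list[tuple[CdsRecord, CdsRecord]]):
    """Per-gene inserted/total Us by codon position with the homogeneity p.

    ``pairs`` are (cryptogene, edited) record pairs. The machine version of
    the inserted-U comparison table; a pooled "All" row is appended.
    """
    import pandas as pd

    from .composition import u_content_by_position

    rows = []
    pooled_ins = [0, 0, 0]
    pooled_tot = [0, 0, 0]
    for crypto, edited in pairs:
        aln = anchor_align(crypto, edited)
        ins = inserted_by_codon_position(aln)
        tot = u_content_by_position(edited).u_counts
        test = inserted_homogeneity_test(ins)
        rows.append(
            {
                "gene": edited.gene if edited.gene != "unknown" else edited.id,
                "inserted_pos1": ins[0], "inserted_pos2": ins[1], "inserted_pos3": ins[2],
                "total_pos1": tot[0], "total_pos2": tot[1], "total_pos3": tot[2],
                "chi2": test.statistic, "p": test.p,
            }
        )
        pooled_ins = [a + b for a, b in zip(pooled_ins, ins)]
        pooled_tot = [a + b for a, b in zip(pooled_tot, tot)]
    if len(pairs) > 1:
        test = inserted_homogeneity_test(pooled_ins)
        rows.append(
            {
                "gene": "All",
                "inserted_pos1": pooled_ins[0], "inserted_pos2": pooled_ins[1],
                "inserted_pos3": pooled_ins[2],
                "total_pos1": pooled_tot[0], "total_pos2": pooled_tot[1],
                "total_pos3": pooled_tot[2],
                "chi2": test.statistic, "p": test.p,
            }
        )
    return pd.DataFrame(rows)
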