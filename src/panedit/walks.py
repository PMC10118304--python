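"""Cumulative nucleotide walks and cumulative hydropathy profiles.

A U walk assigns x[i] = +1 when position i carries the target base (U by
default) and -1 otherwise, and plots the running sum s[k] = sum(x[1..k]).
A positive local slope marks a U-rich region; the final value equals
2*(#target) - n. Walks can be restricted to one codon position, which is
how second-position U enrichment (the hydrophobicity-relevant one) is
visualised. Cumulative Kyte-Doolittle profiles are the protein-level
counterpart, indexed by mRNA coordinate so both can share an x-axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import CdsRecord, ProteinRecord, codon_position_indices

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic); X contributes 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass
class WalkSeries:
    """Cumulative +/-1 walk for one sequence (optionally one codon position).

    ``positions_used`` are 0-based sequence coordinates in ascending order;
    ``s[k]`` is the cumulative value after the (k+1)-th used position.
    N counts as non-target (a -1 step).
    """

    sequence_id: str
    target: str
    positions_used: list[int]
    s: list[int]
    codon_position: int | None = None

    @property
    def final(self) -> int:
        return self.s[-1] if self.s else 0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "rank": np.arange(1, len(self.s) + 1),
                "mrna_position": [p + 1 for p in self.positions_used],
                "s": self.s,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class HydropathyProfile:
    """Per-residue Kyte-Doolittle scores and their running sum."""

    sequence_id: str
    residue_scores: list[float]
    cumulative: list[float]
    #: 1-based mRNA coordinate of each residue's codon start (3*i + 1)
    mrna_coordinates: list[int] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "residue": np.arange(1, len(self.residue_scores) + 1),
                "mrna_position": self.mrna_coordinates,
                "kd": self.residue_scores,
                "cumulative_kd": self.cumulative,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def nucleotide_walk(
    record: CdsRecord, target: str = "U", codon_position: int | None = None
) -> WalkSeries:
    """Cumulative walk of ``target`` occupancy along a CDS.

    With ``codon_position`` in {1, 2, 3} the walk is restricted to the
    indices of that codon slot (ascending); otherwise every position is
    used. An empty position list yields an empty series.
    """
    if codon_position is None:
        positions = list(range(len(record.seq)))
    elif codon_position in (1, 2, 3):
        positions = codon_position_indices(record)[codon_position - 1]
    else:
        raise ValueError(f"codon_position must be 1, 2 or 3, got {codon_position!r}")
    steps = np.array([1 if record.seq[i] == target else -1 for i in positions], dtype=int)
    s = np.cumsum(steps).tolist() if len(steps) else []
    return WalkSeries(
        sequence_id=record.id,
        target=target,
        positions_used=positions,
        s=s,
        codon_position=codon_position,
    )


def cumulative_hydropathy(protein: ProteinRecord) -> HydropathyProfile:
    """Cumulative Kyte-Doolittle profile of a protein.

    The mRNA coordinate of residue i (0-based) is 3*i + 1 (1-based codon
    start), which lets the profile be overlaid on nucleotide walks.
    """
    scores = [KYTE_DOOLITTLE[aa] for aa in protein.seq]
    return HydropathyProfile(
        sequence_id=protein.id,
        residue_scores=scores,
        cumulative=np.cumsum(scores).tolist(),
        mrna_coordinates=[3 * i + 1 for i in range(len(scores))],
    )


def plot_walks(walks: list[WalkSeries], path: str | Path, use_mrna_coordinates: bool = True):
    """Line plot of one or more walks (per-position walks against mRNA coordinate)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for w in walks:
        x = [p + 1 for p in w.positions_used] if use_mrna_coordinates else range(1, len(w.s) + 1)
        label = w.sequence_id
        if w.codon_position:
            label += f" (pos {w.codon_position})"
        ax.plot(list(x), w.s, label=label, linewidth=1)
    ax.set_xlabel("mRNA position" if use_mrna_coordinates else "rank")
    ax.set_ylabel(f"s[{walks[0].target if walks else 'U'}k]")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
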