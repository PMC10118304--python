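"""Hydrophobic cluster analysis (HCA).

The protein sequence is written on a duplicated alpha-helical net
(3.6 residues per turn, the net drawn twice vertically for continuity) so
that residues adjacent in an idealised helix sit next to each other on the
plot. Hydrophobic residues ({V, I, L, F, M, Y, W}) that are close in
sequence and not separated by a proline form clusters; stretches of four
or more consecutive non-hydrophobic residues are the hydrophilic gaps that
delimit them.

Cluster connectivity here is a deliberate, parameterised approximation of
the classic drawn-net contours: two hydrophobic residues are connected iff
their sequence separation is at most ``max_gap`` (default 4, the helical
neighbourhood) and no breaker residue (default proline) lies strictly
between them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import ProteinRecord

HCA_HYDROPHOBIC = frozenset("VILFMYW")

RESIDUES_PER_TURN = 3.6

_CLASSES = {
    **{aa: "hydrophobic" for aa in HCA_HYDROPHOBIC},
    "P": "proline",
    "S": "ser_thr", "T": "ser_thr",
    "G": "glycine",
    "D": "acidic_amide", "E": "acidic_amide", "Q": "acidic_amide", "N": "acidic_amide",
    "R": "basic", "K": "basic", "H": "basic",
}


@dataclass
class HcaNet:
    """Residue coordinates on the duplicated helical net plus symbol classes."""

    sequence_id: str
    #: per-residue (x, y) on the primary net copy; x = residue index,
    #: y = helical phase in turns (0 <= y < 1)
    coords: list[tuple[float, float]]
    #: the duplicate copy, offset by one full turn for visual continuity
    coords_duplicate: list[tuple[float, float]]
    residue_class: list[str]


@dataclass
class HcaClusters:
    """Hydrophobic clusters and the hydrophilic gaps between them."""

    sequence_id: str
    #: disjoint sets of residue indices (hydrophobic members only)
    clusters: list[frozenset[int]]
    #: maximal [start, end) runs of >= min_gap_len consecutive non-hydrophobic residues
    hydrophilic_gaps: list[tuple[int, int]]


def residue_class(aa: str) -> str:
    return _CLASSES.get(aa, "other")


def build_net(protein: ProteinRecord) -> HcaNet:
    """Place each residue on the duplicated alpha-helical net.

    Residue i sits at x = i with helical phase (i / 3.6) mod 1 as its y on
    the primary copy; the duplicate copy is the same net shifted up one
    turn, so pairs split across the seam appear contiguous.
    """
    if len(protein.seq) < 2:
        raise ValueError(f"record {protein.id!r}: HCA needs at least 2 residues")
    coords = [(float(i), (i / RESIDUES_PER_TURN) % 1.0) for i in range(len(protein.seq))]
    dup = [(x, y + 1.0) for x, y in coords]
    return HcaNet(
        sequence_id=protein.id,
        coords=coords,
        coords_duplicate=dup,
        residue_class=[residue_class(aa) for aa in protein.seq],
    )


def detect_clusters(
    protein: ProteinRecord,
    hydrophobic_set=HCA_HYDROPHOBIC,
    max_gap: int = 4,
    breakers=frozenset("P"),
    min_gap_len: int = 4,
) -> HcaClusters:
    """Delimit hydrophobic clusters as connected components.

    Two hydrophobic residues are connected iff their sequence separation is
    <= ``max_gap`` and no breaker lies strictly between them; clusters are
    the connected components of that graph. Every hydrophobic residue
    belongs to exactly one cluster and no cluster spans a breaker.
    """
    seq = protein.seq
    hydro = [i for i, aa in enumerate(seq) if aa in hydrophobic_set]
    clusters: list[set[int]] = []
    current: set[int] = set()
    prev = None
    for i in hydro:
        connected = (
            prev is not None
            and i - prev <= max_gap
            and not any(seq[k] in breakers for k in range(prev + 1, i))
        )
        if connected:
            current.add(i)
        else:
            if current:
                clusters.append(current)
            current = {i}
        prev = i
    if current:
        clusters.append(current)

    gaps: list[tuple[int, int]] = []
    start = None
    for i, aa in enumerate(seq):
        if aa not in hydrophobic_set:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_gap_len:
                gaps.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_gap_len:
        gaps.append((start, len(seq)))

    return HcaClusters(
        sequence_id=protein.id,
        clusters=[frozenset(c) for c in clusters],
        hydrophilic_gaps=gaps,
    )


def clusters_to_tsv(clusters: HcaClusters, path) -> None:
    """TSV cluster table: cluster id, start, end (1-based inclusive), members."""
    import pandas as pd

    rows = []
    for k, c in enumerate(sorted(clusters.clusters, key=min), start=1):
        rows.append(
            {
                "cluster": k,
                "start": min(c) + 1,
                "end": max(c) + 1,
                "size": len(c),
                "members": ",".join(str(i + 1) for i in sorted(c)),
            }
        )
    pd.DataFrame(rows, columns=["cluster", "start", "end", "size", "members"]).to_csv(
        path, sep="\t", index=False
    )


def boundary_distances(clusters: HcaClusters, annotated_sites: list[int]) -> dict[int, int]:
    """Distance (residues) from each annotated site to the nearest cluster boundary.

    Boundaries are the first and last member of each cluster. Used for
    overlay annotations such as "substituted" or "under purifying
    selection" sites, whose placement relative to cluster edges is
    otherwise judged by eye.
    """
    bounds: list[int] = []
    for c in clusters.clusters:
        bounds.extend((min(c), max(c)))
    if not bounds:
        return {s: -1 for s in annotated_sites}
    return {s: min(abs(s - b) for b in bounds) for s in annotated_sites}


_SYMBOL = {
    "proline": ("*", "black"),
    "ser_thr": ("s", "dimgray"),
    "glycine": ("D", "dimgray"),
    "acidic_amide": ("o", "red"),
    "basic": ("o", "blue"),
    "hydrophobic": ("o", "green"),
    "other": ("o", "lightgray"),
}


def plot_net(
    protein: ProteinRecord, path, clusters: HcaClusters | None = None,
    annotations: dict[int, str] | None = None,
):
    """SVG/PNG rendering of the duplicated net with cluster outlines.

    Symbol conventions: stars for prolines, squares for S/T, diamonds for
    G, red for acidic/amide, blue for basic, green for hydrophobic.
    ``annotations`` maps residue index to a label drawn under the net.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    net = build_net(protein)
    if clusters is None:
        clusters = detect_clusters(protein)
    fig, ax = plt.subplots(figsize=(max(6, len(protein.seq) / 8), 3))
    for copy in (net.coords, net.coords_duplicate):
        for (x, y), cls, aa in zip(copy, net.residue_class, protein.seq):
            marker, color = _SYMBOL[cls]
            ax.scatter([x], [y], marker=marker, c=color, s=30)
            ax.annotate(aa, (x, y), fontsize=5, ha="left", va="bottom")
    for c in clusters.clusters:
        xs = sorted(c)
        ax.plot([xs[0] - 0.4, xs[-1] + 0.4], [-0.15, -0.15], color="black", linewidth=2)
    if annotations:
        for i, label in annotations.items():
            ax.annotate(label, (i, -0.35), fontsize=5, ha="center", color="purple")
    ax.set_xlabel("residue")
    ax.set_ylabel("helical phase (turns)")
    ax.set_ylim(-0.5, 2.1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
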