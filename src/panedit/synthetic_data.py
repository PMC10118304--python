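"""Seeded generators emulating the statistical structure of the real inputs.

Three generators cover the three data regimes the pipeline consumes:

* ``simulate_editing_pair`` — a cryptogene / fully-edited-mRNA pair with a
  known ground-truth record of every insertion/deletion run, for testing
  the anchored editing inference end to end;
* ``simulate_divergence`` — a star phylogeny of diverged CDSs with
  per-codon-position substitution rates, the second position shrunk by a
  purifying-selection multiplier;
* ``make_toy_complex`` — a two-chain toy structure whose contact residues
  are known from construction, for testing SASA-based interface detection.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .editing import EditingAlignment, EditingRun
from .seqio import CdsRecord
from .structure import Atom, Chain, PROBE_RADIUS, Residue, StructureModel

BASES = np.array(list("ACGU"))


@dataclass
class EditingSimParams:
    """Parameters of the cryptogene / edited-mRNA simulator.

    ``insertion_rate`` is the expected number of inserted Us per anchor
    gap; run lengths are geometric with success probability
    ``run_length_q`` (mean run 1/q). ``deletion_rate`` is the per-genomic-U
    deletion probability. ``position_bias`` optionally biases insertions
    toward codon positions (3 weights, normalised internally). Defaults
    emulate a pan-edited mitochondrial CDS: a U-poor, G-rich cryptogene
    whose edited mRNA is roughly 60% U with ~90% of its Us inserted.
    """

    cds_length: int = 200  # codons in the cryptogene
    base_composition: tuple[float, float, float, float] = (0.30, 0.25, 0.30, 0.15)  # A C G U
    insertion_rate: float = 1.5
    run_length_q: float = 0.5
    deletion_rate: float = 0.05
    position_bias: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cds_length < 1:
            raise ValueError("cds_length must be >= 1")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp < 0).any():
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.insertion_rate < 0 or self.deletion_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.run_length_q <= 1:
            raise ValueError("run_length_q must be in (0, 1]")
        if self.position_bias is not None:
            w = np.asarray(self.position_bias, dtype=float)
            if w.shape != (3,) or (w < 0).any() or w.sum() == 0:
                raise ValueError("position_bias must be 3 non-negative weights")


@dataclass
class DivergenceSimParams:
    """Parameters of the star-phylogeny divergence simulator."""

    n_species: int = 5
    rates: tuple[float, float, float] = (0.1, 0.1, 0.1)  # per site, per codon position
    purifying_strength: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be >= 0")
        if self.purifying_strength <= 0:
            raise ValueError("purifying_strength must be > 0")


def _bias_acceptance(
    insertion_rate: float,
    weights: np.ndarray,
    p_u: float,
    keep: float,
    max_iter: int = 500,
) -> np.ndarray:
    """Per-codon-position acceptance probabilities for biased insertion.

    Insertion opportunities form a Markov chain over codon positions: a
    gap's first opportunity sits one slot after the previous gap's
    rejection position plus the retained genomic Us emitted in between,
    and every accepted insertion shifts the next opportunity one position
    onward. The acceptance probabilities q[c] are calibrated numerically
    so that the *stationary* expected insertions at position c equal
    insertion_rate * w[c]: the gap-start distribution, the within-gap
    visit counts and the rejection distribution are iterated to their
    joint fixed point while q is rescaled toward the target.

    ``p_u`` is the cryptogene U probability and ``keep`` the per-genomic-U
    retention probability; together they set the distribution of the
    genomic-U shift between consecutive gaps.
    """
    w = weights / weights.sum()
    target = insertion_rate * w

    # distribution over (1 + retained genomic Us) mod 3 between gaps:
    # the genomic U-run length before an anchor is geometric(1 - p_u),
    # thinned by the deletion survival probability ``keep``.
    g_max = 60
    n_probs = (1 - p_u) * p_u ** np.arange(g_max + 1)
    shift = np.zeros(3)
    for n, pn in enumerate(n_probs):
        for g in range(n + 1):
            pg = pn * _binom_pmf(n, g, keep)
            shift[(1 + g) % 3] += pg
    shift /= shift.sum()

    def visits(pi: np.ndarray, q: np.ndarray) -> np.ndarray:
        # within-gap visit counts: v[c] = pi[c] + q[c-1] * v[c-1]
        A = np.zeros((3, 3))
        for c in range(3):
            A[c, (c - 1) % 3] = q[(c - 1) % 3]
        return np.linalg.solve(np.eye(3) - A, pi)

    def stationary_start(pi: np.ndarray, q: np.ndarray) -> np.ndarray:
        # gap-start distribution: previous gap's rejection position
        # convolved with the (1 + genomic Us) shift
        for _ in range(1000):
            reject = visits(pi, q) * (1.0 - q)
            pi_new = np.zeros(3)
            for c in range(3):
                for m in range(3):
                    pi_new[(c + m) % 3] += reject[c] * shift[m]
            pi_new /= pi_new.sum()
            if np.abs(pi_new - pi).max() < 1e-14:
                return pi_new
            pi = pi_new
        return pi

    q = np.clip(target / (1.0 / 3.0 + np.roll(target, 1)), 1e-6, 0.999)
    pi = np.full(3, 1.0 / 3.0)
    for _ in range(max_iter):
        pi = stationary_start(pi, q)
        n_ins = visits(pi, q) * q
        if np.abs(n_ins - target).max() < 1e-12:
            break
        scale = np.where(n_ins > 0, target / n_ins, 1.0)
        q = np.clip(q * scale ** 0.7, 1e-6, 0.999)
    if np.abs(n_ins - target).max() > 1e-6 * max(insertion_rate, 1.0):
        warnings.warn(
            "position_bias/insertion_rate combination could not be calibrated "
            "exactly; realised bias will be distorted",
            stacklevel=3,
        )
    return q


def _binom_pmf(n: int, k: int, p: float) -> float:
    from math import comb

    return comb(n, k) * p ** k * (1 - p) ** (n - k)


def simulate_editing_pair(
    params: EditingSimParams,
) -> tuple[CdsRecord, CdsRecord, EditingAlignment]:
    """Simulate a (cryptogene, edited mRNA, ground truth) triple.

    The cryptogene is drawn iid from ``base_composition``. The edited mRNA
    is built left to right: in each inter-anchor region the retained
    genomic Us are emitted first and inserted Us appended after them, so
    the simulated placement coincides with the ``genomic_left`` convention
    and truth positions are the actual insertion coordinates. Per-run
    ground truth is the net signed U-count difference — exactly what any
    anchored inference can recover.
    """
    rng = np.random.default_rng(params.seed)
    n = 3 * params.cds_length
    crypto = rng.choice(BASES, size=n, p=np.asarray(params.base_composition, dtype=float))
    crypto_seq = "".join(crypto)

    q_bias = None
    if params.position_bias is not None:
        q_bias = _bias_acceptance(
            params.insertion_rate,
            np.asarray(params.position_bias, float),
            p_u=float(params.base_composition[3]),
            keep=1.0 - params.deletion_rate,
        )
    p_run = min(1.0, params.insertion_rate * params.run_length_q)

    edited_chars: list[str] = []
    runs: list[EditingRun] = []
    anchors: list[tuple[int, int]] = []

    def flush_region(c_start: int, c_end: int) -> None:
        """Emit one inter-anchor region (genomic Us then insertions)."""
        g = c_end - c_start  # genomic Us in the region
        e_start = len(edited_chars)
        retained = g - int(rng.binomial(g, params.deletion_rate)) if g else 0
        edited_chars.extend("U" * retained)
        if q_bias is None:
            if rng.random() < p_run:
                run_len = int(rng.geometric(params.run_length_q))
                edited_chars.extend("U" * run_len)
        else:
            while True:
                c = len(edited_chars) % 3
                if rng.random() < q_bias[c]:
                    edited_chars.append("U")
                else:
                    break
        e_end = len(edited_chars)
        if g > 0 or e_end > e_start:
            runs.append(
                EditingRun(
                    edited_span=(e_start, e_end),
                    crypto_span=(c_start, c_end),
                    crypto_u=g,
                    edited_u=e_end - e_start,
                )
            )

    region_start = 0
    for i, ch in enumerate(crypto_seq):
        if ch != "U":
            flush_region(region_start, i)
            anchors.append((i, len(edited_chars)))
            edited_chars.append(ch)
            region_start = i + 1
    flush_region(region_start, n)

    edited_seq = "".join(edited_chars)
    crypto_rec = CdsRecord(
        id=f"sim{params.seed}_cryptogene", seq=crypto_seq,
        species="synthetic", gene="synthetic", editing_status="nonedited",
    )
    edited_rec = CdsRecord(
        id=f"sim{params.seed}_edited", seq=edited_seq,
        species="synthetic", gene="synthetic", editing_status="pan_edited",
    )
    truth = EditingAlignment(
        cryptogene_id=crypto_rec.id,
        edited_id=edited_rec.id,
        anchors=anchors,
        runs=runs,
        edited_frame_offset=0,
        edited_length=len(edited_seq),
    )
    return crypto_rec, edited_rec, truth


def simulate_divergence(root: CdsRecord, params: DivergenceSimParams) -> list[CdsRecord]:
    """Independently diverge ``n_species`` copies of a root CDS.

    Each site substitutes with probability equal to its codon-position
    rate (position 2 divided by ``purifying_strength``), to a uniformly
    chosen different base. Sites before the frame offset never mutate.
    """
    rng = np.random.default_rng(params.seed)
    rates = list(params.rates)
    rates[1] = rates[1] / params.purifying_strength
    seq = np.array(list(root.seq))
    site_rate = np.zeros(len(seq))
    for i in range(root.frame_offset, len(seq)):
        site_rate[i] = min(rates[(i - root.frame_offset) % 3], 1.0)
    species = []
    for s in range(params.n_species):
        mutate = rng.random(len(seq)) < site_rate
        new = seq.copy()
        for i in np.nonzero(mutate)[0]:
            choices = [b for b in "ACGU" if b != seq[i]]
            new[i] = choices[rng.integers(3)]
        species.append(
            CdsRecord(
                id=f"{root.id}_sp{s}", seq="".join(new),
                species=f"species_{s}", gene=root.gene,
                frame_offset=root.frame_offset,
            )
        )
    return species


def make_toy_complex(
    n_residues_a: int,
    n_residues_b: int,
    contact_fraction: float = 0.3,
    seed: int = 0,
    separation: float = 5.8,
    rise: float = 3.0,
    jitter: float = 0.05,
) -> tuple[StructureModel, dict[str, set[int]]]:
    """Two-chain poly-alanine toy complex with a known contact set.

    Each chain is a straight rod of C-alpha spheres (one atom per residue,
    ``rise`` A apart). Chain B runs parallel to chain A at lateral
    distance ``separation``, shifted along the axis so that its first
    k = round(contact_fraction * min(nA, nB)) residues face the last k
    residues of chain A one-to-one; all other inter-chain pairs are beyond
    SASA-occlusion range by construction. Ground truth is computed from
    the (jittered) coordinates with the occlusion cutoff
    r_i + r_j + 2 * probe, i.e. exactly the geometry that can reduce SASA.

    Returns the model and a dict mapping chain id to the set of contact
    residue seq_ids (1-based).
    """
    if n_residues_a < 3 or n_residues_b < 3:
        raise ValueError("chains need at least 3 residues")
    if not 0 < contact_fraction <= 1:
        raise ValueError("contact_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    k = max(1, round(contact_fraction * min(n_residues_a, n_residues_b)))
    x0 = (n_residues_a - k) * rise

    def make_chain(cid: str, n: int, x_start: float, y: float) -> Chain:
        residues = []
        for i in range(n):
            pos = np.array([x_start + i * rise, y, 0.0])
            pos = pos + rng.uniform(-jitter, jitter, size=3)
            residues.append(
                Residue(
                    name="ALA", seq_id=i + 1,
                    atoms=[Atom(element="C", name="CA", coords=pos, radius=1.70)],
                )
            )
        return Chain(id=cid, residues=residues)

    chain_a = make_chain("A", n_residues_a, 0.0, 0.0)
    chain_b = make_chain("B", n_residues_b, x0, separation)
    model = StructureModel(chains=[chain_a, chain_b], name=f"toy_complex_seed{seed}")

    cutoff = {"A": set(), "B": set()}
    for ra in chain_a.residues:
        for rb in chain_b.residues:
            d = np.linalg.norm(ra.atoms[0].coords - rb.atoms[0].coords)
            if d < ra.atoms[0].radius + rb.atoms[0].radius + 2 * PROBE_RADIUS:
                cutoff["A"].add(ra.seq_id)
                cutoff["B"].add(rb.seq_id)
    return model, cutoff
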