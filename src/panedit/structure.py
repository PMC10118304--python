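"""SASA, exposure, interface detection and site-wise hydrophobicity comparison.

Solvent-accessible surface area is computed with a Shrake-Rupley sphere
sampler written here (probe 1.4 A, 960 points per atom by default, element
radii C 1.70 / N 1.55 / O 1.52 / S 1.80 A, hydrogens ignored). Relative
SASA normalises by the Tien et al. theoretical maximum per residue type;
a residue is "exposed" when its relative SASA is strictly above 0.30.
Interface residues are those that lose more than a small epsilon of SASA
(0.1 A^2, guarding against point-sampling noise) when their chain is
evaluated in the two-chain complex instead of alone.

Site-wise hydrophobicity comparison takes an externally supplied residue
pairing between a query and a subject protein (a helper global aligner is
provided for synthetic tests), flags each pair where the query residue has
the higher Kyte-Doolittle value, and tests whether such increases are
enriched in a stratum (exposed vs non-exposed, interface vs non-interface)
with a 2x2 chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .composition import TestResult, two_by_two_test
from .seqio import ProteinRecord
from .walks import KYTE_DOOLITTLE

#: van der Waals radii (A) used for SASA; hydrogens are ignored.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4

#: Theoretical maximum ASA (A^2) per residue type (Tien et al. 2013).
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    element: str
    name: str
    coords: np.ndarray  # (3,) in A
    radius: float


@dataclass
class Residue:
    name: str  # 3-letter code
    seq_id: int  # author numbering
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Chain:
    id: str
    residues: list[Residue]


@dataclass
class StructureModel:
    """Chains -> residues -> atoms with element radii already assigned."""

    chains: list[Chain]
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not in model (have {[c.id for c in self.chains]})")

    def subset(self, chain_ids) -> "StructureModel":
        return StructureModel(
            chains=[self.chain(cid) for cid in chain_ids], name=self.name
        )

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclass
class SasaResult:
    """Per-residue absolute and relative SASA with exposure flags."""

    #: (chain id, residue seq_id) keys, in model order
    residue_keys: list[tuple[str, int]]
    residue_names: list[str]  # 1-letter
    absolute: np.ndarray  # A^2
    relative: np.ndarray  # absolute / max ASA (nan for unknown residue types)
    probe: float
    n_points: int

    @property
    def exposed(self) -> np.ndarray:
        return classify_exposure(self)

    def total(self) -> float:
        return float(self.absolute.sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.residue_keys],
                "residue": [k[1] for k in self.residue_keys],
                "aa": self.residue_names,
                "sasa": self.absolute,
                "relative_sasa": self.relative,
                "exposed": [
                    bool(r > 0.30) if np.isfinite(r) else False for r in self.relative
                ],
            }
        )


@dataclass
class InterfaceMap:
    """Per-residue SASA loss on complex formation for one chain."""

    chain_id: str
    residue_keys: list[tuple[str, int]]
    delta_sasa: np.ndarray  # SASA(alone) - SASA(in complex), >= -tolerance
    epsilon: float

    @property
    def interface(self) -> np.ndarray:
        return self.delta_sasa > self.epsilon

    def interface_residues(self) -> set[int]:
        return {k[1] for k, flag in zip(self.residue_keys, self.interface) if flag}


@dataclass
class SiteComparisonResult:
    """Stratified comparison of per-site hydrophobicity increases."""

    pairs: list[tuple[int, int]]
    increase: np.ndarray  # bool per pair: KD(query) > KD(subject)
    stratum_name: str
    in_stratum: np.ndarray  # bool per pair
    fraction_in: float
    fraction_out: float
    contingency: np.ndarray
    test: TestResult | None
    editing_fraction_in: float | None = None
    editing_fraction_out: float | None = None
    editing_test: TestResult | None = None


def read_structure(
    path: str | Path,
    keep_waters: bool = False,
    keep_hetero: bool = False,
    unknown_radius: float = DEFAULT_RADIUS,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens are dropped; waters and hetero (non-polymer) residues are
    skipped by default; unknown elements get ``unknown_radius`` with a
    warning.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains = []
    for model in st:
        for ch in model:
            residues = []
            for res in ch:
                if res.is_water() and not keep_waters:
                    continue
                if res.het_flag == "H" and not res.is_water() and not keep_hetero \
                        and res.name not in THREE_TO_ONE:
                    continue
                atoms = []
                for at in res:
                    elem = at.element.name.upper()
                    if elem == "H" or elem == "D":
                        continue
                    if elem in ELEMENT_RADII:
                        radius = ELEMENT_RADII[elem]
                    else:
                        warnings.warn(
                            f"unknown element {elem!r} in {res.name} {res.seqid.num}; "
                            f"using radius {unknown_radius} A",
                            stacklevel=2,
                        )
                        radius = unknown_radius
                    atoms.append(
                        Atom(
                            element=elem,
                            name=at.name,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            radius=radius,
                        )
                    )
                if atoms:
                    residues.append(Residue(name=res.name, seq_id=res.seqid.num, atoms=atoms))
            if residues:
                chains.append(Chain(id=ch.name, residues=residues))
        break  # first model only
    return StructureModel(chains=chains, name=st.name or Path(path).stem)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a model as plain-text PDB."""
    lines = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                x, y, z = atom.coords
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{res.name:>4s} {chain.id}"
                    f"{res.seq_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def sphere_points(n: int) -> np.ndarray:
    """n approximately evenly distributed unit vectors (Fibonacci lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _flatten(model: StructureModel):
    coords, radii, res_index, keys, names = [], [], [], [], []
    for chain in model.chains:
        for res in chain.residues:
            keys.append((chain.id, res.seq_id))
            names.append(res.one_letter)
            for atom in res.atoms:
                coords.append(atom.coords)
                radii.append(atom.radius)
                res_index.append(len(keys) - 1)
    return (
        np.asarray(coords, dtype=float),
        np.asarray(radii, dtype=float),
        np.asarray(res_index, dtype=int),
        keys,
        names,
    )


def sasa(model: StructureModel, probe: float = PROBE_RADIUS, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley SASA per residue.

    Each atom is sampled with ``n_points`` evenly distributed points on
    the sphere of radius r + probe; a point is accessible iff it lies
    outside every other atom's extended sphere. Atom SASA is the
    accessible fraction of 4*pi*(r+probe)^2; residue SASA sums its atoms.
    """
    if n_points < 10:
        raise ValueError(f"n_points must be >= 10, got {n_points}")
    if model.n_atoms() == 0:
        raise ValueError("empty model")
    coords, radii, res_index, keys, names = _flatten(model)
    unit = sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    atom_sasa = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * unit
        neighbors = tree.query_ball_point(coords[i], ext[i] + max_ext)
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= ext[j] ** 2
        atom_sasa[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.sum() / n_points
    absolute = np.zeros(len(keys))
    np.add.at(absolute, res_index, atom_sasa)
    relative = np.array(
        [a / MAX_ASA[nm] if nm in MAX_ASA else np.nan for a, nm in zip(absolute, names)]
    )
    return SasaResult(
        residue_keys=keys,
        residue_names=names,
        absolute=absolute,
        relative=relative,
        probe=probe,
        n_points=n_points,
    )


def classify_exposure(result: SasaResult, threshold: float = 0.30) -> np.ndarray:
    """Exposure flags: relative SASA strictly greater than the threshold."""
    missing = [
        (k, nm)
        for k, nm, r in zip(result.residue_keys, result.residue_names, result.relative)
        if not np.isfinite(r)
    ]
    if missing:
        k, nm = missing[0]
        raise ValueError(
            f"residue type {nm!r} at {k[0]}:{k[1]} missing from the max-ASA table"
        )
    return result.relative > threshold


def interface_sites(
    complex_model: StructureModel,
    chain_a: str,
    chain_b: str,
    probe: float = PROBE_RADIUS,
    n_points: int = 960,
    epsilon: float = 0.1,
) -> dict[str, InterfaceMap]:
    """Interface residues of two chains by SASA reduction on complex formation.

    Each chain's per-residue SASA is computed alone and in the two-chain
    context; residues losing more than ``epsilon`` (A^2) are flagged as
    interface.
    """
    if chain_a == chain_b:
        raise ValueError("chain ids must differ")
    together = sasa(complex_model.subset([chain_a, chain_b]), probe, n_points)
    out = {}
    for cid in (chain_a, chain_b):
        alone = sasa(complex_model.subset([cid]), probe, n_points)
        mask = [k[0] == cid for k in together.residue_keys]
        in_complex = together.absolute[np.array(mask)]
        delta = alone.absolute - in_complex
        out[cid] = InterfaceMap(
            chain_id=cid,
            residue_keys=alone.residue_keys,
            delta_sasa=delta,
            epsilon=epsilon,
        )
    return out


def align_proteins(query: ProteinRecord, subject: ProteinRecord) -> list[tuple[int, int]]:
    """Helper global aligner (BLOSUM62, gap open 11 / extend 1).

    Returns aligned (query index, subject index) pairs, both non-gap,
    0-based. Intended for synthetic tests; site pairings of real homolog
    pairs should be supplied by the user.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(query.seq, subject.seq)[0]
    pairs = []
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        pairs.extend(zip(range(qs, qe), range(ss, se)))
    return pairs


def read_pair_tsv(path) -> list[tuple[int, int]]:
    """Read a two-column paired-index TSV (1-based) into 0-based pairs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    return [(int(q) - 1, int(s) - 1) for q, s in zip(df[0], df[1])]


def compare_hydrophobicity(
    query: ProteinRecord,
    subject: ProteinRecord,
    alignment: list[tuple[int, int]],
    strata: dict[int, bool],
    stratum_name: str = "exposed",
    edited_flags: dict[int, bool] | None = None,
) -> SiteComparisonResult:
    """Fraction of aligned sites where the query is more hydrophobic, by stratum.

    ``strata`` maps query residue indices (0-based) to stratum membership
    (e.g. exposed=True / non-exposed=False); pairs whose query site is
    absent from ``strata`` are dropped. The in- vs out-of-stratum contrast
    of increase fractions is tested with a 2x2 chi-square (no continuity
    correction). ``edited_flags`` optionally runs the parallel contrast of
    editing frequency by stratum.
    """
    pairs = [(qi, sj) for qi, sj in alignment if qi in strata]
    if not pairs:
        raise ValueError("no aligned sites overlap the strata definition")
    for qi, sj in pairs:
        if qi >= len(query.seq) or sj >= len(subject.seq):
            raise ValueError(f"alignment pair ({qi}, {sj}) outside sequence bounds")
    increase = np.array(
        [KYTE_DOOLITTLE[query.seq[qi]] > KYTE_DOOLITTLE[subject.seq[sj]] for qi, sj in pairs]
    )
    in_stratum = np.array([strata[qi] for qi, _ in pairs])

    def _contrast(flags: np.ndarray, what: str):
        n_in, n_out = int(in_stratum.sum()), int((~in_stratum).sum())
        frac_in = float(flags[in_stratum].mean()) if n_in else float("nan")
        frac_out = float(flags[~in_stratum].mean()) if n_out else float("nan")
        table = np.array(
            [
                [int(flags[in_stratum].sum()), n_in - int(flags[in_stratum].sum())],
                [int(flags[~in_stratum].sum()), n_out - int(flags[~in_stratum].sum())],
            ],
            dtype=float,
        )
        test = None
        if n_in == 0 or n_out == 0:
            warnings.warn(f"empty stratum in {what} contrast; test skipped", stacklevel=3)
        elif table.sum(axis=0).min() == 0:
            # all-yes or all-no: chi-square degenerate
            test = TestResult(
                statistic=0.0, df=1, p=1.0, observed=table, expected=table,
                test_name=f"{what} by {stratum_name}", degenerate=True,
            )
        else:
            test = two_by_two_test(table, test_name=f"{what} by {stratum_name}")
        return frac_in, frac_out, table, test

    frac_in, frac_out, table, test = _contrast(increase, "hydrophobicity increase")
    result = SiteComparisonResult(
        pairs=pairs,
        increase=increase,
        stratum_name=stratum_name,
        in_stratum=in_stratum,
        fraction_in=frac_in,
        fraction_out=frac_out,
        contingency=table,
        test=test,
    )
    if edited_flags is not None:
        edited = np.array([bool(edited_flags.get(qi, False)) for qi, _ in pairs])
        e_in, e_out, _, e_test = _contrast(edited, "editing frequency")
        result.editing_fraction_in = e_in
        result.editing_fraction_out = e_out
        result.editing_test = e_test
    return result
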