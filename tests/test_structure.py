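import numpy as np
import pytest

from panedit.composition import two_by_two_test
from panedit.seqio import ProteinRecord
from panedit.structure import (
    Atom,
    Chain,
    Residue,
    SasaResult,
    StructureModel,
    align_proteins,
    classify_exposure,
    compare_hydrophobicity,
    interface_sites,
    read_structure,
    sasa,
    sphere_points,
    write_pdb,
)
from panedit.synthetic_data import make_toy_complex


def single_atom_model(radius=1.7, n=1, spacing=100.0):
    residues = [
        Residue("ALA", i + 1, [Atom("C", "CA", np.array([i * spacing, 0.0, 0.0]), radius)])
        for i in range(n)
    ]
    return StructureModel(chains=[Chain("A", residues)])


class TestSasaAnalytics:
    def test_single_sphere_matches_closed_form_within_1pct(self):
        res = sasa(single_atom_model())
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(res.total() - exact) / exact < 0.01

    def test_far_spheres_both_full(self):
        res = sasa(single_atom_model(n=2))
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert np.allclose(res.absolute, exact, rtol=1e-6)

    def test_two_sphere_overlap_matches_spherical_cap_within_2pct(self):
        d = 4.0
        model = single_atom_model(n=2, spacing=d)
        res = sasa(model)
        R = 1.7 + 1.4
        analytic = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        assert np.all(np.abs(res.absolute - analytic) / analytic < 0.02)

    def test_error_decreases_with_more_points(self):
        d = 4.0
        model = single_atom_model(n=2, spacing=d)
        R = 1.7 + 1.4
        analytic = 4 * np.pi * R**2 - 2 * np.pi * R * (R - d / 2)
        errs = [
            abs(sasa(model, n_points=n).absolute[0] - analytic) / analytic
            for n in (60, 960, 4000)
        ]
        assert errs[2] < errs[0]

    def test_additivity_total_equals_residue_sum(self):
        model, _ = make_toy_complex(12, 10, 0.4, seed=0)
        res = sasa(model)
        assert res.total() == pytest.approx(res.absolute.sum())

    def test_buried_in_complex_never_gains(self):
        model, _ = make_toy_complex(15, 12, 0.5, seed=3)
        together = sasa(model)
        for cid in ("A", "B"):
            alone = sasa(model.subset([cid]))
            mask = np.array([k[0] == cid for k in together.residue_keys])
            assert np.all(together.absolute[mask] <= alone.absolute + 1e-6)

    def test_n_points_floor(self):
        with pytest.raises(ValueError):
            sasa(single_atom_model(), n_points=5)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)


class TestExposure:
    def _result(self, relative):
        return SasaResult(
            residue_keys=[("A", i + 1) for i in range(len(relative))],
            residue_names=["A"] * len(relative),
            absolute=np.asarray(relative) * 129.0,
            relative=np.asarray(relative, dtype=float),
            probe=1.4,
            n_points=960,
        )

    def test_strict_threshold(self):
        flags = classify_exposure(self._result([0.50, 0.30, 0.0, 0.300001]))
        assert list(flags) == [True, False, False, True]

    def test_unknown_residue_type_errors(self):
        res = self._result([0.5])
        res.relative = np.array([np.nan])
        with pytest.raises(ValueError, match="max-ASA"):
            classify_exposure(res)


class TestInterface:
    def test_far_chains_no_interface(self):
        model, truth = make_toy_complex(8, 8, 0.5, seed=0, separation=100.0)
        maps = interface_sites(model, "A", "B")
        assert truth == {"A": set(), "B": set()}
        assert maps["A"].interface_residues() == set()
        assert maps["B"].interface_residues() == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_toy_complex_contact_set_recovered(self, seed):
        model, truth = make_toy_complex(25, 20, 0.3, seed=seed)
        maps = interface_sites(model, "A", "B")
        assert {c: maps[c].interface_residues() for c in "AB"} == truth

    def test_same_chain_errors(self):
        model, _ = make_toy_complex(8, 8, 0.5, seed=0)
        with pytest.raises(ValueError):
            interface_sites(model, "A", "A")

    def test_missing_chain_errors(self):
        model, _ = make_toy_complex(8, 8, 0.5, seed=0)
        with pytest.raises(KeyError):
            interface_sites(model, "A", "C")

    def test_delta_sasa_nonnegative_within_tolerance(self):
        model, _ = make_toy_complex(20, 16, 0.4, seed=1)
        maps = interface_sites(model, "A", "B")
        for m in maps.values():
            assert np.all(m.delta_sasa >= -1e-6)


class TestReadWrite:
    def test_pdb_round_trip(self, tmp_path):
        model, _ = make_toy_complex(6, 5, 0.5, seed=4)
        path = tmp_path / "toy.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert [c.id for c in back.chains] == ["A", "B"]
        assert back.n_atoms() == model.n_atoms()
        orig = model.chains[0].residues[0].atoms[0].coords
        got = back.chains[0].residues[0].atoms[0].coords
        assert np.allclose(orig, got, atol=1e-3)

    def test_waters_skipped(self, tmp_path):
        path = tmp_path / "wat.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        model = read_structure(path)
        assert model.n_atoms() == 1

    def test_minimal_single_atom(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\nEND\n"
        )
        model = read_structure(path)
        assert model.n_atoms() == 1
        assert np.allclose(model.chains[0].residues[0].atoms[0].coords, [1.0, 2.0, 3.0])


class TestCompareHydrophobicity:
    def test_identical_proteins_all_zero(self):
        q = ProteinRecord(id="q", seq="MFLSK")
        strata = {i: i < 2 for i in range(5)}
        r = compare_hydrophobicity(q, q, [(i, i) for i in range(5)], strata)
        assert r.fraction_in == 0.0 and r.fraction_out == 0.0
        assert r.test is not None and r.test.degenerate

    def test_constructed_contingency_matches_oracle(self):
        # 20 exposed sites with 9 increases; 20 buried with 3 increases.
        # query L (3.8) vs subject A (1.8) = increase; S vs F = decrease.
        q_seq = "L" * 9 + "S" * 11 + "L" * 3 + "S" * 17
        s_seq = "A" * 9 + "F" * 11 + "A" * 3 + "F" * 17
        q = ProteinRecord(id="q", seq=q_seq)
        s = ProteinRecord(id="s", seq=s_seq)
        strata = {i: i < 20 for i in range(40)}
        r = compare_hydrophobicity(q, s, [(i, i) for i in range(40)], strata)
        assert r.fraction_in == pytest.approx(0.45)
        assert r.fraction_out == pytest.approx(0.15)
        oracle = two_by_two_test([[9, 11], [3, 17]])
        assert r.test.statistic == pytest.approx(oracle.statistic)
        assert r.test.p == pytest.approx(oracle.p)

    def test_subject_always_more_hydrophobic(self):
        q = ProteinRecord(id="q", seq="SSSS")
        s = ProteinRecord(id="s", seq="FFFF")
        strata = {0: True, 1: True, 2: False, 3: False}
        r = compare_hydrophobicity(q, s, [(i, i) for i in range(4)], strata)
        assert r.fraction_in == 0.0 and r.fraction_out == 0.0

    def test_empty_stratum_warns_and_skips_test(self):
        q = ProteinRecord(id="q", seq="LS")
        s = ProteinRecord(id="s", seq="AS")
        with pytest.warns(UserWarning, match="empty stratum"):
            r = compare_hydrophobicity(q, s, [(0, 0), (1, 1)], {0: True, 1: True})
        assert r.test is None

    def test_editing_contrast(self):
        q = ProteinRecord(id="q", seq="LLSS")
        s = ProteinRecord(id="s", seq="AAFF")
        strata = {0: True, 1: True, 2: False, 3: False}
        edited = {0: True, 1: False, 2: True, 3: True}
        r = compare_hydrophobicity(q, s, [(i, i) for i in range(4)], strata,
                                   edited_flags=edited)
        assert r.editing_fraction_in == pytest.approx(0.5)
        assert r.editing_fraction_out == pytest.approx(1.0)


class TestHelperAligner:
    def test_identical_sequences_align_site_to_site(self):
        p = ProteinRecord(id="a", seq="MKTFFLSWVD")
        pairs = align_proteins(p, ProteinRecord(id="b", seq="MKTFFLSWVD"))
        assert pairs == [(i, i) for i in range(10)]

    def test_internal_deletion_shifts_pairing(self):
        q = ProteinRecord(id="a", seq="MKTAYFLSWVD")
        s = ProteinRecord(id="b", seq="MKTFLSWVD")
        pairs = dict(align_proteins(q, s))
        assert pairs[0] == 0 and pairs[10] == 8
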