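import numpy as np
import pytest

from g4kit._geometry import rotation_about_axis
from g4kit.ensemble_metrics import (
    ensemble_rmsd,
    interproton_distance_stats,
    resolve_selection,
    ring_proximity,
    superpose,
    survey_vloop_puckers,
)
from g4kit.structure_io import Atom, Residue, StructureEnsemble
from g4kit.synthetic import build_nucleotide, build_quadruplex, perturb_ensemble, preset


@pytest.fixture(scope="module")
def noisy_vloop():
    return perturb_ensemble(build_quadruplex(preset("vloop-ODN1415")), 5, 0.15, seed=21)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(3).normal(size=(8, 3))
        s = superpose(pts, pts)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(s.rotation, np.eye(3), atol=1e-9)

    def test_recovers_rigid_motion(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 3))
        R = rotation_about_axis([0.2, 1, -1], 83.0)
        t = np.array([4.0, 5.0, -6.0])
        s = superpose(pts, pts @ R.T + t)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(s.rotation, R, atol=1e-9)
        assert np.allclose(s.translation, t, atol=1e-9)

    def test_collinear_degenerate(self):
        pts = np.array([[float(i), 0, 0] for i in range(5)])
        with pytest.raises(ValueError):
            superpose(pts, pts + 2.0)


class TestEnsembleRmsd:
    def test_identical_models_zero(self):
        ens = build_quadruplex(preset("parallel"))
        ens2 = perturb_ensemble(ens, 4, 0.0, seed=0)
        for mode in ("pairwise", "to_mean"):
            assert ensemble_rmsd(ens2, "all@heavy", mode).rmsd_mean == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_symmetric_matrix(self, noisy_vloop):
        stats = ensemble_rmsd(noisy_vloop, "all@heavy", "pairwise")
        mat = np.array(stats.rmsd_matrix)
        assert np.allclose(mat, mat.T, atol=1e-9)
        assert np.allclose(np.diag(mat), 0.0, atol=1e-12)

    def test_to_mean_not_larger_than_pairwise(self, noisy_vloop):
        pw = ensemble_rmsd(noisy_vloop, "all@heavy", "pairwise").rmsd_mean
        tm = ensemble_rmsd(noisy_vloop, "all@heavy", "to_mean").rmsd_mean
        assert tm <= pw + 1e-9

    def test_core_selection_smaller_than_all(self, noisy_vloop):
        core = resolve_selection(noisy_vloop, "core@heavy")
        allsel = resolve_selection(noisy_vloop, "all@heavy")
        assert 0 < len(core) < len(allsel)
        core_res = {s for s, _, _ in core}
        assert core_res == {1, 2, 6, 7, 8, 14, 15, 16, 17, 20, 21, 22}

    def test_selection_ranges_and_globs(self, noisy_vloop):
        sel = resolve_selection(noisy_vloop, "14-15@F2'")
        assert {s for s, _, _ in sel} == {14, 15}
        assert all(n == "F2'" for _, _, n in sel)

    def test_global_rigid_motion_invariance(self, noisy_vloop):
        R = rotation_about_axis([1, 0, 2], 31.0)
        t = np.array([7.0, -2.0, 1.0])
        moved_models = []
        for m in noisy_vloop.models:
            moved_models.append([
                Residue(
                    chain_id=r.chain_id, seq_index=r.seq_index, name=r.name,
                    base_type=r.base_type, variant=r.variant,
                    atoms={
                        n: Atom(a.name, a.element, tuple(R @ np.asarray(a.xyz) + t))
                        for n, a in r.atoms.items()
                    },
                )
                for r in m
            ])
        moved = StructureEnsemble(models=moved_models, source_id="moved")
        a = ensemble_rmsd(noisy_vloop, "all@heavy", "pairwise").rmsd_mean
        b = ensemble_rmsd(moved, "all@heavy", "pairwise").rmsd_mean
        assert a == pytest.approx(b, abs=1e-9)


class TestInterprotonDistances:
    def _fixed_pair(self, dists):
        models = []
        for d in dists:
            r1 = Residue("A", 1, "DG", atoms={"H8": Atom("H8", "H", (0.0, 0.0, 0.0))})
            r2 = Residue("A", 2, "DG", atoms={"H2'": Atom("H2'", "H", (d, 0.0, 0.0))})
            models.append([r1, r2])
        return StructureEnsemble(models=models)

    def test_fixed_distance(self):
        st = interproton_distance_stats(self._fixed_pair([3.0, 3.0]), (1, "H8"), (2, "H2'"))
        assert (st["min"], st["mean"], st["max"]) == (3.0, 3.0, 3.0)

    def test_two_model_stats(self):
        st = interproton_distance_stats(self._fixed_pair([2.0, 4.0]), (1, "H8"), (2, "H2'"))
        assert st["min"] == 2.0 and st["max"] == 4.0 and st["mean"] == 3.0

    def test_proton_reconstruction_flagged(self):
        nt = build_nucleotide(18, 38, -120.0, "G", "deoxy")
        stripped = Residue(
            chain_id="A", seq_index=1, name="DG", base_type="G",
            atoms={n: a for n, a in nt.atoms.items() if a.element != "H"},
        )
        full = Residue(
            chain_id="A", seq_index=2, name="DG", base_type="G",
            atoms={
                n: Atom(a.name, a.element, tuple(np.asarray(a.xyz) + [20.0, 0, 0]))
                for n, a in nt.atoms.items()
            },
        )
        ens = StructureEnsemble(models=[[stripped, full]])
        st = interproton_distance_stats(ens, (1, "H8"), (2, "H8"))
        assert st["protons_rebuilt"]
        # rebuilt H8 should sit close to the true in-plane position
        true = np.asarray(nt.atoms["H8"].xyz)
        rebuilt_dist = st["per_model"][0]
        ref = np.linalg.norm(true - (true + [20.0, 0, 0]))
        assert st["per_model"][0] == pytest.approx(ref, abs=0.5)


class TestRingProximity:
    def test_proton_on_normal(self):
        nt = build_nucleotide(18, 38, 60.0, "G", "deoxy")
        from g4kit.conformer_classify import base_plane

        bp = base_plane(nt)
        probe = np.asarray(bp.centroid6) + 2.0 * np.asarray(bp.normal)
        r2 = Residue("A", 99, "DG", atoms={"HX": Atom("HX", "H", tuple(probe))})
        ens = StructureEnsemble(models=[[nt, r2]])
        out = ring_proximity(ens, (99, "HX"), 1)
        assert out[0]["centroid_distance"] == pytest.approx(2.0, abs=1e-9)
        assert out[0]["height"] == pytest.approx(2.0, abs=1e-9)
        assert not out[0]["in_plane"]

    def test_in_plane_proton(self):
        nt = build_nucleotide(18, 38, 60.0, "G", "deoxy")
        from g4kit.conformer_classify import base_plane

        bp = base_plane(nt)
        normal = np.asarray(bp.normal)
        lateral = np.cross(normal, [1.0, 0.0, 0.0])
        lateral /= np.linalg.norm(lateral)
        probe = np.asarray(bp.centroid6) + 3.0 * lateral
        r2 = Residue("A", 99, "DG", atoms={"HX": Atom("HX", "H", tuple(probe))})
        ens = StructureEnsemble(models=[[nt, r2]])
        out = ring_proximity(ens, (99, "HX"), 1)
        assert out[0]["centroid_distance"] == pytest.approx(3.0, abs=1e-9)
        assert out[0]["height"] == pytest.approx(0.0, abs=1e-9)
        assert out[0]["in_plane"]


class TestSurvey:
    def test_rows_match_construction(self):
        # mild noise: the pseudorotation phase is a stiff function of the
        # coordinates, so survey tolerances must stay generous
        noisy = perturb_ensemble(
            build_quadruplex(preset("vloop-ODN1415")), 5, 0.05, seed=21
        )
        rows = survey_vloop_puckers([noisy])
        pre = [r for r in rows if r.role == "preceding_vloop"]
        post = [r for r in rows if r.role == "following_vloop"]
        assert len(pre) == len(post) == noisy.n_models
        assert all(r.residue == 14 for r in pre)
        assert all(r.residue == 15 for r in post)
        for r in rows:
            d = min(abs(r.P - 54.0), 360.0 - abs(r.P - 54.0))
            assert d < 25.0  # generated at P=54, loose bound under noise

    def test_non_g4_skipped_with_warning(self, caplog):
        nt = build_nucleotide(18, 38, 60.0, "G", "deoxy")
        ens = StructureEnsemble(models=[[nt]], source_id="lonely")
        with caplog.at_level("WARNING", logger="g4kit.ensemble_metrics"):
            rows = survey_vloop_puckers([ens])
        assert rows == []
        assert any("lonely" in rec.message for rec in caplog.records)

    def test_parallel_has_no_rows(self):
        ens = build_quadruplex(preset("parallel"))
        ens5 = perturb_ensemble(ens, 2, 0.05, seed=1)
        assert survey_vloop_puckers([ens5]) == []
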