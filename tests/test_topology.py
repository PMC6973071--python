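import numpy as np
import pytest

from g4kit._geometry import rotation_about_axis
from g4kit.g4_topology import (
    AmbiguityError,
    GeometryCutoffs,
    HoogsteenEdge,
    analyze_topology,
    detect_hoogsteen_pairs,
    detect_tetrads,
    stack_tetrads,
)
from g4kit.structure_io import Atom, Residue, StructureEnsemble
from g4kit.synthetic import build_quadruplex, preset, perturb_ensemble


def _apply_rigid(model, R, t):
    out = []
    for r in model:
        atoms = {
            n: Atom(a.name, a.element, tuple(R @ np.asarray(a.xyz) + t))
            for n, a in r.atoms.items()
        }
        out.append(
            Residue(
                chain_id=r.chain_id, seq_index=r.seq_index, name=r.name,
                base_type=r.base_type, variant=r.variant, atoms=atoms,
            )
        )
    return out


class TestHoogsteenDetection:
    def test_ideal_tetrad_single_cycle(self, preset_ensembles):
        # one tetrad layer in isolation: take the parallel preset's top
        # tetrad residues only
        model = [
            r for r in preset_ensembles["parallel"].models[0]
            if r.seq_index in (1, 5, 9, 13)
        ]
        edges = detect_hoogsteen_pairs(model)
        assert len(edges) == 4
        tetrads = detect_tetrads(edges)
        assert len(tetrads) == 1

    def test_translated_base_breaks_cycle(self, preset_ensembles):
        model = [
            r for r in preset_ensembles["parallel"].models[0]
            if r.seq_index in (1, 5, 9, 13)
        ]
        broken = []
        for r in model:
            if r.seq_index == 9:
                atoms = {
                    n: Atom(a.name, a.element, tuple(np.asarray(a.xyz) + [0, 0, 5.0]))
                    for n, a in r.atoms.items()
                }
                r = Residue(
                    chain_id=r.chain_id, seq_index=r.seq_index, name=r.name,
                    base_type=r.base_type, variant=r.variant, atoms=atoms,
                )
            broken.append(r)
        edges = detect_hoogsteen_pairs(broken)
        assert len(edges) == 2
        assert detect_tetrads(edges) == []

    def test_full_model_edge_count(self, vloop_model):
        edges = detect_hoogsteen_pairs(vloop_model)
        assert len(edges) == 12  # 3 tetrads x 4 edges

    def test_three_cycle_gives_no_tetrad(self):
        edges = [
            HoogsteenEdge(1, 2, ()),
            HoogsteenEdge(2, 3, ()),
            HoogsteenEdge(3, 1, ()),
        ]
        assert detect_tetrads(edges) == []

    def test_ambiguity_error(self):
        edges = [HoogsteenEdge(a, b, ()) for a, b in
                 [(1, 2), (2, 3), (3, 4), (4, 1), (2, 1), (1, 4), (4, 3), (3, 2)]]
        # both directed 4-cycles share the same residue set -> deduplicated
        assert len(detect_tetrads(edges)) == 1
        edges += [HoogsteenEdge(a, b, ()) for a, b in
                  [(1, 5), (5, 6), (6, 7), (7, 1)]]
        with pytest.raises(AmbiguityError):
            detect_tetrads(edges)


class TestOracleEquivalence:
    """Detected topology must equal the generating specification."""

    @pytest.mark.parametrize("name", ["parallel", "hybrid-ODN", "vloop-ODN1415", "vloop-typeB"])
    def test_full_equivalence(self, name, preset_specs, preset_ensembles):
        spec = preset_specs[name]
        topo = analyze_topology(preset_ensembles[name].models[0])
        assert [list(t.cycle) for t in topo.tetrads] == spec.expected_tetrads()
        assert topo.stacking == spec.expected_stacking()
        expected_orient = spec.expected_column_orientations()
        for i, col in enumerate(topo.columns):
            assert col.orientation == expected_orient[i], f"column {i}"
        assert [l.cls for l in topo.loops] == spec.expected_loop_classes()
        got_grooves = {k: v["label"] for k, v in topo.grooves.items()}
        assert got_grooves == spec.expected_grooves

    def test_parallel_columns_unbroken_no_inversions(self, preset_ensembles):
        topo = analyze_topology(preset_ensembles["parallel"].models[0])
        for col in topo.columns:
            assert not col.broken
            assert col.inversions == ()
            assert col.orientation == "up"

    def test_vloop_broken_column_and_inversion(self, preset_ensembles):
        topo = analyze_topology(preset_ensembles["vloop-ODN1415"].models[0])
        broken = [c for c in topo.columns if c.broken]
        assert len(broken) == 1
        assert set(broken[0].residues) == {1, 2, 14}
        inv = [c for c in topo.columns if c.inversions]
        assert len(inv) == 1
        assert set(inv[0].residues) == {15, 16, 17}
        assert inv[0].inversions == ((0, 1),)  # between residues 15 and 16

    def test_vloop_record_type_a(self, preset_ensembles):
        topo = analyze_topology(preset_ensembles["vloop-ODN1415"].models[0])
        assert len(topo.vloops) == 1
        v = topo.vloops[0]
        assert (v.anchor5, v.anchor3, v.n_intervening) == (14, 15, 0)
        assert v.chi5.cls == "syn"
        assert v.chi3.cls == "anti"
        assert v.turn_locus == "within_following_tract"
        assert v.pucker5.octant == "north-east"

    def test_vloop_record_type_b(self, preset_ensembles):
        topo = analyze_topology(preset_ensembles["vloop-typeB"].models[0])
        assert len(topo.vloops) == 1
        assert topo.vloops[0].turn_locus == "between_linked_residues"

    def test_no_vloops_in_parallel_and_hybrid(self, preset_ensembles):
        for name in ("parallel", "hybrid-ODN"):
            topo = analyze_topology(preset_ensembles[name].models[0])
            assert topo.vloops == []

    def test_residues_in_at_most_one_tetrad(self, preset_ensembles):
        for name, ens in preset_ensembles.items():
            topo = analyze_topology(ens.models[0])
            seen = [i for t in topo.tetrads for i in t.cycle]
            assert len(seen) == len(set(seen))
            assert len(topo.columns) == 4


class TestInvariances:
    def test_rigid_motion_invariance(self, vloop_model):
        topo0 = analyze_topology(vloop_model)
        R = rotation_about_axis([1, -2, 0.5], 77.0)
        moved = _apply_rigid(vloop_model, R, np.array([10.0, -4.0, 3.0]))
        topo1 = analyze_topology(moved)
        assert [t.cycle for t in topo1.tetrads] == [t.cycle for t in topo0.tetrads]
        assert topo1.stacking == topo0.stacking
        assert [c.residues for c in topo1.columns] == [c.residues for c in topo0.columns]
        assert [c.orientation for c in topo1.columns] == [c.orientation for c in topo0.columns]
        assert {k: v["label"] for k, v in topo1.grooves.items()} == {
            k: v["label"] for k, v in topo0.grooves.items()
        }
        assert [l.cls for l in topo1.loops] == [l.cls for l in topo0.loops]

    def test_per_model_analysis_independent_of_model_order(self, preset_ensembles):
        ens = perturb_ensemble(preset_ensembles["vloop-ODN1415"], 3, 0.1, seed=2)
        topos = [analyze_topology(m) for m in ens.models]
        topos_rev = [analyze_topology(m) for m in reversed(ens.models)]
        assert [t.vloops[0].anchor5 for t in topos] == [
            t.vloops[0].anchor5 for t in reversed(topos_rev)
        ]

    def test_stacking_senses(self, preset_ensembles):
        topo = analyze_topology(preset_ensembles["parallel"].models[0])
        assert topo.stacking == ["homopolar", "homopolar"]
        topo_v = analyze_topology(preset_ensembles["vloop-ODN1415"].models[0])
        assert topo_v.stacking == ["heteropolar", "homopolar"]


def test_reverse_donor_convention_flips_cycles(vloop_model):
    normal = analyze_topology(vloop_model)
    rev = analyze_topology(
        vloop_model, GeometryCutoffs(reverse_donor_convention=True)
    )
    fwd = normal.tetrads[0].cycle
    back = rev.tetrads[0].cycle
    assert fwd[0] == back[0]
    assert list(back[1:]) == list(reversed(fwd[1:]))
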