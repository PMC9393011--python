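"""Tree and painting machinery: parsing, painting, shared-time matrices."""

import numpy as np
import pytest

from bmhet.trees import (
    NewickParseError,
    PaintingError,
    paint_clade,
    paint_from_reconstruction,
    paint_uniform,
    parse_newick,
    parse_simmap,
    rescale_to_height,
    shared_time_matrices,
    write_newick,
    write_simmap,
)
from bmhet.simulate import sim_pure_birth

from conftest import random_painted


class TestNewick:
    def test_three_tip_ultrametric(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.tip_labels == ["A", "B", "C"]
        d = t.depths()
        assert all(d[tip] == 2 for tip in t.tips())

    def test_single_tip(self):
        t = parse_newick("(A:1);")
        assert t.tip_labels == ["A"]
        assert t.height == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_exact(self, seed):
        t = sim_pure_birth(100, seed=seed)
        t2 = parse_newick(write_newick(t))
        d1, d2 = t.depths(), t2.depths()
        for a, b in zip(t.preorder(), t2.preorder()):
            assert a.length == b.length
            assert d1[a] == d2[b]

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        text = "((A:0.25,B:1.5):0.75,(C:0.4,D:2.0):1.1);"
        ours = parse_newick(text)
        ref = dendropy.Tree.get(data=text, schema="newick")
        ref_depths = {
            leaf.taxon.label: leaf.distance_from_root()
            for leaf in ref.leaf_node_iter()
        }
        d = ours.depths()
        for tip in ours.tips():
            assert d[tip] == pytest.approx(ref_depths[tip.label], abs=1e-12)

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,B:1):1", "(A:1,B:1));", "(A,B);", "(A:1 B:2);"],
    )
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises((NewickParseError, ValueError)) as err:
            parse_newick(bad)
        # missing-length trees are rejected too, but without an offset
        if isinstance(err.value, NewickParseError) and err.value.offset is not None:
            assert "offset" in str(err.value)


class TestSimmap:
    def test_direct_reading(self):
        pt = parse_simmap("(A:{0,0.5:1,0.5},B:{0,1.0});")
        a, b = pt.tips()
        assert a.segments == [("0", 0.5), ("1", 0.5)]
        assert b.segments == [("0", 1.0)]
        assert pt.regimes == ["0", "1"]

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_segments(self, seed):
        pt = random_painted(40, 3, seed)
        pt2 = parse_simmap(write_simmap(pt))
        for a, b in zip(pt.preorder(), pt2.preorder()):
            assert a.segments == b.segments

    def test_tipward_order_dialect(self):
        rootward = parse_simmap("(A:{0,0.5:1,1.5},B:{0,2.0});")
        tipward = parse_simmap(
            "(A:{1,1.5:0,0.5},B:{0,2.0});", segment_order="tipward"
        )
        for a, b in zip(rootward.preorder(), tipward.preorder()):
            assert a.segments == b.segments

    def test_single_regime_collapses_to_C(self):
        pt = parse_simmap("((A:{x,1},B:{x,1}):{x,1},C:{x,2});")
        stm = shared_time_matrices(pt)
        assert stm.regimes == ("x",)
        expected = np.array([[2, 1, 0], [1, 2, 0], [0, 0, 2]], dtype=float)
        np.testing.assert_allclose(stm.matrix("x"), expected)

    def test_bad_segment_sum_rejected(self):
        with pytest.raises((NewickParseError, PaintingError)):
            parse_simmap("(A:{0,0.5:1,0.5}:2.0,B:{0,2.0});")

    def test_empty_annotation_rejected(self):
        with pytest.raises(NewickParseError):
            parse_simmap("(A:{},B:{0,1.0});")


class TestPainting:
    def test_clade_midpoint_stem(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        pt = paint_clade(t, t.mrca(["A", "B"]), "derived", "base", 0.5)
        stem = [n for n in pt.edges() if not n.is_tip][0]
        assert stem.segments == [("base", 0.5), ("derived", 0.5)]
        for tip in pt.tips():
            if tip.label in ("A", "B"):
                assert tip.segments == [("derived", 1.0)]
            else:
                assert tip.segments == [("base", 2.0)]

    def test_zero_shift_fraction_paints_whole_stem(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        pt = paint_clade(t, ["A", "B"], "derived", "base", shift_fraction=0.0)
        stem = [n for n in pt.edges() if not n.is_tip][0]
        assert stem.segments == [("derived", 1.0)]

    def test_painting_conserves_total_shared_time(self):
        t = sim_pure_birth(30, seed=5)
        node = t.mrca(t.tip_labels[:8])
        pt = paint_clade(t, node, "d", "b", 0.5)
        stm = shared_time_matrices(pt)
        base = shared_time_matrices(paint_uniform(t, "u"))
        np.testing.assert_allclose(stm.total, base.total, atol=1e-12)

    def test_reconstruction_midpoint(self):
        t = parse_newick("(A:2,B:2);")
        root = t.root
        a, b = t.tips()
        pt = paint_from_reconstruction(t, {root: "A", a: "B", b: "A"})
        assert pt.tips()[0].segments == [("A", 1.0), ("B", 1.0)]
        assert pt.tips()[1].segments == [("A", 2.0)]

    def test_reconstruction_uniform_when_all_same(self):
        t = sim_pure_birth(10, seed=1)
        states = {n: "s" for n in t.preorder()}
        pt = paint_from_reconstruction(t, states)
        assert pt.regimes == ["s"]

    def test_transition_count_matches_reconstruction(self):
        t = sim_pure_birth(20, seed=2)
        rng = np.random.default_rng(3)
        states = {}
        for n in t.preorder():
            states[n] = str(rng.integers(2))
        pt = paint_from_reconstruction(t, states)
        expected = sum(
            1 for n in t.edges() if states[n] != states[n.parent] and n.length > 0
        )
        assert pt.n_transitions() == expected

    def test_missing_state_raises(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            paint_from_reconstruction(t, {t.tips()[0]: "x"})


class TestRescale:
    def test_linear_scaling(self):
        pt = random_painted(10, 2, seed=4)
        half = rescale_to_height(pt, pt.height / 2)
        for a, b in zip(pt.preorder(), half.preorder()):
            if not a.is_root:
                assert b.length == pytest.approx(a.length / 2)
                for (sa, da), (sb, db) in zip(a.segments, b.segments):
                    assert sa == sb and db == pytest.approx(da / 2)
        assert half.height == pytest.approx(pt.height / 2)

    def test_zero_height_rejected(self):
        t = parse_newick("(A:0.0,B:0.0);")
        with pytest.raises(ValueError):
            rescale_to_height(t, 1.0)


class TestSharedTime:
    def test_two_tip_split_at_root(self):
        pt = parse_simmap("(A:{A,0.5:B,0.5},B:{A,0.5:B,0.5});")
        stm = shared_time_matrices(pt)
        np.testing.assert_allclose(stm.matrix("A"), np.diag([0.5, 0.5]))
        np.testing.assert_allclose(stm.matrix("B"), np.diag([0.5, 0.5]))

    @pytest.mark.parametrize("seed", range(50))
    def test_conservation_over_random_paintings(self, seed):
        pt = random_painted(12, 3, seed)
        stm = shared_time_matrices(pt)
        base = shared_time_matrices(paint_uniform(pt, "all"))
        np.testing.assert_allclose(stm.total, base.total, atol=1e-10)
        assert (stm.stack >= -1e-15).all()
        for k in range(stm.stack.shape[0]):
            np.testing.assert_allclose(stm.stack[k], stm.stack[k].T, atol=1e-12)
            eig = np.linalg.eigvalsh(stm.stack[k])
            assert eig.min() >= -1e-9

    def test_taxon_order_permutes_rows(self):
        pt = random_painted(10, 2, seed=9)
        taxa = pt.tip_labels
        perm = taxa[::-1]
        stm = shared_time_matrices(pt, taxa)
        stm_perm = shared_time_matrices(pt, perm)
        idx = [taxa.index(t) for t in perm]
        np.testing.assert_allclose(
            stm_perm.stack, stm.stack[:, idx][:, :, idx], atol=1e-12
        )
        np.testing.assert_allclose(
            stm.reorder(perm).stack, stm_perm.stack, atol=1e-12
        )

    def test_unknown_taxon_raises(self):
        pt = random_painted(5, 2, seed=0)
        with pytest.raises(KeyError):
            shared_time_matrices(pt, pt.tip_labels + ["nope"])
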