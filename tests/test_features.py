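import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from srcshave import (
    GeneMap,
    combine_features,
    extract_features,
    orient_significance,
    scale_rows,
)
from srcshave.features import FeatureMatrix, minmax_rows

from conftest import make_dataset


class TestExtractFeatures:
    def test_perfect_separation(self):
        ds = make_dataset([[0, 0, 0, 1, 1, 1]], [0, 0, 0, 1, 1, 1])
        f = extract_features(ds).features[:, 0]
        assert np.allclose(f, [0.0, 0.0, 1.0, 1.0, np.sqrt(3)])

    def test_constant_variable(self):
        ds = make_dataset([[5, 5, 5, 5, 5, 5]], [0, 0, 0, 1, 1, 1])
        f = extract_features(ds).features[:, 0]
        assert np.allclose(f, [0.0, 0.0, 0.0, 0.0, 5 * np.sqrt(6)])

    def test_against_direct_pearson_formula(self):
        # controls [1,2,3], cases [4,5,6]: the point-biserial correlation
        # computed from explicit sums over the 6 paired points
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        expected_corr = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        ds = make_dataset([x], y.astype(int))
        f = extract_features(ds).features[:, 0]
        assert np.allclose(f[:3], [1.0, 1.0, 3.0])
        assert f[3] == pytest.approx(expected_corr, abs=1e-12)
        assert f[4] == pytest.approx(np.linalg.norm(x), abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(7, 12))
        status = np.array([0] * 6 + [1] * 6)
        perm = rng.permutation(12)
        a = extract_features(make_dataset(vals, status)).features
        b = extract_features(make_dataset(vals[:, perm], status[perm])).features
        assert np.allclose(a, b)

    def test_corr_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(3, 10))
        status = np.array([0] * 5 + [1] * 5)
        base = extract_features(make_dataset(vals, status)).features[3]
        scaled = extract_features(make_dataset(7.5 * vals - 3.0, status)).features[3]
        assert np.allclose(base, scaled, atol=1e-10)


class TestScaleAndOrient:
    def test_affine_map(self):
        fm = FeatureMatrix(np.array([[1.0, 3.0, 5.0]] * 5), ("a", "b", "c"),
                           (None,) * 3)
        assert np.allclose(scale_rows(fm).features[0], [0, 0.5, 1])

    def test_constant_row_maps_to_half(self):
        fm = FeatureMatrix(np.full((5, 3), 2.0), ("a", "b", "c"), (None,) * 3)
        assert np.allclose(scale_rows(fm).features, 0.5)

    def test_rescaling_scaled_matrix_is_idempotent(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.uniform(size=(5, 8)), tuple("abcdefgh"), (None,) * 8)
        once = scale_rows(fm)
        twice = scale_rows(once)
        assert np.allclose(once.features, twice.features)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (5, 4), elements=st.floats(-1e6, 1e6)))
    def test_scaled_entries_lie_in_unit_interval(self, M):
        fm = FeatureMatrix(M, ("a", "b", "c", "d"), (None,) * 4)
        S = scale_rows(fm).features
        assert np.all(S >= 0) and np.all(S <= 1)

    def test_orientation_flips_spread_entries_only(self):
        block = np.array([[0.0], [0.0], [1.0], [1.0], [1.0]])
        fm = FeatureMatrix(block, ("a",), (None,), scaled=True)
        assert np.allclose(orient_significance(fm).features[:, 0], 1.0)
        low = FeatureMatrix(1 - block, ("a",), (None,), scaled=True)
        assert np.allclose(orient_significance(low).features[:, 0], 0.0)

    def test_orientation_is_an_involution(self):
        rng = np.random.default_rng(2)
        fm = FeatureMatrix(rng.uniform(size=(10, 6)), tuple("abcdef"), (None,) * 6,
                           scaled=True)
        again = orient_significance(orient_significance(fm))
        assert np.allclose(again.features, fm.features)

    def test_orientation_requires_scaled(self):
        fm = FeatureMatrix(np.zeros((5, 2)), ("a", "b"), (None,) * 2, scaled=False)
        with pytest.raises(ValueError):
            orient_significance(fm)


def oriented_fm(ids, rng):
    fm = FeatureMatrix(rng.uniform(size=(5, len(ids))), tuple(ids),
                       (None,) * len(ids), scaled=True, oriented=True)
    return fm


class TestCombine:
    def test_cross_combination_counts(self):
        rng = np.random.default_rng(3)
        e = oriented_fm(["e1", "e2"], rng)
        s = oriented_fm(["s1", "s2", "s3"], rng)
        gmap = GeneMap(entries={"G1": (("e1", "e2"), ("s1", "s2", "s3"))})
        comb = combine_features(e, s, gmap)
        assert comb.p == 6 and comb.r == 10
        assert comb.genes == ("G1",) * 6

    def test_single_pair_stacks_blocks(self):
        rng = np.random.default_rng(4)
        e = oriented_fm(["e1"], rng)
        s = oriented_fm(["s1"], rng)
        gmap = GeneMap(entries={"G1": (("e1",), ("s1",))})
        comb = combine_features(e, s, gmap)
        assert comb.p == 1
        assert np.allclose(comb.features[:5, 0], e.features[:, 0])
        assert np.allclose(comb.features[5:, 0], s.features[:, 0])

    def test_no_joint_genes_gives_empty_matrix(self):
        rng = np.random.default_rng(5)
        e = oriented_fm(["e1"], rng)
        s = oriented_fm(["s1"], rng)
        gmap = GeneMap(entries={"G1": (("e1",), ()), "G2": ((), ("s1",))})
        assert combine_features(e, s, gmap).p == 0

    def test_column_count_matches_pair_sum(self):
        rng = np.random.default_rng(6)
        e = oriented_fm([f"e{i}" for i in range(6)], rng)
        s = oriented_fm([f"s{i}" for i in range(7)], rng)
        gmap = GeneMap(entries={
            "G1": (("e0", "e1"), ("s0",)),
            "G2": (("e2",), ("s1", "s2", "s3")),
            "G3": (("e3", "e4", "e5"), ("s4", "s5", "s6")),
        })
        expected = 2 * 1 + 1 * 3 + 3 * 3
        assert combine_features(e, s, gmap).p == expected

    def test_missing_id_is_error(self):
        rng = np.random.default_rng(7)
        e = oriented_fm(["e1"], rng)
        s = oriented_fm(["s1"], rng)
        gmap = GeneMap(entries={"G1": (("e1", "eX"), ("s1",))})
        with pytest.raises(KeyError):
            combine_features(e, s, gmap)


def test_feature_matrix_tsv_export(tmp_path):
    from srcshave.features import write_feature_matrix
    rng = np.random.default_rng(8)
    fm = FeatureMatrix(rng.uniform(size=(5, 2)), ("e1|s1", "e1|s2"), ("G1", "G1"),
                       scaled=True, oriented=True)
    path = tmp_path / "fm.tsv"
    write_feature_matrix(fm, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "key\te1|s1\te1|s2"
    assert lines[1] == "gene\tG1\tG1"
    assert len(lines) == 2 + fm.r


def test_minmax_rows_handles_mixed_constant_rows():
    M = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
    out = minmax_rows(M)
    assert np.allclose(out[0], [0, 0.5, 1])
    assert np.allclose(out[1], 0.5)
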