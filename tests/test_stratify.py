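import itertools

import numpy as np
import pandas as pd
import pytest

from pnstrat import (
    DataError,
    label_groups,
    merge_subgroups,
    pca_overlay,
    ward_cluster,
    zscore_genes,
)
from pnstrat.stratify import SampleGrouping

from conftest import make_expr


def grouping_from(labels: dict) -> SampleGrouping:
    series = pd.Series(labels)
    return SampleGrouping(labels=series, k=series.nunique())


def best_two_partition_ward(points: np.ndarray):
    """Brute force: the 2-partition minimising total within-cluster SSE."""
    n = len(points)
    best, best_cost = None, np.inf
    for mask_bits in range(1, 2 ** (n - 1)):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all() or not mask.any():
            continue
        cost = sum(((points[m] - points[m].mean(axis=0)) ** 2).sum()
                   for m in (mask, ~mask))
        if cost < best_cost:
            best_cost, best = cost, mask
    return best


class TestWardCluster:
    def test_duplicated_blocks_recovered(self):
        block1 = np.tile([[0.0], [0.0], [5.0]], (1, 4))
        block2 = block1 + 10.0
        data = pd.DataFrame(np.hstack([block1, block2]),
                            index=["g1", "g2", "g3"],
                            columns=[f"s{j}" for j in range(8)])
        out = ward_cluster(data, axis="samples", k=2)
        labels = out.labels
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[4]

    def test_1d_points_match_bruteforce_oracle(self):
        points = np.array([[0.0], [1.0], [10.0], [11.0]])
        data = pd.DataFrame(points.T, index=["g1"], columns=list("abcd"))
        out = ward_cluster(data, axis="samples", k=2)
        oracle = best_two_partition_ward(points)
        got = (out.labels == out.labels.iloc[0]).to_numpy()
        assert np.array_equal(got, oracle) or np.array_equal(got, ~oracle)
        assert out.labels["a"] == out.labels["b"]
        assert out.labels["c"] == out.labels["d"]
        assert out.labels["a"] != out.labels["c"]

    def test_k_equal_one(self):
        data = pd.DataFrame(np.arange(8.0).reshape(2, 4))
        out = ward_cluster(data, axis="samples", k=1)
        assert out.labels.nunique() == 1

    def test_k_too_large_rejected(self):
        data = pd.DataFrame(np.arange(8.0).reshape(2, 4))
        with pytest.raises(DataError):
            ward_cluster(data, axis="samples", k=5)

    def test_nonfinite_rejected(self):
        data = pd.DataFrame([[np.nan, 1.0], [0.0, 2.0]])
        with pytest.raises(DataError):
            ward_cluster(data, axis="samples", k=2)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.normal(size=(10, 30)))
        out = ward_cluster(data, axis="samples", k=3)
        heights = out.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-9).all()

    def test_row_order_invariance_up_to_relabel(self):
        rng = np.random.default_rng(5)
        values = np.vstack([rng.normal(0, 1, (3, 8)), rng.normal(6, 1, (3, 8))])
        data = pd.DataFrame(values.T, columns=[f"s{j}" for j in range(6)])
        out1 = ward_cluster(data, axis="samples", k=2)
        perm = rng.permutation(6)
        data2 = data.iloc[:, perm]
        out2 = ward_cluster(data2, axis="samples", k=2)
        s = out1.labels
        t = out2.labels.reindex(s.index)
        same = (s == s.iloc[0]).to_numpy()
        other = (t == t.iloc[0]).to_numpy()
        assert np.array_equal(same, other) or np.array_equal(same, ~other)


class TestLabelGroups:
    def residuals(self):
        # cluster-1 genes g1..g3 low in samples a,b; high in c,d
        values = np.array([
            [-1.0, -1.0, 1.0, 1.0],
            [-1.0, -1.0, 1.0, 1.0],
            [-1.0, -1.0, 1.0, 1.0],
            [0.3, 0.1, -0.2, 0.4],
        ])
        return pd.DataFrame(values, index=["g1", "g2", "g3", "g4"],
                            columns=list("abcd"))

    def gene_grouping(self):
        return grouping_from({"g1": "1", "g2": "1", "g3": "1", "g4": "2"})

    def test_lower_mean_side_is_A(self):
        samples = grouping_from({"a": "1", "b": "1", "c": "2", "d": "2"})
        out = label_groups(samples, self.gene_grouping(), self.residuals())
        assert out.labels.to_dict() == {"a": "A", "b": "A", "c": "B", "d": "B"}

    def test_k4_ordering_convention(self):
        values = np.array([[-2.0, -1.0, 1.0, 2.0]])
        data = pd.DataFrame(values, index=["g1"], columns=list("abcd"))
        samples = grouping_from({"a": "1", "b": "2", "c": "3", "d": "4"})
        genes = grouping_from({"g1": "1"})
        out = label_groups(samples, genes, data)
        assert out.labels.to_dict() == {"a": "A1", "b": "A2", "c": "B1", "d": "B2"}

    def test_sample_order_permutation_invariant(self):
        samples = grouping_from({"a": "1", "b": "1", "c": "2", "d": "2"})
        res = self.residuals()
        out1 = label_groups(samples, self.gene_grouping(), res)
        shuffled = SampleGrouping(labels=samples.labels.iloc[[3, 1, 0, 2]], k=2)
        out2 = label_groups(shuffled, self.gene_grouping(), res.iloc[:, ::-1])
        assert out1.labels.sort_index().equals(out2.labels.sort_index())


class TestMergeSubgroups:
    def test_printed_cohort_sizes(self):
        """Subgroups of 22/51/75/208 merge to groups of 73 and 283."""
        labels = {}
        i = 0
        for lab, n in [("A1", 22), ("A2", 51), ("B1", 75), ("B2", 208)]:
            for _ in range(n):
                labels[f"s{i}"] = lab
                i += 1
        grouping = grouping_from(labels)
        merged = merge_subgroups(grouping, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        assert merged.sizes() == {"A": 73, "B": 283}

    def test_identity_map(self):
        grouping = grouping_from({"a": "A", "b": "B"})
        out = merge_subgroups(grouping, {"A": "A", "B": "B"})
        assert out.labels.equals(grouping.labels)

    def test_missing_source_label_rejected(self):
        grouping = grouping_from({"a": "A", "b": "B"})
        with pytest.raises(DataError, match="B"):
            merge_subgroups(grouping, {"A": "A"})


class TestPcaOverlay:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(6, 5))
        values[:, 4] = values[:, 3]
        mat = make_expr(values, scale="log2")
        out = pca_overlay({"c": mat})
        np.testing.assert_allclose(
            out.loc["c:s3", ["PC1", "PC2"]].astype(float),
            out.loc["c:s4", ["PC1", "PC2"]].astype(float), atol=1e-10)

    def test_components_orthogonal(self):
        rng = np.random.default_rng(8)
        mat = make_expr(rng.normal(size=(10, 12)), scale="log2")
        out = pca_overlay({"c": mat}, n_components=3)
        comps = out.attrs["components"]
        gram = comps @ comps.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_pc1_matches_known_axis(self):
        """2-gene data stretched along (1, 1)/sqrt(2): PC1 parallel to it."""
        rng = np.random.default_rng(1)
        t = rng.normal(0, 5, 40)
        noise = rng.normal(0, 0.1, (2, 40))
        values = np.vstack([t, t]) + noise
        out = pca_overlay({"c": make_expr(values, scale="log2")})
        axis = np.array([1.0, 1.0]) / np.sqrt(2)
        cos = abs(out.attrs["components"][0] @ axis)
        assert cos > 0.999

    def test_disjoint_universes_rejected(self):
        m1 = make_expr(np.zeros((2, 3)), scale="log2", genes=["g1", "g2"])
        m2 = make_expr(np.zeros((2, 3)), scale="log2", genes=["h1", "h2"])
        with pytest.raises(DataError):
            pca_overlay({"a": m1, "b": m2})

    def test_cohort_tags_carried(self):
        m = make_expr(np.random.default_rng(0).normal(size=(3, 4)), scale="log2")
        out = pca_overlay({"x": m, "y": m})
        assert set(out["cohort"]) == {"x", "y"}


def test_zscore_rows_zero_mean_unit_sd():
    rng = np.random.default_rng(0)
    data = pd.DataFrame(rng.normal(2, 3, size=(5, 40)))
    z = zscore_genes(data)
    np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)
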