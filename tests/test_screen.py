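"""Differential CpG screening and hierarchical structure."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methpanel.screen import (
    cluster_cpgs,
    cluster_samples,
    differential_cpgs,
    filter_tss,
    mann_whitney,
)
from methpanel.simulate import CohortConfig, SampleAnnotation, generate_cohort


def exact_mwu_oracle(x, y):
    """Exact two-sided Mann-Whitney by enumerating every group assignment of
    the pooled values (valid without ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    total = comb(len(pooled), n1)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


def make_matrix(rows, samples):
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(
            [("c", i * 10) for i in range(len(rows))], names=["chrom", "pos"]
        ),
        columns=samples, dtype=float,
    )


def make_ann(n_pr, n_sd):
    return [SampleAnnotation(f"PR{i}", "PR") for i in range(n_pr)] + [
        SampleAnnotation(f"SD{i}", "SD") for i in range(n_sd)
    ]


class TestMannWhitney:
    def test_complete_separation_u_max(self):
        x = np.full(13, 0.9)
        y = np.full(12, 0.1)
        u, p = mann_whitney(x, y)
        assert u == 13 * 12
        assert p < 0.01

    def test_identical_value_sets_null(self):
        x = np.array([0.1, 0.2, 0.3])
        u, p = mann_whitney(x, x.copy())
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_example(self):
        u, p = mann_whitney(np.array([0.1, 0.2, 0.3]), np.array([0.4, 0.5, 0.6]))
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 orderings as extreme

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=6),
        st.lists(st.integers(0, 1000), min_size=2, max_size=6),
    )
    def test_matches_exact_enumeration_oracle(self, xs, ys):
        pooled = xs + ys
        if len(set(pooled)) != len(pooled):  # oracle assumes no ties
            return
        x, y = np.array(xs, float), np.array(ys, float)
        u, p = mann_whitney(x, y)
        u_o, p_o = exact_mwu_oracle(x, y)
        assert u == u_o
        assert p == pytest.approx(p_o)

    @given(
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8),
        st.lists(st.floats(0, 1, width=32), min_size=2, max_size=8),
    )
    def test_statistic_symmetry(self, xs, ys):
        x, y = np.array(xs), np.array(ys)
        u_xy, _ = mann_whitney(x, y)
        u_yx, _ = mann_whitney(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))


class TestDifferentialCpgs:
    def test_extreme_cpg_selected(self):
        ann = make_ann(13, 12)
        m = make_matrix([[0.9] * 13 + [0.1] * 12], [a.sample_id for a in ann])
        res = differential_cpgs(m, ann)
        assert len(res) == 1
        assert res.loc[0, "u_statistic"] == 156
        assert res.loc[0, "delta_beta"] == pytest.approx(0.8)

    def test_null_cpg_not_selected(self):
        ann = make_ann(3, 3)
        m = make_matrix([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]], [a.sample_id for a in ann])
        assert len(differential_cpgs(m, ann)) == 0

    def test_significant_set_monotone_in_alpha(self, cohort_small):
        betas, ann, _ = cohort_small
        small = differential_cpgs(betas, ann, alpha=0.005)
        large = differential_cpgs(betas, ann, alpha=0.05)
        small_keys = set(zip(small["chrom"], small["pos"]))
        large_keys = set(zip(large["chrom"], large["pos"]))
        assert small_keys <= large_keys

    def test_single_group_rejected(self):
        ann = [SampleAnnotation(f"PR{i}", "PR") for i in range(4)]
        m = make_matrix([[0.1, 0.2, 0.3, 0.4]], [a.sample_id for a in ann])
        with pytest.raises(ValueError, match="PR and SD"):
            differential_cpgs(m, ann)

    def test_undertested_cpgs_skipped_on_missingness(self):
        ann = make_ann(3, 3)
        row = [0.9, np.nan, np.nan, 0.1, 0.2, 0.3]
        m = make_matrix([row], [a.sample_id for a in ann])
        assert len(differential_cpgs(m, ann, alpha=1.0)) == 0  # n_pr < 2

    def test_bh_correction_is_more_conservative(self, cohort_small):
        betas, ann, _ = cohort_small
        raw = differential_cpgs(betas, ann, alpha=0.05)
        bh = differential_cpgs(betas, ann, alpha=0.05, correction="bh")
        assert len(bh) <= len(raw)


class TestFilterTss:
    def _results(self, positions):
        return pd.DataFrame(
            {"chrom": "chrS", "pos": positions,
             "u_statistic": 0.0, "p_value": 0.001, "delta_beta": 0.5,
             "n_pr": 5, "n_sd": 5}
        )

    def test_cpg_exactly_at_tss_kept_with_zero_window(self, ref_small):
        t = ref_small.tss[0]
        res = filter_tss(self._results([t.pos]), ref_small, window=0)
        assert len(res) == 1
        assert res.loc[0, "gene"] == t.gene

    def test_window_semantics(self, ref_small):
        t = ref_small.tss[0]
        near = self._results([t.pos + 10])
        assert len(filter_tss(near, ref_small, window=1000)) == 1
        assert len(filter_tss(near, ref_small, window=5)) == 0

    def test_matches_bruteforce_interval_check(self, ref_small, rng):
        positions = sorted(rng.integers(0, len(ref_small.seq), size=300).tolist())
        res = filter_tss(self._results(positions), ref_small, window=250)
        expected = [
            p for p in positions
            if any(abs(p - t.pos) <= 250 for t in ref_small.tss)
        ]
        assert sorted(res["pos"].tolist()) == sorted(expected)


class TestClusterCpgs:
    def test_two_leaf_merge_height_is_manhattan_distance(self):
        n = 24
        m = make_matrix([[0.0] * n, [1.0] * n], [f"s{i}" for i in range(n)])
        d = cluster_cpgs(m)
        assert d.linkage_matrix.shape == (1, 4)
        assert d.linkage_matrix[0, 2] == pytest.approx(n)

    def test_planted_two_block_recovery(self, rng):
        block1 = rng.uniform(0.7, 1.0, size=(5, 20))
        block2 = rng.uniform(0.0, 0.3, size=(5, 20))
        m = make_matrix(np.vstack([block1, block2]).tolist(), [f"s{i}" for i in range(20)])
        labels = cluster_cpgs(m).cut_k(2)
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_sample_permutation_invariant_topology(self, cohort_small):
        betas, _, _ = cohort_small
        sub = betas.iloc[:12]
        perm = sub[list(np.random.default_rng(3).permutation(sub.columns))]
        a = cluster_cpgs(sub).cut_k(3)
        b = cluster_cpgs(perm).cut_k(3)
        # identical partition of the leaves (labels may be renumbered)
        pairs_a = {(i, j) for i in a.index for j in a.index if a[i] == a[j]}
        pairs_b = {(i, j) for i in b.index for j in b.index if b[i] == b[j]}
        assert pairs_a == pairs_b

    def test_degenerate_identical_rows(self):
        m = make_matrix([[0.5] * 6] * 3, [f"s{i}" for i in range(6)])
        d = cluster_cpgs(m)
        assert np.allclose(d.linkage_matrix[:, 2], 0.0)

    def test_nested_list_serialization_covers_all_leaves(self, cohort_small):
        betas, _, _ = cohort_small
        d = cluster_cpgs(betas.iloc[:6])
        def flatten(node):
            if isinstance(node, list):
                return [x for child in node for x in flatten(child)]
            return [node]
        assert sorted(map(str, flatten(d.to_nested_lists()))) == sorted(map(str, d.labels))


class TestClusterSamples:
    def test_full_enrichment_gives_pure_top_cluster(self, ref_small):
        cfg = CohortConfig(
            n_responders=12, n_nonresponders=12, n_background_cpgs=80,
            enrichment=1.0, seed=31,
        )
        betas, ann = generate_cohort(ref_small, cfg)
        labels, summary = cluster_samples(betas, ann, k=2)
        top = summary[summary["cluster"] == 1].iloc[0]
        assert top["mean_beta"] > summary[summary["cluster"] == 2].iloc[0]["mean_beta"]
        assert top["n_sd"] == 0 and top["n_pr"] > 0

    def test_k1_single_cluster(self, cohort_small):
        betas, ann, _ = cohort_small
        labels, summary = cluster_samples(betas, ann, k=1)
        assert set(labels) == {1}
        assert summary.loc[0, "n"] == betas.shape[1]

    def test_enrichment_recovered_within_binomial_error(self, ref_small):
        n = 150
        cfg = CohortConfig(
            n_responders=n, n_nonresponders=n, n_background_cpgs=80,
            enrichment=0.8, seed=37,
        )
        betas, ann = generate_cohort(ref_small, cfg)
        _labels, summary = cluster_samples(betas, ann, k=2)
        top = summary[summary["cluster"] == 1].iloc[0]
        frac_pr = top["n_pr"] / (top["n_pr"] + top["n_sd"])
        se3 = 3 * np.sqrt(0.8 * 0.2 / n)
        # high cluster should hold ~enrichment share of the PR samples
        assert abs(top["n_pr"] / n - 0.8) <= se3
        assert frac_pr > 0.5
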