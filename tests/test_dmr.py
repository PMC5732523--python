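"""Block construction and differential-methylation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmarker import BetaDataset, adjust_fdr, block_stats, build_blocks, cpg_stats, feature_stats
from methmarker.dmr import Block


def _annotation(positions, chrom="chr1"):
    if isinstance(positions, dict):
        items = [(c, p) for c, ps in positions.items() for p in ps]
    else:
        items = [(chrom, p) for p in positions]
    return pd.DataFrame(
        {
            "chrom": [c for c, _ in items],
            "pos": [p for _, p in items],
            "gene": "G",
            "island_relation": "Island",
            "snp_in_primer": False,
            "prior_gene": False,
        },
        index=[f"cg{i:04d}" for i in range(len(items))],
    )


def brute_force_blocks(ann: pd.DataFrame, k: int, max_span: int):
    """Independent oracle: enumerate every consecutive k-tuple per chromosome."""
    out = set()
    for chrom, grp in ann.sort_values(["chrom", "pos"]).groupby("chrom"):
        pos = grp["pos"].tolist()
        ids = grp.index.tolist()
        for i in range(len(pos)):
            window = pos[i : i + k]
            if len(window) == k and window[-1] - window[0] < max_span:
                out.add(tuple(ids[i : i + k]))
    return out


class TestBuildBlocks:
    def test_single_window(self):
        ann = _annotation([10, 20, 30, 40, 50, 60])
        blocks = build_blocks(ann, k=6, max_span=1000)
        assert len(blocks) == 1
        assert blocks[0].span == 50
        assert blocks[0].cpg_ids == tuple(ann.index)

    def test_fewer_sites_than_window(self):
        assert build_blocks(_annotation([10, 20, 30, 40, 50]), k=6) == []

    def test_span_bound_is_strict(self):
        # span exactly equal to max_span is rejected
        ann = _annotation([0, 1, 2, 3, 4, 1000])
        assert build_blocks(ann, k=6, max_span=1000) == []
        ann2 = _annotation([0, 1, 2, 3, 4, 999])
        assert len(build_blocks(ann2, k=6, max_span=1000)) == 1

    def test_matches_brute_force_on_random_annotation(self, rng):
        positions = {
            f"chr{c}": sorted(rng.choice(100_000, size=50, replace=False))
            for c in (1, 2)
        }
        ann = _annotation(positions)
        got = {b.cpg_ids for b in build_blocks(ann, k=6, max_span=1000)}
        assert got == brute_force_blocks(ann, 6, 1000)

    def test_duplicate_position_rejected(self):
        ann = _annotation([10, 10, 30, 40, 50, 60])
        with pytest.raises(ValueError, match="duplicate"):
            build_blocks(ann)


class TestFeatureStats:
    def test_identical_groups(self):
        s = feature_stats([0.5, 0.5, 0.5], [0.5, 0.5])
        assert s.diff == 0
        assert s.fold_change == pytest.approx(1.0)
        assert s.p_value == pytest.approx(1.0)

    def test_exact_two_sided_p_for_extreme_ordering(self):
        # all 3 cases above both controls: one-sided 1/C(5,2)=1/10, two-sided 0.2
        s = feature_stats([0.8, 0.7, 0.9], [0.1, 0.2])
        assert s.p_value == pytest.approx(0.2)
        assert s.mcam == pytest.approx(0.8)
        assert s.mcom == pytest.approx(0.15)

    def test_missing_values_excluded(self):
        s = feature_stats([0.8, np.nan, 0.7, 0.9], [0.1, 0.2, np.nan])
        assert s.p_value == pytest.approx(0.2)

    def test_all_missing_group_raises(self):
        with pytest.raises(ValueError, match="missing"):
            feature_stats([0.5], [np.nan, np.nan])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_label_swap_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(6), r.random(5)
        s1 = feature_stats(a, b)
        s2 = feature_stats(b, a)
        assert s2.diff == pytest.approx(-s1.diff)
        assert s2.fold_change == pytest.approx(1 / s1.fold_change)
        assert s2.p_value == pytest.approx(s1.p_value)

    def test_exact_and_asymptotic_paths_agree_loosely(self, rng):
        # sanity: |exact - normal approx| <= 0.05 at group sizes >= 8
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            a = rng.random(9) + 0.2 * rng.random()
            b = rng.random(8)
            exact = feature_stats(a, b).p_value  # both groups <= 10: exact path
            asym = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                use_continuity=True).pvalue
            assert abs(exact - asym) <= 0.05


class TestAdjustFdr:
    def test_single_p_identity(self):
        assert adjust_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_bh(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_cap_at_one(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([])


def _toy_dataset(beta: np.ndarray, positions, groups):
    ann = _annotation(positions)
    samples = [f"s{i}" for i in range(beta.shape[1])]
    return BetaDataset(
        beta=pd.DataFrame(beta, index=ann.index, columns=samples),
        annotation=ann,
        sample_groups=pd.Series(groups, index=samples),
        dataset_id="toy",
    )


class TestBlockStats:
    def test_constant_block(self):
        beta = np.full((6, 5), 0.3)
        ds = _toy_dataset(beta, [10, 20, 30, 40, 50, 60], ["case"] * 3 + ["control"] * 2)
        blocks = build_blocks(ds.annotation)
        out = block_stats(ds, blocks)
        assert out.iloc[0]["mcam"] == pytest.approx(0.3)
        assert out.iloc[0]["mcom"] == pytest.approx(0.3)
        assert out.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_missing_cpgs_use_remaining_mean(self):
        beta = np.tile(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])[:, None], (1, 5))
        beta[3:, 0] = np.nan  # sample s0 misses 3 of 6 CpGs
        ds = _toy_dataset(beta, [10, 20, 30, 40, 50, 60], ["case"] * 3 + ["control"] * 2)
        blocks = build_blocks(ds.annotation)
        row_of = {p: i for i, p in enumerate(ds.beta.index)}
        vals = ds.beta.to_numpy()
        # block value for s0 = mean of the 3 non-missing CpGs
        expected = np.nanmean(vals[:, 0])
        out = block_stats(ds, blocks)
        assert out.iloc[0]["mcam"] == pytest.approx(np.mean([expected, 0.35, 0.35]))

    def test_block_fdr_equals_adjust_fdr_of_block_p(self, rng):
        beta = rng.random((12, 8))
        ds = _toy_dataset(beta, list(range(10, 130, 10)), ["case"] * 4 + ["control"] * 4)
        blocks = build_blocks(ds.annotation)
        out = block_stats(ds, blocks)
        np.testing.assert_allclose(out["fdr"], adjust_fdr(out["p_value"]))

    def test_block_level_equals_stats_on_precomputed_means(self, rng):
        beta = rng.random((6, 7))
        ds = _toy_dataset(beta, [10, 20, 30, 40, 50, 60], ["case"] * 4 + ["control"] * 3)
        blocks = build_blocks(ds.annotation)
        out = block_stats(ds, blocks)
        means = beta.mean(axis=0)
        ref = feature_stats(means[:4], means[4:])
        assert out.iloc[0]["p_value"] == pytest.approx(ref.p_value)
        assert out.iloc[0]["mcam"] == pytest.approx(ref.mcam)

    def test_unknown_probe_rejected(self, rng):
        beta = rng.random((6, 4))
        ds = _toy_dataset(beta, [10, 20, 30, 40, 50, 60], ["case"] * 2 + ["control"] * 2)
        bogus = [Block("b", "chr1", ("nope",) * 6, 10, 60)]
        with pytest.raises(ValueError, match="unknown probe"):
            block_stats(ds, bogus)


def test_null_fdr_calibration(rng):
    """Label-permuted data: the share of features called at q < 0.01 stays near zero."""
    n_feat, n_rep = 400, 50
    frac = []
    for _ in range(n_rep):
        beta = rng.random((n_feat, 30))
        ds = _toy_dataset(beta, list(range(10, 10 + 10 * n_feat, 10)),
                          ["case"] * 15 + ["control"] * 15)
        frac.append(float((cpg_stats(ds)["fdr"] < 0.01).mean()))
    mc_err = np.std(frac, ddof=1) / np.sqrt(n_rep)
    assert np.mean(frac) <= 0.01 + 3 * mc_err
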