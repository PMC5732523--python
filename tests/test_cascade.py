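"""Filter-cascade stages, primer difficulty and top-k selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmarker import (
    GenomicRegion,
    annotation_filter,
    apply_stage,
    blood_filter,
    primer_difficulty,
    select_top_k,
    unique_cpgs_from_dmrs,
)
from methmarker.cascade import CascadeConfig, PrimerScore, StageThresholds
from methmarker.dmr import Block

STAGE1 = CascadeConfig().stage1


def _stats(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


class TestApplyStage:
    def test_survivor_example(self):
        stats = _stats({"cg1": dict(mcam=0.45, mcom=0.18, fdr=0.005, fold_change=2.5)})
        ids, row = apply_stage(stats, STAGE1)
        assert ids == ["cg1"]
        assert (row.n_in, row.n_out) == (1, 1)

    def test_boundaries_are_strict(self):
        for col, val in [("mcam", 0.40), ("mcom", 0.20), ("fdr", 0.01), ("fold_change", 2.0)]:
            base = dict(mcam=0.45, mcom=0.18, fdr=0.005, fold_change=2.5)
            base[col] = val
            ids, _ = apply_stage(_stats({"cg1": base}), STAGE1)
            assert ids == [], f"{col}={val} should fail the strict comparison"

    def test_matches_brute_force_conjunction(self, rng):
        stats = pd.DataFrame(
            {
                "mcam": rng.uniform(0.2, 0.6, 20),
                "mcom": rng.uniform(0.0, 0.4, 20),
                "fdr": rng.uniform(0.0, 0.05, 20),
                "fold_change": rng.uniform(1.0, 4.0, 20),
            },
            index=[f"cg{i}" for i in range(20)],
        )
        expected = [
            i for i, r in stats.iterrows()
            if r.mcam > 0.40 and r.mcom < 0.20 and r.fdr < 0.01 and r.fold_change > 2
        ]
        ids, _ = apply_stage(stats, STAGE1)
        assert ids == expected

    def test_missing_statistic_rejected(self):
        stats = _stats({"cg1": dict(mcam=0.5)})
        with pytest.raises(ValueError, match="absent"):
            apply_stage(stats, STAGE1)

    def test_relaxing_a_threshold_never_shrinks_survivors(self, rng):
        stats = pd.DataFrame(
            {
                "mcam": rng.uniform(0, 1, 50),
                "mcom": rng.uniform(0, 1, 50),
                "fdr": rng.uniform(0, 1, 50),
                "fold_change": rng.uniform(0, 4, 50),
            },
            index=[f"cg{i}" for i in range(50)],
        )
        tight, _ = apply_stage(stats, STAGE1)
        relaxed, _ = apply_stage(
            stats, StageThresholds(mcam_min=0.30, mcom_max=0.20, fdr_max=0.01, fc_min=2.0)
        )
        assert set(tight) <= set(relaxed)


class TestUniqueCpgs:
    def test_shared_members_deduplicated(self):
        b1 = Block("b1", "chr1", ("a", "b", "c", "d", "e", "f"), 1, 6)
        b2 = Block("b2", "chr1", ("b", "c", "d", "e", "f", "g"), 2, 7)
        assert unique_cpgs_from_dmrs([b1, b2]) == set("abcdefg")

    def test_empty(self):
        assert unique_cpgs_from_dmrs([]) == set()

    def test_random_overlap_matches_set_union(self, rng):
        blocks = []
        for i in range(30):
            start = int(rng.integers(0, 40))
            members = tuple(f"cg{j}" for j in range(start, start + 6))
            blocks.append(Block(f"b{i}", "chr1", members, start, start + 5))
        oracle = set().union(*(set(b.cpg_ids) for b in blocks))
        assert unique_cpgs_from_dmrs(blocks) == oracle


class TestBloodFilter:
    def test_below_cutoff_in_all_datasets_survives(self):
        pbmc = pd.Series({"cg1": 0.05})
        pbl = pd.Series({"cg1": 0.08})
        assert blood_filter({"cg1"}, [pbmc, pbl], 0.10) == ["cg1"]

    def test_any_dataset_above_cutoff_removes(self):
        pbmc = pd.Series({"cg1": 0.05})
        pbl = pd.Series({"cg1": 0.30})
        assert blood_filter({"cg1"}, [pbmc, pbl], 0.10) == []

    def test_absent_probe_retained_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="methmarker"):
            out = blood_filter({"cgX"}, [pd.Series({"cg1": 0.5})], 0.10)
        assert out == ["cgX"]
        assert any("absent" in r.message for r in caplog.records)

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError, match="no blood datasets"):
            blood_filter({"cg1"}, [], 0.10)

    def test_matches_mean_oracle(self, rng):
        probes = [f"cg{i}" for i in range(50)]
        beta1 = pd.DataFrame(rng.random((50, 10)), index=probes)
        beta2 = pd.DataFrame(rng.random((50, 8)) * 0.3, index=probes)
        means = [beta1.mean(axis=1), beta2.mean(axis=1)]
        expected = sorted(
            p for p in probes if means[0][p] <= 0.4 and means[1][p] <= 0.4
        )
        assert blood_filter(set(probes), means, 0.4) == expected


class TestAnnotationFilter:
    def test_island_shore_and_flags(self):
        ann = pd.DataFrame(
            {
                "island_relation": ["Island", "S_Shelf", "N_Shore", "Island", "Island"],
                "snp_in_primer": [False, False, False, True, False],
                "prior_gene": [False, False, False, False, True],
            },
            index=[f"cg{i}" for i in range(5)],
        )
        assert annotation_filter(set(ann.index), ann) == ["cg0", "cg2"]


class TestPrimerDifficulty:
    def test_at_extreme_gc(self):
        s = primer_difficulty("ATATATATAT", 0, (1.0, 0.25, 1.0))
        assert s.gc_fraction == 0.0
        assert s.max_polyt == 1
        assert s.difficulty == pytest.approx(0.5)

    def test_longest_run_scans_t_and_a(self):
        assert primer_difficulty("GGTTTTTGG", 0).max_polyt == 5
        assert primer_difficulty("GGAAAAAAG", 0).max_polyt == 6  # A runs count too

    def test_n_excluded_from_gc(self):
        s = primer_difficulty("GCNN", 0)
        assert s.gc_fraction == pytest.approx(1.0)

    def test_monotone_in_snp_count(self):
        lo = primer_difficulty("ACGTACGT", 0).difficulty
        hi = primer_difficulty("ACGTACGT", 3).difficulty
        assert hi > lo

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            primer_difficulty("ACGU", 0)

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60), st.integers(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_run_length_matches_scan_oracle(self, seq, snps):
        def longest(s, base):
            best = cur = 0
            for ch in s:
                cur = cur + 1 if ch == base else 0
                best = max(best, cur)
            return best

        score = primer_difficulty(seq, snps)
        assert score.max_polyt == max(longest(seq, "T"), longest(seq, "A"))
        assert score.gc_fraction == pytest.approx((seq.count("G") + seq.count("C")) / len(seq))


def _scored(difficulties, chroms=None):
    out = []
    for i, d in enumerate(difficulties):
        chrom = (chroms or ["chr1"] * len(difficulties))[i]
        region = GenomicRegion(chrom, 100 + i, 200 + i, (), f"r{i}")
        out.append((region, PrimerScore(region.region_id, 0.5, 1, 0, d)))
    return out


class TestSelectTopK:
    def test_ascending_difficulty(self):
        scored = _scored([0.2, 0.1, 0.9])
        assert select_top_k(scored, 2) == [scored[1][0].region_id, scored[0][0].region_id]

    def test_ties_break_by_position_and_are_stable(self):
        scored = _scored([0.5, 0.5, 0.5])
        first = select_top_k(scored, 3)
        assert first == sorted(r.region_id for r, _ in scored)
        assert select_top_k(list(reversed(scored)), 3) == first

    def test_k_larger_than_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_top_k(_scored([0.1]), 2)
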