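"""The staged marker-filter cascade and primer-difficulty ranking.

Stages, in run order (thresholds strict, exactly as printed in the config):

1. block-level DMR filter on the discovery cohort
   (McaM > 0.40, McoM < 0.20, FDR < 0.01, fold change > 2)
2. CpG-level filter on the discovery cohort, over the unique CpGs covered by
   surviving blocks (McaM > 0.25, McoM < 0.20, Diff > 0.15, FC > 2, FDR < 0.01)
3. external-validation CpG filter
   (McaM > 0.15, McoM < 0.15, Diff > 0.10, FC > 2, raw P < 0.05)
4. blood filter: mean beta must be <= blood_mean_max in EVERY blood reference
   dataset (PBMC, PBL), so the marker stays quiet in liquid-biopsy background
5. annotation filter: island/shore location, no SNP in the primer footprint,
   gene not previously studied (externally supplied flag)

Surviving CpGs are mapped back to their stage-1 blocks; each such block is a
candidate region, ranked by a three-component primer-difficulty score
(GC deviation, poly-T/A runs, SNP count) and the top k (default 5) selected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmr import Block
from .io_core import BetaDataset, GenomicRegion

logger = logging.getLogger("methmarker")

#: threshold name -> (stats column, comparison direction)
_THRESHOLD_SPEC = {
    "mcam_min": ("mcam", "gt"),
    "mcom_max": ("mcom", "lt"),
    "diff_min": ("diff", "gt"),
    "fc_min": ("fold_change", "gt"),
    "fdr_max": ("fdr", "lt"),
    "p_max": ("p_value", "lt"),
}


@dataclass(frozen=True)
class StageThresholds:
    """One stage's inequality set; None disables that comparison."""

    mcam_min: float | None = None
    mcom_max: float | None = None
    diff_min: float | None = None
    fc_min: float | None = None
    fdr_max: float | None = None
    p_max: float | None = None


@dataclass
class CascadeConfig:
    stage1: StageThresholds = field(
        default_factory=lambda: StageThresholds(mcam_min=0.40, mcom_max=0.20, fdr_max=0.01, fc_min=2.0)
    )
    stage2: StageThresholds = field(
        default_factory=lambda: StageThresholds(
            mcam_min=0.25, mcom_max=0.20, diff_min=0.15, fc_min=2.0, fdr_max=0.01
        )
    )
    stage3: StageThresholds = field(
        default_factory=lambda: StageThresholds(
            mcam_min=0.15, mcom_max=0.15, diff_min=0.10, fc_min=2.0, p_max=0.05
        )
    )
    blood_mean_max: float = 0.10
    island_keep: tuple[str, ...] = ("Island", "N_Shore", "S_Shore")
    top_k: int = 5
    difficulty_weights: tuple[float, float, float] = (1.0, 0.25, 1.0)


@dataclass
class PrimerScore:
    """Primer-difficulty components and the weighted scalar for one region."""

    region_id: str
    gc_fraction: float
    max_polyt: int
    snp_count: int
    difficulty: float


@dataclass
class StageRow:
    stage: str
    n_in: int
    n_out: int


@dataclass
class CascadeReport:
    rows: list[StageRow]
    survivors: dict[str, list[str]]  # stage -> surviving feature ids
    candidates: list[tuple[GenomicRegion, PrimerScore]]
    selected: list[str]  # top-k region ids, ascending difficulty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(r.stage, r.n_in, r.n_out) for r in self.rows],
                            columns=["stage", "n_in", "n_out"])


# ---------------------------------------------------------------------------
# stage primitives
# ---------------------------------------------------------------------------


def apply_stage(stats: pd.DataFrame, thresholds: StageThresholds) -> tuple[list[str], StageRow]:
    """Keep features for which ALL configured inequalities hold strictly."""
    if stats.empty:
        raise ValueError("empty stats table")
    keep = np.ones(len(stats), dtype=bool)
    for name, (col, direction) in _THRESHOLD_SPEC.items():
        bound = getattr(thresholds, name)
        if bound is None:
            continue
        if col not in stats.columns:
            raise ValueError(f"threshold {name} needs statistic {col!r}, absent from stats")
        vals = stats[col].to_numpy(dtype=float)
        keep &= (vals > bound) if direction == "gt" else (vals < bound)
    ids = stats.index[keep].astype(str).tolist()
    return ids, StageRow(stage="", n_in=len(stats), n_out=len(ids))


def unique_cpgs_from_dmrs(surviving_blocks: list[Block]) -> set[str]:
    """Union of member CpG ids over blocks (overlapping blocks share CpGs)."""
    out: set[str] = set()
    for b in surviving_blocks:
        out.update(b.cpg_ids)
    return out


def dataset_means(ds: BetaDataset) -> pd.Series:
    """Per-probe mean beta over all samples of a (blood reference) dataset."""
    return ds.beta.mean(axis=1, skipna=True)


def blood_filter(
    candidates: "set[str] | list[str]",
    blood_means: "list[pd.Series] | list[BetaDataset]",
    blood_mean_max: float = 0.10,
) -> list[str]:
    """Survive iff mean beta <= cutoff in EVERY blood dataset.

    Probes absent from a blood dataset are retained there with a warning
    (no evidence against them).
    """
    if not blood_means:
        raise ValueError("blood filter enabled but no blood datasets supplied")
    means = [dataset_means(b) if isinstance(b, BetaDataset) else b for b in blood_means]
    surviving = []
    for probe in sorted(candidates):
        ok = True
        for i, m in enumerate(means):
            if probe not in m.index:
                logger.warning("probe %s absent from blood dataset %d; retained", probe, i)
                continue
            if m[probe] > blood_mean_max:
                ok = False
                break
        if ok:
            surviving.append(probe)
    return surviving


def annotation_filter(
    candidates: "set[str] | list[str]",
    annotation: pd.DataFrame,
    island_keep: tuple[str, ...] = ("Island", "N_Shore", "S_Shore"),
) -> list[str]:
    """Keep island/shore CpGs without primer SNPs or previously studied genes."""
    ann = annotation.loc[sorted(candidates)]
    keep = (
        ann["island_relation"].isin(island_keep)
        & ~ann["snp_in_primer"].astype(bool)
        & ~ann["prior_gene"].astype(bool)
    )
    return ann.index[keep].tolist()


# ---------------------------------------------------------------------------
# primer difficulty
# ---------------------------------------------------------------------------

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


def primer_difficulty(
    seq: str,
    snp_count: int,
    weights: tuple[float, float, float] = (1.0, 0.25, 1.0),
    region_id: str = "",
) -> PrimerScore:
    """Score amplification difficulty from GC content, homopolymer runs, SNPs.

    difficulty = w1*|GC - 0.5| + w2*max(0, longest T-or-A run - 4) + w3*snps.
    Ns are excluded from the GC numerator and denominator.
    """
    seq = seq.upper()
    if not seq or not _VALID_SEQ.match(seq):
        bad = next((c for c in seq if c not in "ACGTN"), "")
        raise ValueError(f"invalid sequence character {bad!r}" if seq else "empty sequence")
    if snp_count < 0:
        raise ValueError("snp_count must be >= 0")
    n_acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / n_acgt if n_acgt else 0.0
    max_run = 0
    for base in ("T", "A"):
        for m in re.finditer(f"{base}+", seq):
            max_run = max(max_run, len(m.group()))
    w1, w2, w3 = weights
    difficulty = w1 * abs(gc - 0.5) + w2 * max(0, max_run - 4) + w3 * snp_count
    return PrimerScore(
        region_id=region_id, gc_fraction=gc, max_polyt=max_run,
        snp_count=int(snp_count), difficulty=float(difficulty),
    )


def _region_sort_key(region: GenomicRegion):
    m = re.match(r"^chr(\d+)$", region.chrom)
    return ((0, int(m.group(1))) if m else (1, region.chrom), region.start)


def select_top_k(
    scored: list[tuple[GenomicRegion, PrimerScore]], k: int
) -> list[str]:
    """The k easiest regions, ascending difficulty; ties broken by (chrom, start)."""
    if k > len(scored):
        raise ValueError(f"k={k} exceeds {len(scored)} candidates")
    ranked = sorted(scored, key=lambda rs: (rs[1].difficulty, _region_sort_key(rs[0])))
    return [r.region_id for r, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


def run_cascade(
    block_stats: pd.DataFrame,
    blocks: list[Block],
    cpg_stats: pd.DataFrame,
    validation_stats: pd.DataFrame,
    blood_means: "list[pd.Series] | list[BetaDataset]",
    annotation: pd.DataFrame,
    sequences: dict[str, tuple[str, int]],
    config: CascadeConfig | None = None,
) -> CascadeReport:
    """Run stages 1-5 plus primer ranking; see the module docstring.

    ``sequences`` maps region/block ids to (nucleotide string, SNP count);
    regions without a sequence record are kept unscored last, with a warning.
    """
    cfg = config or CascadeConfig()
    rows: list[StageRow] = []
    survivors: dict[str, list[str]] = {}

    block_ids, row = apply_stage(block_stats, cfg.stage1)
    rows.append(StageRow("stage1_dmr", row.n_in, row.n_out))
    survivors["stage1_dmr"] = block_ids
    surviving_blocks = [b for b in blocks if b.block_id in set(block_ids)]

    cpgs = unique_cpgs_from_dmrs(surviving_blocks)
    rows.append(StageRow("unique_cpgs", len(block_ids), len(cpgs)))
    survivors["unique_cpgs"] = sorted(cpgs)

    stage2_ids, _ = apply_stage(cpg_stats.loc[sorted(cpgs)], cfg.stage2) if cpgs else ([], None)
    rows.append(StageRow("stage2_cpg", len(cpgs), len(stage2_ids)))
    survivors["stage2_cpg"] = stage2_ids

    if stage2_ids:
        present = [c for c in stage2_ids if c in validation_stats.index]
        absent = set(stage2_ids) - set(present)
        if absent:
            logger.warning("%d candidates absent from validation stats; removed", len(absent))
        stage3_ids, _ = apply_stage(validation_stats.loc[present], cfg.stage3) if present else ([], None)
    else:
        stage3_ids = []
    rows.append(StageRow("stage3_validation", len(stage2_ids), len(stage3_ids)))
    survivors["stage3_validation"] = stage3_ids

    stage4_ids = blood_filter(stage3_ids, blood_means, cfg.blood_mean_max) if stage3_ids else []
    rows.append(StageRow("stage4_blood", len(stage3_ids), len(stage4_ids)))
    survivors["stage4_blood"] = stage4_ids

    stage5_ids = annotation_filter(stage4_ids, annotation, cfg.island_keep) if stage4_ids else []
    rows.append(StageRow("stage5_annotation", len(stage4_ids), len(stage5_ids)))
    survivors["stage5_annotation"] = stage5_ids

    final = set(stage5_ids)
    seen: set[str] = set()
    candidates: list[tuple[GenomicRegion, PrimerScore]] = []
    for b in surviving_blocks:
        if b.block_id in seen or not (set(b.cpg_ids) & final):
            continue
        seen.add(b.block_id)
        region = GenomicRegion(
            chrom=b.chrom, start=b.start, end=b.end,
            cpg_ids=tuple(sorted(set(b.cpg_ids) & final,
                                 key=lambda c: annotation.loc[c, "pos"])),
            label=b.block_id,
        )
        if b.block_id in sequences:
            seq, snps = sequences[b.block_id]
            score = primer_difficulty(seq, snps, cfg.difficulty_weights, region.region_id)
        else:
            logger.warning("no sequence record for region %s; ranked last", b.block_id)
            score = PrimerScore(region.region_id, np.nan, 0, 0, float("inf"))
        candidates.append((region, score))
    rows.append(StageRow("candidate_regions", len(stage5_ids), len(candidates)))

    k = min(cfg.top_k, len(candidates))
    selected = select_top_k(candidates, k) if candidates else []
    rows.append(StageRow("top_k_selected", len(candidates), len(selected)))

    return CascadeReport(rows=rows, survivors=survivors, candidates=candidates, selected=selected)


def selected_regions(report: CascadeReport) -> list[GenomicRegion]:
    """The top-k candidate regions as GenomicRegion objects, in selection order."""
    by_id = {r.region_id: r for r, _ in report.candidates}
    return [by_id[rid] for rid in report.selected]
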