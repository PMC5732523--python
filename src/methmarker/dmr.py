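"""Sliding-window methylation blocks and differential-methylation statistics.

A *block* is a run of k adjacent CpG sites (default k=6) on one chromosome
spanning strictly less than ``max_span`` bases (default 1000 bp, reflecting
the short range of methylation linkage).  The window slides one CpG at a
time, so adjacent blocks overlap.

Per-feature statistics are the case/control mean methylation fractions
(McaM/McoM), their difference, a pseudocount-adjusted fold change, a
two-sided Wilcoxon rank-sum p-value and a Benjamini-Hochberg q-value.  The
Wilcoxon uses the exact null by enumeration when both group sizes are <= 10
and there are no ties, otherwise the normal approximation with midranks,
tie-corrected variance and continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_core import BetaDataset

logger = logging.getLogger("methmarker")

#: pseudocount for fold change, so McoM = 0 does not divide by zero while
#: preserving ">2" semantics at methylation scale
FOLD_CHANGE_EPS = 1e-3

DEFAULT_BLOCK_SIZE = 6
DEFAULT_MAX_SPAN = 1000

STAT_COLUMNS = ["mcam", "mcom", "diff", "fold_change", "p_value", "fdr"]


@dataclass(frozen=True)
class Block:
    """An ordered run of exactly k adjacent CpGs on one chromosome."""

    block_id: str
    chrom: str
    cpg_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class FeatureStats:
    """Differential-methylation summary for one CpG or block."""

    feature_id: str
    mcam: float
    mcom: float
    diff: float
    fold_change: float
    p_value: float
    fdr: float = np.nan


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------


def build_blocks(
    annotation: pd.DataFrame,
    k: int = DEFAULT_BLOCK_SIZE,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[Block]:
    """Slide a k-CpG window one site at a time along each chromosome.

    A candidate window (k consecutive manifest CpGs, no intervening site)
    is kept iff its span (last pos - first pos) is strictly less than
    ``max_span``.  Output is ordered by (chrom, first position).
    """
    if k < 2:
        raise ValueError(f"window size k must be >= 2, got {k}")
    ann = annotation[["chrom", "pos"]].copy()
    ann["probe_id"] = annotation.index
    dup = ann.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = ann.loc[dup].iloc[0]
        raise ValueError(f"duplicate manifest entry at {row.chrom}:{row.pos}")
    ann = ann.sort_values(["chrom", "pos"], kind="mergesort")

    blocks: list[Block] = []
    for chrom, grp in ann.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        for i in range(len(pos) - k + 1):
            span = int(pos[i + k - 1] - pos[i])
            if span < max_span:
                blocks.append(
                    Block(
                        block_id=f"{chrom}:{pos[i]}-{pos[i + k - 1]}",
                        chrom=str(chrom),
                        cpg_ids=tuple(ids[i : i + k]),
                        start=int(pos[i]),
                        end=int(pos[i + k - 1]),
                    )
                )
    return blocks


# ---------------------------------------------------------------------------
# per-feature statistics
# ---------------------------------------------------------------------------


def _wilcoxon_p(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value with the exact/asymptotic switch."""
    if case.size == 0 or control.size == 0:
        raise ValueError("a group is entirely missing")
    combined = np.concatenate([case, control])
    if np.all(combined == combined[0]):
        return 1.0  # degenerate: no rank information
    has_ties = np.unique(combined).size < combined.size
    if case.size <= 10 and control.size <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(
            case, control, alternative="two-sided", method=method, use_continuity=True
        ).pvalue
    )


def feature_stats(
    values_case: "np.ndarray | list[float]",
    values_control: "np.ndarray | list[float]",
    feature_id: str = "",
    eps: float = FOLD_CHANGE_EPS,
) -> FeatureStats:
    """McaM, McoM, Diff, fold change and Wilcoxon P for one feature.

    Missing (NaN) values are excluded per group; each group must retain at
    least one value.
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if case.size == 0 or control.size == 0:
        raise ValueError(f"feature {feature_id!r}: a group is entirely missing")
    mcam = float(case.mean())
    mcom = float(control.mean())
    return FeatureStats(
        feature_id=feature_id,
        mcam=mcam,
        mcom=mcom,
        diff=mcam - mcom,
        fold_change=(mcam + eps) / (mcom + eps),
        p_value=_wilcoxon_p(case, control),
    )


def adjust_fdr(p_values: "np.ndarray | list[float]") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stats_frame(
    case_mat: np.ndarray,
    ctrl_mat: np.ndarray,
    feature_ids: "pd.Index | list[str]",
    eps: float = FOLD_CHANGE_EPS,
) -> pd.DataFrame:
    """Vectorised feature stats over a (features x samples) split matrix pair.

    Uses one asymptotic Mann-Whitney call over the whole matrix when both
    groups are large (>10) and complete; otherwise falls back to the
    per-feature path, which applies the exact rule where it holds.
    """
    n_feat = case_mat.shape[0]
    mcam = np.nanmean(case_mat, axis=1)
    mcom = np.nanmean(ctrl_mat, axis=1)

    complete = not (np.isnan(case_mat).any() or np.isnan(ctrl_mat).any())
    if complete and case_mat.shape[1] > 10 and ctrl_mat.shape[1] > 10:
        res = mannwhitneyu(
            case_mat, ctrl_mat, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
        # rows with zero rank information (all values tied) -> p = 1
        flat = np.all(
            np.concatenate([case_mat, ctrl_mat], axis=1)
            == np.concatenate([case_mat, ctrl_mat], axis=1)[:, :1],
            axis=1,
        )
        p = np.where(flat | np.isnan(p), 1.0, p)
    else:
        p = np.empty(n_feat)
        for i in range(n_feat):
            c = case_mat[i][~np.isnan(case_mat[i])]
            t = ctrl_mat[i][~np.isnan(ctrl_mat[i])]
            p[i] = _wilcoxon_p(c, t)

    df = pd.DataFrame(
        {
            "mcam": mcam,
            "mcom": mcom,
            "diff": mcam - mcom,
            "fold_change": (mcam + eps) / (mcom + eps),
            "p_value": p,
            "fdr": adjust_fdr(p),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return df


def cpg_stats(dataset: BetaDataset) -> pd.DataFrame:
    """Per-CpG differential stats; the FDR family is all CpGs of the dataset."""
    dataset.validate()
    case = dataset.beta[dataset.case_samples].to_numpy(dtype=float)
    ctrl = dataset.beta[dataset.control_samples].to_numpy(dtype=float)
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ValueError("dataset needs at least one case and one control")
    return _stats_frame(case, ctrl, dataset.beta.index)


def block_stats(dataset: BetaDataset, blocks: list[Block]) -> pd.DataFrame:
    """Per-block stats on per-sample block means; FDR family is all blocks.

    A sample's block value is the mean over the block's non-missing CpG
    betas; samples with every member CpG missing are excluded for that block.
    """
    dataset.validate()
    if not blocks:
        raise ValueError("no blocks supplied")
    row_of = {probe: i for i, probe in enumerate(dataset.beta.index)}
    try:
        idx = np.array([[row_of[c] for c in b.cpg_ids] for b in blocks])
    except KeyError as exc:
        raise ValueError(f"block references unknown probe {exc.args[0]!r}") from None

    beta = dataset.beta.to_numpy(dtype=float)
    block_vals = np.nanmean(beta[idx], axis=1)  # blocks x samples
    cols = pd.Index(dataset.beta.columns)
    case_cols = cols.get_indexer(dataset.case_samples)
    ctrl_cols = cols.get_indexer(dataset.control_samples)
    return _stats_frame(
        block_vals[:, case_cols],
        block_vals[:, ctrl_cols],
        [b.block_id for b in blocks],
    )


def write_stats(stats: pd.DataFrame, path) -> None:
    stats.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
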