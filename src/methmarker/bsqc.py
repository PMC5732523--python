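"""Targeted bisulfite-sequencing QC and region-mean aggregation.

QC passes run in a fixed order, matching the assay's reported workflow:

1. drop samples with bisulfite conversion rate < ``conv_min`` (conversion is
   estimated from non-CpG cytosines, assumed unmethylated, as transformed
   C->T over total C);
2. over the remaining samples, drop CpG sites with mean coverage below
   ``cov_min`` or missing rate above ``cpg_missing_max`` (a call is missing
   iff its total read count is zero or the record is absent);
3. over the remaining CpGs, drop samples with missing rate above
   ``sample_missing_max``.

Mean coverage is computed over non-missing calls among conversion-passing
samples.  Region means are unweighted means of per-CpG fractions m_i/t_i
(coverage weighting available via ``weighted=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import BsCounts, GenomicRegion

logger = logging.getLogger("methmarker")


@dataclass
class QcConfig:
    conv_min: float = 0.98
    cov_min: float = 20.0
    cpg_missing_max: float = 0.20
    sample_missing_max: float = 0.30


@dataclass
class BsCohort:
    """A targeted-BS validation cohort.

    ``samples``: indexed by sample_id with columns pair_id, group
    (tumor/normal), age, sex, smoking, alcohol.  ``meth``/``total``: CpG x
    sample read-count matrices (NaN or total 0 = missing call).
    ``conversion``: per-sample converted/total non-CpG cytosine counts.
    ``cpg_positions``: cpg_id -> chrom, pos.
    """

    samples: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame
    conversion: pd.DataFrame
    cpg_positions: pd.DataFrame

    def validate(self) -> None:
        if not self.meth.index.equals(self.total.index):
            raise ValueError("meth/total CpG indices differ")
        if list(self.meth.columns) != list(self.total.columns):
            raise ValueError("meth/total sample columns differ")
        m = self.meth.to_numpy(dtype=float)
        t = self.total.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(m > t):
                raise ValueError("methylated reads exceed total reads")
        if np.any(m < 0) or np.any(t < 0):
            raise ValueError("negative read counts")
        missing = set(self.meth.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def fractions(self) -> pd.DataFrame:
        """Per-CpG methylation fractions m/t; NaN where the call is missing."""
        t = self.total.to_numpy(dtype=float)
        m = self.meth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(t > 0, m / np.where(t > 0, t, 1), np.nan)
        return pd.DataFrame(f, index=self.meth.index, columns=self.meth.columns)


@dataclass
class QcReport:
    sample_conversion: pd.Series  # per-sample conversion rate
    removed_samples: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    removed_cpgs: list[tuple[str, str]] = field(default_factory=list)
    cpg_mean_coverage: pd.Series | None = None
    cpg_missing_rate: pd.Series | None = None
    sample_missing_rate: pd.Series | None = None
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_cpgs_in: int = 0
    n_cpgs_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", sid, reason) for sid, reason in self.removed_samples]
        rows += [("cpg", cid, reason) for cid, reason in self.removed_cpgs]
        return pd.DataFrame(rows, columns=["entity", "id", "reason"])


def build_cohort(counts: BsCounts, samples: pd.DataFrame) -> BsCohort:
    """Pivot parsed BS count records into a BsCohort (missing calls -> NaN)."""
    calls = counts.calls
    meth = calls.pivot_table(index="cpg_id", columns="sample_id", values="methylated",
                             aggfunc="first")
    total = calls.pivot_table(index="cpg_id", columns="sample_id", values="total",
                              aggfunc="first")
    ordered = [s for s in samples.index if s in meth.columns]
    meth, total = meth[ordered], total[ordered]
    pos = (
        calls.drop_duplicates("cpg_id").set_index("cpg_id")[["chrom", "pos"]].loc[meth.index]
    )
    cohort = BsCohort(
        samples=samples.loc[ordered].copy(),
        meth=meth,
        total=total,
        conversion=counts.conversion.reindex(ordered),
        cpg_positions=pos,
    )
    cohort.validate()
    return cohort


def conversion_rate(converted_noncpg: int, total_noncpg: int) -> float:
    """Fraction of non-CpG cytosines read as T (converted / total)."""
    if total_noncpg <= 0:
        raise ValueError("total non-CpG cytosine count must be > 0")
    if not 0 <= converted_noncpg <= total_noncpg:
        raise ValueError("converted count outside [0, total]")
    return converted_noncpg / total_noncpg


def qc_pipeline(cohort: BsCohort, config: QcConfig | None = None) -> tuple[BsCohort, QcReport]:
    """Apply the three ordered QC passes; see the module docstring."""
    cfg = config or QcConfig()
    cohort.validate()
    report = QcReport(
        sample_conversion=pd.Series(dtype=float),
        n_samples_in=cohort.meth.shape[1],
        n_cpgs_in=cohort.meth.shape[0],
    )

    # pass 1: conversion
    conv = pd.Series(
        {
            s: conversion_rate(int(row["converted"]), int(row["total"]))
            for s, row in cohort.conversion.iterrows()
        }
    ).reindex(cohort.meth.columns)
    report.sample_conversion = conv
    keep_samples = [s for s in cohort.meth.columns if conv[s] >= cfg.conv_min]
    report.removed_samples += [
        (s, "low_conversion") for s in cohort.meth.columns if s not in set(keep_samples)
    ]
    if not keep_samples:
        raise ValueError("QC removed all samples at the conversion pass")

    meth = cohort.meth[keep_samples]
    total = cohort.total[keep_samples]
    missing = total.isna() | (total <= 0)

    # pass 2: CpG coverage / missingness over conversion-passing samples
    cov = total.where(~missing)
    mean_cov = cov.mean(axis=1, skipna=True).fillna(0.0)
    miss_rate = missing.mean(axis=1)
    report.cpg_mean_coverage = mean_cov
    report.cpg_missing_rate = miss_rate
    keep_cpgs = []
    for cid in meth.index:
        if mean_cov[cid] < cfg.cov_min:
            report.removed_cpgs.append((cid, "low_coverage"))
        elif miss_rate[cid] > cfg.cpg_missing_max:
            report.removed_cpgs.append((cid, "high_missing"))
        else:
            keep_cpgs.append(cid)
    if not keep_cpgs:
        raise ValueError("QC removed all CpG sites")
    meth, total = meth.loc[keep_cpgs], total.loc[keep_cpgs]
    missing = missing.loc[keep_cpgs]

    # pass 3: sample missingness over remaining CpGs
    samp_miss = missing.mean(axis=0)
    report.sample_missing_rate = samp_miss
    final_samples = [s for s in meth.columns if samp_miss[s] <= cfg.sample_missing_max]
    report.removed_samples += [
        (s, "high_missing") for s in meth.columns if s not in set(final_samples)
    ]
    if not final_samples:
        raise ValueError("QC removed all samples at the missing-rate pass")

    filtered = BsCohort(
        samples=cohort.samples.loc[final_samples].copy(),
        meth=meth[final_samples],
        total=total[final_samples],
        conversion=cohort.conversion.loc[final_samples],
        cpg_positions=cohort.cpg_positions.loc[keep_cpgs],
    )
    report.n_samples_out = len(final_samples)
    report.n_cpgs_out = len(keep_cpgs)
    logger.info(
        "QC: %d/%d samples and %d/%d CpGs retained",
        report.n_samples_out, report.n_samples_in, report.n_cpgs_out, report.n_cpgs_in,
    )
    return filtered, report


def region_means(
    cohort: BsCohort, regions: list[GenomicRegion], weighted: bool = False
) -> pd.DataFrame:
    """Per (sample, region) mean methylation fraction (sample x region).

    Unweighted mean of per-CpG fractions over the region's non-missing CpGs
    (``weighted=True`` pools read counts instead).  NaN where every region
    CpG is missing for a sample; a region with zero surviving CpGs raises.
    """
    cohort.validate()
    frac = cohort.fractions
    out = {}
    for region in regions:
        name = region.label or region.region_id
        in_region = (
            (cohort.cpg_positions["chrom"] == region.chrom)
            & (cohort.cpg_positions["pos"] >= region.start)
            & (cohort.cpg_positions["pos"] <= region.end)
        )
        cpgs = cohort.cpg_positions.index[in_region]
        if len(cpgs) == 0:
            raise ValueError(f"region {region.region_id} has no surviving CpGs")
        if weighted:
            m = cohort.meth.loc[cpgs].sum(axis=0, skipna=True)
            t = cohort.total.loc[cpgs].sum(axis=0, skipna=True)
            out[name] = (m / t.where(t > 0)).astype(float)
        else:
            out[name] = frac.loc[cpgs].mean(axis=0, skipna=True)
    return pd.DataFrame(out, index=cohort.meth.columns)
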