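"""Synthetic-cohort generator with known ground truth.

Emulates the study's four array cohorts sharing one CpG universe — a
discovery tumor/normal set (84 cases / 16 controls), a small external
validation set (4 / 8), and two healthy blood references (PBMC N=111,
PBL N=527) — plus a paired targeted bisulfite-sequencing validation cohort
of 94 tumor/adjacent-normal pairs with covariates drawn to match the
reported patient-table marginals (male 69/94, smoking 58/94, alcohol 34
drinkers all male, age median 64, IQR 57-70).

Array betas are drawn from beta distributions with role/group-specific
means and common precision phi (mean m, precision phi -> Beta(m*phi,
(1-m)*phi)).  Planted hyper-methylated blocks satisfy the 6-CpG / <1000 bp
block geometry and carry island/shore annotation; background CpGs share a
per-CpG baseline mean across groups and roles so that, absent planting,
case and control are exchangeable.

Targeted-BS counts: per sample-region mean drawn around the group mean
(between-sample biological heterogeneity), per-CpG fraction around that,
coverage negative-binomial, and bisulfite conversion failure modelled as
unconverted unmethylated cytosines read as methylated — which is what makes
the <98% conversion filter matter.  A configurable handful of samples is
seeded with failing conversion or high missingness to exercise QC.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsqc import BsCohort
from .io_core import BetaDataset, BsCounts, GenomicRegion

logger = logging.getLogger("methmarker")

ROLES = ("discovery", "validation", "pbmc", "pbl")
_ROLE_STREAM = {"universe": 0, "discovery": 1, "validation": 2, "pbmc": 3, "pbl": 4,
                "targeted": 5, "sequences": 6}


@dataclass
class SimConfig:
    """Study-design parameters; defaults are the emulated cohort sizes."""

    # array cohorts
    n_case_discovery: int = 84
    n_control_discovery: int = 16
    n_case_validation: int = 4
    n_control_validation: int = 8
    n_pbmc: int = 111
    n_pbl: int = 527
    # CpG universe
    n_background_cpg: int = 5000
    n_planted_blocks: int = 20
    block_size: int = 6
    # planted/background means and array noise
    planted_case_mean: float = 0.45
    planted_control_mean: float = 0.15
    planted_validation_control_mean: float = 0.10
    planted_blood_mean: float = 0.05
    background_mean: float = 0.12
    baseline_precision: float = 15.0  # spread of per-CpG background baselines
    precision: float = 30.0  # beta-distribution phi for array noise
    array_missing_rate: float = 0.0
    # targeted-BS cohort
    n_pairs: int = 94
    coverage_mean: float = 200.0
    coverage_dispersion: float = 5.0
    missing_call_rate: float = 0.02
    conversion_low: float = 0.985
    conversion_high: float = 0.999
    bs_tumor_mean: float = 0.45
    bs_normal_mean: float = 0.15
    bs_sample_sd: float = 1.0  # logit-scale per-sample effect shared across regions
    bs_region_sd: float = 0.7  # logit-scale per sample-region effect
    bs_within_precision: float = 30.0  # CpG-to-CpG within a sample-region
    noncpg_sites: int = 20000
    # injected QC faults
    n_low_conversion: int = 3
    low_conversion_rate: float = 0.97
    n_high_missing: int = 2
    high_missing_rate: float = 0.5
    # covariate marginals
    male_fraction: float = 69 / 94
    smoking_fraction: float = 58 / 94
    alcohol_fraction_given_male: float = 34 / 69
    age_mean: float = 64.0
    age_sd: float = 9.6  # IQR 57-70 -> sd = 13 / 1.349
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_case_mean", "planted_control_mean",
                     "planted_validation_control_mean", "planted_blood_mean",
                     "background_mean", "bs_tumor_mean", "bs_normal_mean"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0,1)")
        if self.precision <= 0 or self.bs_within_precision <= 0:
            raise ValueError("beta precision must be > 0")
        if self.bs_sample_sd < 0 or self.bs_region_sd < 0:
            raise ValueError("logit-scale standard deviations must be >= 0")
        if min(self.n_case_discovery, self.n_control_discovery, self.n_pairs) < 1:
            raise ValueError("sample counts must be >= 1")


@dataclass
class GroundTruth:
    """Planted-marker bookkeeping for recovery evaluation."""

    planted_cpgs: list[str]
    planted_blocks: list[GenomicRegion]
    true_means: pd.DataFrame  # cpg x {case, control, validation_control, blood}
    labels: pd.Series | None = None  # per-sample truth for one dataset

    def to_frame(self) -> pd.DataFrame:
        out = self.true_means.copy()
        out["planted"] = out.index.isin(self.planted_cpgs)
        return out


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _ROLE_STREAM[stream]]))


def _beta_draw(rng: np.random.Generator, mean, phi: float, size=None) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 1e-3, 1 - 1e-3)
    return rng.beta(mean * phi, (1 - mean) * phi, size=size)


# ---------------------------------------------------------------------------
# CpG universe
# ---------------------------------------------------------------------------


def simulate_universe(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the shared CpG manifest and plant hyper-methylated blocks.

    Background CpG spacing is drawn wide enough that random runs rarely form
    tight blocks; each planted block is six CpGs ~20-60 bp apart (span well
    under 1000 bp), annotated Island or N_Shore, SNP- and prior-gene-free.
    """
    rng = _rng(config, "universe")
    n_chrom = 20
    k = config.block_size
    n_bg_per_chrom = np.full(n_chrom, config.n_background_cpg // n_chrom)
    n_bg_per_chrom[: config.n_background_cpg % n_chrom] += 1
    blocks_per_chrom = np.bincount(
        rng.integers(0, n_chrom, size=config.n_planted_blocks), minlength=n_chrom
    )

    rows = []
    planted_blocks: list[GenomicRegion] = []
    probe_counter = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        n_bg = int(n_bg_per_chrom[ci])
        # island-like clustering: a third of gaps are tight, so background
        # CpGs do form sub-1000 bp windows and stage 1 has a real null family
        tight = rng.random(n_bg) < 0.3
        gaps = np.where(tight, rng.integers(30, 150, size=n_bg), rng.integers(700, 3000, size=n_bg))
        pos = 10_000 + np.cumsum(gaps)
        entries = [(int(p), False) for p in pos]
        # insert planted runs into gaps wide enough to hold them collision-free
        next_gap = np.diff(pos, append=pos[-1] + 10_000)
        open_anchors = set(np.flatnonzero(next_gap > 600).tolist())
        for _ in range(int(blocks_per_chrom[ci])):
            anchor = int(rng.choice(sorted(open_anchors)))
            open_anchors.discard(anchor)
            base = int(pos[anchor]) + 100
            spacing = rng.integers(20, 61, size=k - 1)
            run = base + np.concatenate([[0], np.cumsum(spacing)])
            entries.extend((int(p), True) for p in run)
        entries.sort()
        block_run: list[tuple[int, str]] = []
        for p, is_planted in entries:
            probe_id = f"cg{probe_counter:08d}"
            probe_counter += 1
            rows.append((probe_id, chrom, p, is_planted))
            if is_planted:
                block_run.append((p, probe_id))
                if len(block_run) == k:
                    planted_blocks.append(
                        GenomicRegion(
                            chrom=chrom,
                            start=block_run[0][0],
                            end=block_run[-1][0],
                            cpg_ids=tuple(pid for _, pid in block_run),
                            label=f"{chrom}:{block_run[0][0]}-{block_run[-1][0]}",
                        )
                    )
                    block_run = []

    ann = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "planted"]).set_index("probe_id")
    n = len(ann)
    planted_mask = ann["planted"].to_numpy()

    relation = rng.choice(
        ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"],
        size=n, p=[0.25, 0.10, 0.10, 0.05, 0.05, 0.45],
    )
    relation[planted_mask] = rng.choice(["Island", "N_Shore"], size=planted_mask.sum())
    snp = rng.random(n) < 0.10
    prior = rng.random(n) < 0.05
    snp[planted_mask] = False
    prior[planted_mask] = False
    gene = np.array([f"GENE{i // 40}" for i in range(n)], dtype=object)

    annotation = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "pos": ann["pos"].astype(int),
            "gene": gene,
            "island_relation": relation,
            "snp_in_primer": snp,
            "prior_gene": prior,
        },
        index=ann.index,
    )

    baseline = _beta_draw(rng, config.background_mean, config.baseline_precision, size=n)
    baseline = np.clip(baseline, 0.02, 0.6)
    true_means = pd.DataFrame(
        {
            "case": np.where(planted_mask, config.planted_case_mean, baseline),
            "control": np.where(planted_mask, config.planted_control_mean, baseline),
            "validation_control": np.where(
                planted_mask, config.planted_validation_control_mean, baseline
            ),
            "blood": np.where(planted_mask, config.planted_blood_mean, baseline),
        },
        index=ann.index,
    )
    truth = GroundTruth(
        planted_cpgs=ann.index[planted_mask].tolist(),
        planted_blocks=planted_blocks,
        true_means=true_means,
    )
    if len(truth.planted_cpgs) != config.n_planted_blocks * k:
        raise RuntimeError("planted block bookkeeping mismatch")
    return annotation, truth


# ---------------------------------------------------------------------------
# array cohorts
# ---------------------------------------------------------------------------


def simulate_array(config: SimConfig, role: str) -> tuple[BetaDataset, GroundTruth]:
    """Simulate one array cohort for ``role`` in {discovery, validation, pbmc, pbl}.

    All roles share the universe derived from ``config.seed``; draws use a
    role-specific stream so datasets are independent given the truth.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    annotation, truth = simulate_universe(config)
    rng = _rng(config, role)
    tm = truth.true_means

    if role == "discovery":
        groups = ["case"] * config.n_case_discovery + ["control"] * config.n_control_discovery
        means = {"case": tm["case"].values, "control": tm["control"].values}
        prefix = "DISC"
    elif role == "validation":
        groups = ["case"] * config.n_case_validation + ["control"] * config.n_control_validation
        means = {"case": tm["case"].values, "control": tm["validation_control"].values}
        prefix = "VAL"
    else:
        n = config.n_pbmc if role == "pbmc" else config.n_pbl
        groups = ["control"] * n
        means = {"control": tm["blood"].values}
        prefix = role.upper()

    sample_ids = [f"{prefix}{i:04d}" for i in range(len(groups))]
    beta = np.empty((len(annotation), len(groups)))
    for j, g in enumerate(groups):
        beta[:, j] = _beta_draw(rng, means[g], config.precision)
    if config.array_missing_rate > 0:
        beta[rng.random(beta.shape) < config.array_missing_rate] = np.nan

    ds = BetaDataset(
        beta=pd.DataFrame(beta, index=annotation.index, columns=sample_ids),
        annotation=annotation,
        sample_groups=pd.Series(groups, index=sample_ids, name="group"),
        dataset_id=role,
    )
    ds.validate()
    truth.labels = ds.sample_groups.copy()
    return ds, truth


# ---------------------------------------------------------------------------
# targeted-BS cohort
# ---------------------------------------------------------------------------


def simulate_covariates(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Patient covariates honouring the cohort marginals.

    Alcohol use is drawn only among males (every female is non-alcohol, as
    in the emulated cohort).
    """
    n = config.n_pairs
    male = rng.random(n) < config.male_fraction
    smoking = rng.random(n) < config.smoking_fraction
    alcohol = male & (rng.random(n) < config.alcohol_fraction_given_male)
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, size=n)), 35, 90).astype(int)
    return pd.DataFrame(
        {
            "pair_id": [f"P{i:03d}" for i in range(n)],
            "sex": np.where(male, "male", "female"),
            "age": age,
            "smoking": smoking,
            "alcohol": alcohol,
        }
    )


def simulate_targeted_bs(
    config: SimConfig, regions: list[GenomicRegion]
) -> tuple[BsCohort, pd.DataFrame]:
    """Simulate the paired targeted-BS cohort over candidate ``regions``.

    Returns the cohort and a per-sample truth frame (true region means,
    conversion rate, injected-fault tags).
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    rng = _rng(config, "targeted")
    patients = simulate_covariates(config, rng)

    sample_rows, truth_rows = [], []
    for _, pat in patients.iterrows():
        for tissue in ("tumor", "normal"):
            sample_rows.append(
                {
                    "sample_id": f"{pat.pair_id}{'T' if tissue == 'tumor' else 'N'}",
                    "pair_id": pat.pair_id,
                    "group": tissue,
                    "age": pat.age,
                    "sex": pat.sex,
                    "smoking": bool(pat.smoking),
                    "alcohol": bool(pat.alcohol),
                }
            )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(samples)

    conv = rng.uniform(config.conversion_low, config.conversion_high, size=n_samples)
    miss_p = np.full(n_samples, config.missing_call_rate)
    fault = np.array([""] * n_samples, dtype=object)
    order = rng.permutation(n_samples)
    low_conv_idx = order[: config.n_low_conversion]
    high_miss_idx = order[config.n_low_conversion : config.n_low_conversion + config.n_high_missing]
    conv[low_conv_idx] = config.low_conversion_rate
    miss_p[high_miss_idx] = config.high_missing_rate
    fault[low_conv_idx] = "low_conversion"
    fault[high_miss_idx] = "high_missing"

    cpg_ids, cpg_chrom, cpg_pos = [], [], []
    for region in regions:
        for pos in _region_cpg_positions(region):
            cpg_ids.append(f"{region.chrom}:{pos}")
            cpg_chrom.append(region.chrom)
            cpg_pos.append(pos)
    n_cpg = len(cpg_ids)
    region_of = np.concatenate(
        [np.full(len(_region_cpg_positions(r)), ri) for ri, r in enumerate(regions)]
    )

    is_tumor = (samples["group"] == "tumor").to_numpy()
    group_mean = np.where(is_tumor, config.bs_tumor_mean, config.bs_normal_mean)
    # logistic-normal biological heterogeneity: a per-sample effect shared
    # across regions (global methylation propensity) plus an independent
    # per sample-region effect; per-CpG fractions are drawn around these
    logit = np.log(group_mean / (1 - group_mean))
    u_sample = rng.normal(0.0, config.bs_sample_sd, size=n_samples)
    e_region = rng.normal(0.0, config.bs_region_sd, size=(n_samples, len(regions)))
    eta = logit[:, None] + u_sample[:, None] + e_region
    sample_region_mean = 1.0 / (1.0 + np.exp(-eta))
    frac_true = _beta_draw(
        rng, sample_region_mean[:, region_of].T, config.bs_within_precision
    )  # cpg x sample

    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    total = rng.negative_binomial(config.coverage_dispersion, p_nb, size=(n_cpg, n_samples))
    total[rng.random((n_cpg, n_samples)) < miss_p[None, :]] = 0
    # unconverted unmethylated C reads as methylated: observed fraction
    p_obs = frac_true + (1 - frac_true) * (1 - conv[None, :])
    meth = rng.binomial(total, np.clip(p_obs, 0, 1))
    meth = np.where(total > 0, meth, np.nan)
    total_f = np.where(total > 0, total, np.nan).astype(float)

    noncpg_total = rng.poisson(config.noncpg_sites, size=n_samples) + 1
    noncpg_conv = rng.binomial(noncpg_total, conv)
    conversion = pd.DataFrame(
        {"converted": noncpg_conv, "total": noncpg_total}, index=samples.index
    )

    cohort = BsCohort(
        samples=samples,
        meth=pd.DataFrame(meth, index=cpg_ids, columns=samples.index),
        total=pd.DataFrame(total_f, index=cpg_ids, columns=samples.index),
        conversion=conversion,
        cpg_positions=pd.DataFrame({"chrom": cpg_chrom, "pos": cpg_pos}, index=cpg_ids),
    )
    cohort.validate()
    truth = pd.DataFrame(
        {
            "group": samples["group"].values,
            "true_conversion": conv,
            "injected_fault": fault,
        },
        index=samples.index,
    )
    for ri, region in enumerate(regions):
        truth[f"true_mean_{region.region_id}"] = sample_region_mean[:, ri]
    return cohort, truth


def _region_cpg_positions(region: GenomicRegion) -> list[int]:
    """CpG coordinates assayed in a region (its known CpGs; span endpoints if none)."""
    if region.cpg_ids:
        # positions encoded in the universe are not carried on the region, so
        # spread the known count evenly over the span
        k = len(region.cpg_ids)
        if k == 1:
            return [region.start]
        step = max(1, region.span // (k - 1))
        return [region.start + i * step for i in range(k - 1)] + [region.end]
    return [region.start, region.end]


# ---------------------------------------------------------------------------
# region sequences
# ---------------------------------------------------------------------------


def make_region_sequences(
    regions: list[GenomicRegion], seed: int, flank: int = 60
) -> list[tuple[str, str, int]]:
    """Deterministic synthetic sequence + SNP count per region.

    Each region's sequence (span + primer flanks) is drawn from a seeded
    stream keyed by its coordinates, with region-specific GC content, so any
    caller regenerates identical records.
    """
    records = []
    for region in regions:
        key = zlib.crc32(region.region_id.encode())
        rng = np.random.default_rng(np.random.SeedSequence([seed, _ROLE_STREAM["sequences"], key]))
        length = region.span + 1 + 2 * flank
        gc = rng.uniform(0.30, 0.70)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        snp_count = int(rng.poisson(1.0))
        records.append((region.region_id, seq, snp_count))
    return records


# ---------------------------------------------------------------------------
# end-to-end synthetic discovery
# ---------------------------------------------------------------------------


def run_synthetic_discovery(config: SimConfig, cascade_config=None):
    """Simulate all four array cohorts and run the full filter cascade.

    Returns ``(report, truth, annotation)`` — the cascade report, the ground
    truth for recovery evaluation, and the shared manifest.
    """
    from . import cascade as _cascade
    from . import dmr as _dmr

    discovery, truth = simulate_array(config, "discovery")
    validation, _ = simulate_array(config, "validation")
    pbmc, _ = simulate_array(config, "pbmc")
    pbl, _ = simulate_array(config, "pbl")

    annotation = discovery.annotation
    blocks = _dmr.build_blocks(annotation)
    regions = [
        GenomicRegion(b.chrom, b.start, b.end, b.cpg_ids, b.block_id) for b in blocks
    ]
    sequences = {
        rid: (seq, snps)
        for rid, seq, snps in make_region_sequences(regions, config.seed)
    }
    report = _cascade.run_cascade(
        block_stats=_dmr.block_stats(discovery, blocks),
        blocks=blocks,
        cpg_stats=_dmr.cpg_stats(discovery),
        validation_stats=_dmr.cpg_stats(validation),
        blood_means=[pbmc, pbl],
        annotation=annotation,
        sequences=sequences,
        config=cascade_config,
    )
    return report, truth, annotation


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def truth_eval(surviving_cpgs: "set[str] | list[str]", truth: GroundTruth) -> dict:
    """Recovery sensitivity and empirical FDR of a cascade's surviving CpGs."""
    survivors = set(surviving_cpgs)
    universe = set(truth.true_means.index)
    stray = survivors - universe
    if stray:
        raise ValueError(f"survivor ids absent from ground truth: {sorted(stray)[:5]}")
    planted = set(truth.planted_cpgs)
    tp = len(survivors & planted)
    fp = len(survivors - planted)
    return {
        "n_planted": len(planted),
        "n_survivors": len(survivors),
        "n_background_survivors": fp,
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "empirical_fdr": fp / len(survivors) if survivors else 0.0,
    }
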