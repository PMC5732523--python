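"""Readers, writers and the shared data model for the methylation-marker pipeline.

All in-memory genomic coordinates are 1-based inclusive (hg19-manifest
convention); BED export converts to 0-based half-open.  Missing beta values are
``NaN`` — never 0, since 0 is a valid methylation fraction.
CpG sites are strand-collapsed upstream; the package does not track strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("methmarker")

#: valid relation-to-CpG-island categories, as on 450K-style manifests
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: manifest file column -> internal annotation column
_MANIFEST_COLUMNS = {
    "IlmnID": "probe_id",
    "CHR": "chrom",
    "MAPINFO": "pos",
    "Gene": "gene",
    "Relation_to_Island": "island_relation",
    "SNP_in_primer": "snp_in_primer",
    "Prior_gene": "prior_gene",
}

#: float formatting used by every writer, so identical inputs give identical bytes
FLOAT_FORMAT = "%.6g"


def configure_logging(verbose: bool = False) -> None:
    """Route package log records to stderr (idempotent)."""
    root = logging.getLogger("methmarker")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicRegion:
    """A contiguous genomic interval holding an ordered run of CpG sites.

    ``start``/``end`` are 1-based inclusive; ``cpg_ids`` are sorted by
    genomic position.
    """

    chrom: str
    start: int
    end: int
    cpg_ids: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def span(self) -> int:
        """End minus start in bases (0 for a single-CpG region)."""
        return self.end - self.start


@dataclass
class BetaDataset:
    """One array-style methylation cohort: beta matrix + annotation + groups.

    ``beta`` is CpG x sample with values in [0, 1] or NaN; ``annotation`` is
    indexed by probe_id with columns chrom, pos, gene, island_relation,
    snp_in_primer, prior_gene; ``sample_groups`` maps sample id to
    "case"/"control".  ``covariates`` optionally carries the sample sheet.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    sample_groups: pd.Series
    dataset_id: str = ""
    covariates: pd.DataFrame | None = None

    def validate(self) -> None:
        if len(self.beta) != len(self.annotation):
            raise ValueError(
                f"beta has {len(self.beta)} rows but annotation has {len(self.annotation)}"
            )
        if not self.beta.index.equals(self.annotation.index):
            raise ValueError("beta and annotation indices differ")
        if self.beta.index.has_duplicates:
            dups = self.beta.index[self.beta.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                f"beta value {vals[i, j]} out of [0,1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )
        missing = set(self.beta.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)[:5]}")
        bad_groups = set(self.sample_groups.unique()) - {"case", "control"}
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.sample_groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.beta.columns if self.sample_groups[s] == "control"]


# ---------------------------------------------------------------------------
# beta matrix / manifest / sample sheet
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a 450K-manifest-like CSV into the internal annotation frame."""
    raw = pd.read_csv(path, dtype={"IlmnID": str, "CHR": str})
    missing = set(_MANIFEST_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    ann = raw.rename(columns=_MANIFEST_COLUMNS)[list(_MANIFEST_COLUMNS.values())]
    if ann["probe_id"].duplicated().any():
        dups = ann.loc[ann["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids in manifest: {dups[:5]}")
    ann = ann.set_index("probe_id")
    ann["pos"] = ann["pos"].astype(int)
    if (ann["pos"] < 1).any():
        raise ValueError("manifest positions must be >= 1")
    bad = set(ann["island_relation"].unique()) - set(ISLAND_RELATIONS)
    if bad:
        raise ValueError(f"unknown island relations: {sorted(bad)}")
    ann["gene"] = ann["gene"].where(ann["gene"].notna(), None)
    ann["snp_in_primer"] = ann["snp_in_primer"].astype(bool)
    ann["prior_gene"] = ann["prior_gene"].astype(bool)
    return ann


def write_manifest(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()
    out.columns = ["probe_id"] + list(annotation.columns)
    inv = {v: k for k, v in _MANIFEST_COLUMNS.items()}
    out = out.rename(columns=inv)
    out.to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV (sample_id, group, covariates...)."""
    sheet = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError(f"sample sheet {path} needs sample_id and group columns")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet.set_index("sample_id")


def read_beta_matrix(
    path: str | Path,
    manifest_path: str | Path,
    sample_sheet_path: str | Path,
    dataset_id: str = "",
) -> BetaDataset:
    """Read a beta-value TSV joined to its manifest and sample sheet.

    Probes absent from the manifest are dropped (count logged); beta values
    outside [0, 1] raise with the offending probe and sample named.
    """
    beta = pd.read_csv(path, sep="\t", index_col=0)
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    if beta.index.has_duplicates:
        dups = beta.index[beta.index.duplicated()].tolist()
        raise ValueError(f"duplicate probe ids in {path}: {dups[:5]}")
    ann = read_manifest(manifest_path)
    sheet = read_sample_sheet(sample_sheet_path)

    unknown_samples = set(beta.columns) - set(sheet.index)
    if unknown_samples:
        raise ValueError(
            f"samples in beta matrix absent from sample sheet: {sorted(unknown_samples)[:5]}"
        )

    in_manifest = beta.index.isin(ann.index)
    n_dropped = int((~in_manifest).sum())
    if n_dropped:
        logger.info("dropped %d probes absent from manifest (%s)", n_dropped, path)
        beta = beta.loc[in_manifest]

    ann = ann.loc[beta.index]
    groups = sheet.loc[beta.columns, "group"].astype(str)
    ds = BetaDataset(
        beta=beta.astype(float),
        annotation=ann,
        sample_groups=groups,
        dataset_id=dataset_id or Path(path).stem,
        covariates=sheet.loc[beta.columns],
    )
    ds.validate()
    return ds


def write_beta_dataset(ds: BetaDataset, beta_path: str | Path) -> None:
    ds.beta.to_csv(beta_path, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------


def write_regions_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED: 0-based half-open, name col 4, CpG ids col 5."""
    with open(path, "w") as fh:
        for r in regions:
            cpgs = ",".join(r.cpg_ids) if r.cpg_ids else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label or r.region_id}\t{cpgs}\n")


def read_regions_bed(path: str | Path) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED line has <3 columns")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            cpg_ids: tuple[str, ...] = ()
            if len(parts) > 4 and parts[4] != ".":
                cpg_ids = tuple(parts[4].split(","))
            regions.append(
                GenomicRegion(chrom=chrom, start=start0 + 1, end=end, cpg_ids=cpg_ids, label=label)
            )
    return regions


# ---------------------------------------------------------------------------
# targeted-BS count tables
# ---------------------------------------------------------------------------


@dataclass
class BsCounts:
    """Parsed targeted-BS calls: CpG count records plus conversion tallies.

    ``calls`` columns: sample_id, chrom, pos, cpg_id, methylated, total.
    ``conversion`` is indexed by sample with columns converted, total,
    accumulated from non-CpG cytosine rows (converted = total - methylated,
    non-CpG cytosines being assumed unmethylated).
    """

    calls: pd.DataFrame
    conversion: pd.DataFrame


def read_bs_counts(path: str | Path, sample_id: str | None = None) -> BsCounts:
    """Read a targeted-BS count TSV (chrom, pos, methylated_reads, total_reads, context).

    An optional leading ``sample_id`` column supports multi-sample files;
    otherwise ``sample_id`` (default: file stem) labels every row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    required = {"chrom", "pos", "methylated_reads", "total_reads", "context"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks columns: {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = sample_id or Path(path).stem
    df["sample_id"] = df["sample_id"].astype(str)

    if (df["methylated_reads"] < 0).any() or (df["total_reads"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    bad = df["methylated_reads"] > df["total_reads"]
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ValueError(
            f"{path}: methylated_reads {row.methylated_reads} > total_reads "
            f"{row.total_reads} at {row.chrom}:{row.pos} ({row.sample_id})"
        )

    is_cpg = df["context"] == "CpG"
    calls = df.loc[is_cpg, ["sample_id", "chrom", "pos", "methylated_reads", "total_reads"]]
    calls = calls.rename(columns={"methylated_reads": "methylated", "total_reads": "total"})
    calls = calls.assign(cpg_id=calls["chrom"] + ":" + calls["pos"].astype(str))

    non_cpg = df.loc[~is_cpg]
    conv = (
        non_cpg.groupby("sample_id")
        .agg(
            converted=("total_reads", "sum"),
            total=("total_reads", "sum"),
        )
        .astype(int)
    )
    # converted = total - methylated, summed per sample
    conv["converted"] = (
        non_cpg.assign(conv=non_cpg["total_reads"] - non_cpg["methylated_reads"])
        .groupby("sample_id")["conv"]
        .sum()
        .astype(int)
    )
    return BsCounts(calls=calls.reset_index(drop=True), conversion=conv)


def write_bs_counts(
    calls: pd.DataFrame, conversion: pd.DataFrame, path: str | Path
) -> None:
    """Write a multi-sample BS count TSV; conversion tallies become one non-CpG row per sample."""
    rows = calls.rename(columns={"methylated": "methylated_reads", "total": "total_reads"})
    rows = rows[["sample_id", "chrom", "pos", "methylated_reads", "total_reads"]]
    rows = rows.assign(context="CpG")
    conv_rows = pd.DataFrame(
        {
            "sample_id": conversion.index,
            "chrom": "chrNonCpG",
            "pos": 1,
            "methylated_reads": (conversion["total"] - conversion["converted"]).values,
            "total_reads": conversion["total"].values,
            "context": "CHH",
        }
    )
    pd.concat([rows, conv_rows], ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region sequences (for primer-difficulty scoring)
# ---------------------------------------------------------------------------


def write_region_sequences(
    records: Iterable[tuple[str, str, int]], path: str | Path
) -> None:
    """Write (region_id, sequence, snp_count) records as FASTA with ``snps=N``."""
    seq_records = [
        SeqRecord(Seq(seq), id=region_id, description=f"snps={snp_count}")
        for region_id, seq, snp_count in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_region_sequences(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a region-sequence FASTA back into {region_id: (sequence, snp_count)}."""
    out: dict[str, tuple[str, int]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        snp_count = 0
        for token in rec.description.split():
            if token.startswith("snps="):
                snp_count = int(token[5:])
        out[rec.id] = (str(rec.seq).upper(), snp_count)
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunables for a run, loadable from one YAML file with sections
    ``sim``, ``cascade``, ``qc``, ``models`` (each optional; defaults apply)."""

    sim: "object" = None  # SimConfig
    cascade: "object" = None  # CascadeConfig
    qc: "object" = None  # QcConfig
    models: "object" = None  # ModelConfig

    def __post_init__(self) -> None:
        from .bsqc import QcConfig
        from .cascade import CascadeConfig
        from .models import ModelConfig
        from .simulate import SimConfig

        if self.sim is None:
            self.sim = SimConfig()
        if self.cascade is None:
            self.cascade = CascadeConfig()
        if self.qc is None:
            self.qc = QcConfig()
        if self.models is None:
            self.models = ModelConfig()


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing file/sections/keys fall back to defaults."""
    from .bsqc import QcConfig
    from .cascade import CascadeConfig, StageThresholds
    from .models import ModelConfig
    from .simulate import SimConfig

    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def build(cls, section: dict):
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(section) - valid
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**section)

    cascade_raw = dict(raw.get("cascade", {}))
    for stage in ("stage1", "stage2", "stage3"):
        if stage in cascade_raw and isinstance(cascade_raw[stage], dict):
            cascade_raw[stage] = build(StageThresholds, cascade_raw[stage])
    return PipelineConfig(
        sim=build(SimConfig, raw.get("sim", {})),
        cascade=build(CascadeConfig, cascade_raw),
        qc=build(QcConfig, raw.get("qc", {})),
        models=build(ModelConfig, raw.get("models", {})),
    )
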