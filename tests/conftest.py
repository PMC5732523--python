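"""Shared fixtures: a small simulated study and a hand-built QC cohort."""

import numpy as np
import pandas as pd
import pytest

from methmarker import SimConfig
from methmarker.bsqc import BsCohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, small-universe study design for unit tests."""
    return SimConfig(
        n_background_cpg=400,
        n_planted_blocks=4,
        n_pbmc=20,
        n_pbl=30,
        n_pairs=20,
        n_low_conversion=1,
        n_high_missing=1,
        seed=7,
    )


def make_qc_cohort() -> BsCohort:
    """8 samples x 6 CpGs with exactly one violation of each QC rule.

    - S1: bisulfite conversion 0.97 (< 0.98)            -> removed, pass 1
    - C1: mean coverage 19x among remaining samples     -> removed, pass 2
    - C2: missing in 2 of the 7 remaining samples (0.29 > 0.20) -> removed, pass 2
    - S2: missing 2 of the 4 remaining CpGs (0.50 > 0.30)       -> removed, pass 3
    Expected survivors: 6 samples x 4 CpGs.
    """
    samples = [f"S{i}" for i in range(1, 9)]
    cpgs = [f"chr1:{100 + 10 * i}" for i in range(6)]  # C1..C6

    total = pd.DataFrame(30.0, index=cpgs, columns=samples)
    total.loc[cpgs[0]] = 19.0  # C1: low coverage
    total.loc[cpgs[1], ["S3", "S4"]] = 0.0  # C2: missing in 2 of 7 post-S1 samples
    total.loc[cpgs[2], "S2"] = 0.0  # S2's missing calls (C3, C4)
    total.loc[cpgs[3], "S2"] = 0.0
    meth = (total * 0.4).round()

    conversion = pd.DataFrame(
        {"converted": [970] + [990] * 7, "total": [1000] * 8}, index=samples
    )
    meta = pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(8)],
            "group": ["tumor", "normal"] * 4,
            "age": [60 + i for i in range(8)],
            "sex": ["male", "female"] * 4,
            "smoking": [True, False] * 4,
            "alcohol": [True, False] * 4,
        },
        index=samples,
    )
    positions = pd.DataFrame(
        {"chrom": "chr1", "pos": [100 + 10 * i for i in range(6)]}, index=cpgs
    )
    return BsCohort(
        samples=meta, meth=meth, total=total, conversion=conversion, cpg_positions=positions
    )


@pytest.fixture()
def qc_cohort() -> BsCohort:
    return make_qc_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
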