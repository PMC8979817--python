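"""Shared fixtures: handcrafted toy matrices and reusable simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylphase.diffmeth import call_group_specific, dmc_test, segment_dmrs
from methylphase.io_formats import CpGCountMatrix
from methylphase.synthetic_cohort import PlantSpec, SimConfig, simulate_methylomes


def make_matrix(meth, total, groups, positions=None, chrom="chr1", assay="WGBS"):
    """Build a CpGCountMatrix from plain lists; one sample per column."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    n_pos, n_samp = meth.shape
    if positions is None:
        positions = np.arange(n_pos) * 100 + 1000
    samples = [f"s{j + 1}" for j in range(n_samp)]
    meta = pd.DataFrame({"assay": assay, "group": list(groups)}, index=samples)
    meta.index.name = "sample_id"
    chroms = np.array([chrom] * n_pos, dtype=object)
    return CpGCountMatrix(chroms, np.asarray(positions), samples, meth, total, meta)


@pytest.fixture
def tiny_matrix():
    """Six CpGs, 3 reference + 3 tumor samples, strong signal at CpGs 2-4."""
    total = np.full((6, 6), 20)
    meth = np.array([
        [2, 3, 1, 2, 3, 2],
        [2, 1, 3, 18, 19, 17],
        [3, 2, 2, 19, 18, 18],
        [1, 2, 3, 17, 18, 19],
        [2, 3, 2, 3, 2, 1],
        [18, 17, 19, 18, 17, 19],
    ])
    return make_matrix(meth, total, ["ref"] * 3 + ["tum"] * 3)


SMALL_KW = dict(n_chroms=1, chrom_length_bp=1_200_000, n_cpgs=8000,
                groups=(("CD34", 4), ("IDH", 5), ("AML", 6)),
                planted_dmrs=(PlantSpec(("IDH",), 15, (12, 30), 0.4),),
                planted_shared_hyper=(), n_decoy_loops=20)


def small_config(seed, **overrides) -> SimConfig:
    """Desk-scale SimConfig: 1 chrom x 1.2 Mb, ~8k CpGs, 20 planted regions."""
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort with 15 planted target-specific regions."""
    cfg = small_config(11)
    matrix, truth = simulate_methylomes(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-scale cohort (2x5 Mb, ~50k CpGs, 100 planted regions)."""
    cfg = SimConfig(seed=2)
    matrix, truth = simulate_methylomes(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def study_analysis(study_cohort):
    """Two-stage analysis of the study cohort: (dmcs, dmrs, specific)."""
    _, matrix, _ = study_cohort
    dmcs = dmc_test(matrix, "CD34", "IDH")
    dmrs = segment_dmrs(dmcs, matrix, "CD34", "IDH")
    specific = call_group_specific(dmrs, matrix, "IDH", ["AML", "TET2"], ["TET2"])
    return dmcs, dmrs, specific
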