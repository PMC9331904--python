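"""Shared fixtures: small deterministic cohorts, pool plans and BAF data."""

import numpy as np
import pandas as pd
import pytest

import poolgwas as pg


@pytest.fixture(scope="session")
def trio():
    return pg.make_fixture("trio")


@pytest.fixture(scope="session")
def reference_cohort():
    return pg.make_fixture("reference-exact", seed=4)


@pytest.fixture(scope="session")
def small_cohort():
    """~120 related individuals with genotypes and traits (fast)."""
    cfg = pg.RunConfig(master_seed=9, cohort_size=120, n_variants=80,
                       write_genotype_vcf=False)
    cohort, panel, geno = pg.simulate_cohort(cfg)
    return cohort, panel, geno


@pytest.fixture(scope="session")
def default_scan_data():
    """Full-size cohort with pools, kinship and measured BAF (500 variants)."""
    cfg = pg.RunConfig(master_seed=1, cohort_size=1402, n_variants=500,
                       write_genotype_vcf=False)
    cohort, panel, geno = pg.simulate_cohort(cfg)
    kin = pg.pedigree_kinship(cohort)
    plan = pg.build_pool_plan(cohort, kinship=kin)
    plan = pg.replicate_and_batch(plan, seed=1)
    baf = pg.measure_baf(plan, cohort, geno, variant_ids=panel["id"].to_numpy(), seed=1)
    return cohort, panel, geno, plan, baf


@pytest.fixture(scope="session")
def six_pool_units():
    """Numerically benign 6-pool/12-unit table for single-variant fits."""
    return pd.DataFrame({
        "unit_id": [f"P{i}_R{r}" for i in range(1, 7) for r in (1, 2)],
        "pool_id": np.repeat([1, 2, 3, 4, 5, 6], 2),
        "replicate": np.tile([1, 2], 6),
        "chip": [(i + r - 1) % 2 + 1 for i in range(6) for r in (1, 2)],
        "n": np.repeat([50, 60, 70, 55, 65, 75], 2),
        "T2D": np.repeat([0, 1, 0, 1, 0, 1], 2),
        "HT_prop": np.repeat([0.2, 0.5, 0.8, 0.3, 0.6, 0.9], 2),
        "COB_prop": 0.5,
        "DL_prop": 0.5,
        "phi": 0.0,
    })


@pytest.fixture(scope="session")
def six_pool_baf():
    # overlapping BAF between outcome classes -> no separation
    return np.repeat([0.30, 0.35, 0.40, 0.28, 0.42, 0.33], 2) + np.tile([0.005, -0.005], 6)
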