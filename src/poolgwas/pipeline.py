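"""End-to-end orchestration: simulate -> pool -> associate -> report.

Also houses the registered test fixtures (``make_fixture``): tiny, fully
deterministic datasets used by the test-suite and by worked examples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._rng import stream
from .association import ModelSpec, run_gwas
from .config import RunConfig
from .exceptions import ConfigError, PoolGwasError
from .kinship import pedigree_kinship
from .pooling import (
    REFERENCE_COMBINATION_COUNTS,
    PoolBAFMatrix,
    build_pool_plan,
    measure_baf,
    replicate_and_batch,
)
from .reporting import manhattan_data, qq_data
from .simulate import (
    Cohort,
    LiabilityModel,
    assign_traits,
    default_panel,
    gene_drop,
    simulate_pedigrees,
)

__version__ = "0.1.0"
log = logging.getLogger("poolgwas")


@dataclass
class PipelineResult:
    cohort: Cohort
    panel: pd.DataFrame
    genotypes: np.ndarray
    plan: object
    baf: PoolBAFMatrix
    records: pd.DataFrame
    summary: object


def simulate_cohort(config: RunConfig) -> tuple[Cohort, pd.DataFrame, np.ndarray]:
    """Stages 1–3: pedigrees, gene-dropped genotypes, liability traits.

    Families are simulated until the cohort reaches at least the requested
    size, then truncated to it exactly (construction order puts parents
    before children, so a truncated suffix never orphans anyone).
    """
    config.validate()
    mean_size = float(config.family_distribution.get("mean_size", 4.0))
    n_fam = max(1, int(np.ceil(config.cohort_size / mean_size * 1.3)))
    cohort = simulate_pedigrees(n_fam, config.family_distribution, seed=config.master_seed)
    if cohort.n < config.cohort_size:  # rare; top up
        n_fam = int(n_fam * 1.5) + 2
        cohort = simulate_pedigrees(n_fam, config.family_distribution, seed=config.master_seed)
    cohort = Cohort(
        cohort.individuals.iloc[: config.cohort_size].reset_index(drop=True),
        metadata=cohort.metadata,
    )
    panel = default_panel(
        config.n_variants, seed=config.master_seed,
        maf_beta=config.maf_beta, causal=config.causal,
    )
    genotypes = gene_drop(cohort, panel, seed=config.master_seed)
    model = LiabilityModel(config.shared_loading, config.family_variance)
    assign_traits(
        cohort, genotypes, model, config.prevalences,
        seed=config.master_seed, panel=panel,
        require_t2d_case=config.require_t2d_case,
    )
    return cohort, panel, genotypes


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Run all stages; optionally write the artifact directory.

    Outputs are deterministic given the config (one master seed feeds named
    sub-streams per stage). The artifact directory is self-describing:
    ``run_metadata.json`` records the config, its hash, the package version
    and the scan summary.
    """
    stage = "simulate"
    try:
        cohort, panel, genotypes = simulate_cohort(config)
        stage = "kinship"
        kin = pedigree_kinship(cohort)
        stage = "pool"
        plan = build_pool_plan(cohort, config.pool_threshold, kinship=kin)
        plan = replicate_and_batch(
            plan, config.n_replicates, config.n_chips, seed=config.master_seed
        )
        log.info("pool plan: %d pools, %d units", plan.n_pools, plan.n_units)
        baf = measure_baf(
            plan, cohort, genotypes,
            variant_ids=panel["id"].to_numpy(),
            dirichlet_concentration=config.dirichlet_concentration,
            array_sd=config.array_sd,
            seed=config.master_seed,
        )
        stage = "assoc"
        spec = ModelSpec(reference=config.reference)
        records, summary = run_gwas(baf, panel=panel, alpha=config.alpha, spec=spec)
        log.info(
            "scan: m=%d, alpha*=%.3g, lambda=%.4f, %d significant",
            summary.m, summary.alpha_star, summary.lambda_gc, len(summary.significant),
        )
    except PoolGwasError as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    result = PipelineResult(cohort, panel, genotypes, plan, baf, records, summary)
    if outdir is not None:
        _write_artifacts(Path(outdir), config, result)
    return result


def _write_artifacts(outdir: Path, config: RunConfig, res: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_ped(outdir / "pedigree.ped", res.cohort)
    io.write_phenotypes(outdir / "phenotypes.tsv", res.cohort)
    res.panel.to_csv(outdir / "panel.tsv", sep="\t", index=False)
    if config.write_genotype_vcf:
        io.write_vcf(outdir / "genotypes.vcf", res.cohort, res.panel, res.genotypes)
    io.write_pool_plan(outdir / "pool_plan.tsv", res.plan)
    io.write_baf_long(outdir / "baf.tsv", res.baf)
    io.write_summary_stats(outdir / "summary_stats.tsv", res.records)
    valid = res.records["p"].dropna()
    if len(valid) >= 2:
        qq_data(valid).to_csv(outdir / "qq.tsv", sep="\t", index=False)
    if {"chrom", "pos"} <= set(res.records.columns):
        manhattan_data(res.records).to_csv(outdir / "manhattan.tsv", sep="\t", index=False)
    meta = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "n_pools": res.plan.n_pools,
        "n_units": res.plan.n_units,
        "m": res.summary.m,
        "alpha_star": res.summary.alpha_star,
        "lambda_gc": res.summary.lambda_gc,
        "n_significant": len(res.summary.significant),
        "pooling_error": res.summary.pooling_error,
        "rng_streams": "named sub-streams of master_seed (see poolgwas._rng)",
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("trio", "reference-exact", "null-5k", "causal-5k")


def make_fixture(name: str, seed: int = 0):
    """Small bundled datasets for tests and examples.

    - ``trio``: one father/mother/child family, no traits.
    - ``reference-exact``: a 1,402-member family cohort whose trait-combination
      counts equal the reference design's 16 counts exactly (labels assigned
      by seeded permutation).
    - ``null-5k``: cohort + 5,000-variant panel with zero causal effects.
    - ``causal-5k``: same but 5 variants carry liability effects of 0.3.
    """
    if name == "trio":
        return simulate_pedigrees(1, {"shape": "trio"}, seed=seed)
    if name == "reference-exact":
        cfg = RunConfig(master_seed=seed, cohort_size=1402, n_variants=1)
        cohort, _, _ = simulate_cohort(cfg)
        rng = stream(seed, "fixture")
        labels = np.repeat(np.arange(16), REFERENCE_COMBINATION_COUNTS)
        rng.shuffle(labels)
        bits = ((labels[:, None] >> np.array([3, 2, 1, 0])) & 1).astype(np.int8)
        for j, t in enumerate(("T2D", "CO", "HTN", "DL")):
            cohort.individuals[t] = bits[:, j]
        return cohort
    if name in ("null-5k", "causal-5k"):
        causal = {i: 0.3 for i in (10, 500, 1500, 3000, 4500)} if name == "causal-5k" else {}
        cfg = RunConfig(master_seed=seed, cohort_size=1402, n_variants=5000, causal=causal)
        cohort, panel, genotypes = simulate_cohort(cfg)
        return cohort, panel, genotypes
    raise ConfigError(f"unknown fixture {name!r}; available: {FIXTURES}")
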