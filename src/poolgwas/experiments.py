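"""Reusable simulation studies: null calibration, FWER, and power.

These functions run the full pipeline (cohort -> pools -> BAF -> scan)
under controlled conditions and summarize operating characteristics. They
back both the test-suite and the reproducibility script, and are useful for
planning: e.g. :func:`power_experiment` maps the detectable effect size of
a pooled design before any blood is drawn.
"""

from __future__ import annotations

import numpy as np

from .association import run_gwas
from .config import RunConfig
from .kinship import pedigree_kinship
from .pipeline import simulate_cohort
from .pooling import PoolBAFMatrix, build_pool_plan, measure_baf, replicate_and_batch


def _simulate_baf(seed: int, n_variants: int, cohort_size: int = 1402,
                  panel_override=None, **config_kwargs):
    """Cohort -> pools -> measured BAF under default study conditions."""
    cfg = RunConfig(master_seed=seed, cohort_size=cohort_size,
                    n_variants=n_variants, write_genotype_vcf=False, **config_kwargs)
    cohort, panel, geno = simulate_cohort(cfg)
    if panel_override is not None:
        panel = panel_override(panel)
        from .simulate import gene_drop

        geno = gene_drop(cohort, panel, seed=cfg.master_seed)
    kin = pedigree_kinship(cohort)
    plan = build_pool_plan(cohort, cfg.pool_threshold, kinship=kin)
    plan = replicate_and_batch(plan, cfg.n_replicates, cfg.n_chips, seed=seed)
    baf = measure_baf(
        plan, cohort, geno, variant_ids=panel["id"].to_numpy(),
        dirichlet_concentration=cfg.dirichlet_concentration,
        array_sd=cfg.array_sd, seed=seed,
    )
    return cohort, panel, plan, baf


def null_calibration(seed: int, n_variants: int = 10_000,
                     cohort_size: int = 1402) -> dict:
    """One all-null scan; returns tail fractions, lambda and extremes."""
    _, panel, plan, baf = _simulate_baf(seed, n_variants, cohort_size)
    records, summary = run_gwas(baf, panel=panel)
    p = records["p"].dropna().to_numpy()
    return {
        "m": summary.m,
        "n_valid": p.size,
        "frac_p_lt_05": float((p < 0.05).mean()),
        "lambda_gc": summary.lambda_gc,
        "min_p": float(p.min()),
        "alpha_star": summary.alpha_star,
        "n_significant": len(summary.significant),
        "pooling_error": summary.pooling_error,
    }


def fwer_experiment(n_seeds: int = 20, n_variants: int = 2_000,
                    seed0: int = 0, alpha: float = 0.05) -> dict:
    """Family-wise error rate of Bonferroni across independent null scans."""
    hits = 0
    for s in range(n_seeds):
        _, panel, plan, baf = _simulate_baf(seed0 + s, n_variants)
        records, summary = run_gwas(baf, panel=panel, alpha=alpha, pooling_error=False)
        hits += len(summary.significant) > 0
    return {"n_seeds": n_seeds, "n_variants": n_variants,
            "fwer": hits / n_seeds, "alpha": alpha}


def power_experiment(
    effects=(0.05, 0.10, 0.15),
    n_seeds: int = 50,
    seed0: int = 0,
    alpha_star: float = 0.05 / 5000,
    maf: float | None = None,
    n_context_variants: int = 40,
) -> dict:
    """Detection rate of a planted case-pool BAF shift, per effect size.

    Each replicate simulates a fresh cohort; the shift is added to the
    observed BAF of every T2D-pool measurement of one probe variant. By
    default the probe is the variant whose MAF is closest to the panel
    median (a neutral, computed choice); pass ``maf`` to force a specific
    probe allele frequency. The other ``n_context_variants`` null variants
    supply the replicate-variance estimate exactly as in a real scan.
    """
    effects = tuple(effects)
    detections = {e: 0 for e in effects}
    for s in range(n_seeds):
        def override(panel):
            panel = panel.copy()
            if maf is not None:
                panel.loc[0, "maf"] = maf
                probe = 0
            else:
                probe = int((panel["maf"] - panel["maf"].median()).abs().idxmin())
            panel.attrs["probe"] = probe
            return panel

        _, panel, plan, baf = _simulate_baf(seed0 + s, n_context_variants,
                                            panel_override=override)
        probe = panel.attrs["probe"]
        case = (baf.units["T2D"] == 1).to_numpy()
        for eff in effects:
            shifted = baf.baf.copy()
            shifted[case, probe] = np.clip(shifted[case, probe] + eff, 0.0, 1.0)
            baf2 = PoolBAFMatrix(baf=shifted, true_af=baf.true_af,
                                 units=baf.units, variant_ids=baf.variant_ids)
            records, _ = run_gwas(baf2, pooling_error=False)
            p = records["p"].iloc[probe]
            detections[eff] += bool(np.isfinite(p) and p < alpha_star)
    return {
        "n_seeds": n_seeds,
        "alpha_star": alpha_star,
        "maf": maf,
        "detection_rate": {e: detections[e] / n_seeds for e in effects},
    }


def permutation_check(seed: int = 0, effect: float = 0.10, n_permutations: int = 40,
                      alpha_star: float = 0.05 / 5000) -> dict:
    """Planted signal destroyed by permuting pool outcome labels.

    The planted variant (the panel's median-MAF variant, as in
    :func:`power_experiment`) is significant on the observed labels; after
    permuting T2D across pools (keeping pool composition fixed) the fraction
    of permutations still reaching alpha_star should be tiny. A permutation
    that happens to strongly overlap the original labels retains part of the
    planted contrast, so survival is bounded away from zero for very strong
    signals; the near-threshold effect used here makes survival rare.
    """
    rng = np.random.default_rng(seed)
    _, panel, plan, baf = _simulate_baf(seed, 40)
    probe = int((panel["maf"] - panel["maf"].median()).abs().idxmin())
    case = (baf.units["T2D"] == 1).to_numpy()
    shifted = baf.baf.copy()
    shifted[case, probe] = np.clip(shifted[case, probe] + effect, 0.0, 1.0)
    baf2 = PoolBAFMatrix(baf=shifted, true_af=baf.true_af,
                         units=baf.units, variant_ids=baf.variant_ids)
    records, _ = run_gwas(baf2, pooling_error=False)
    p_obs = float(records["p"].iloc[probe])
    pool_ids = baf.units["pool_id"].to_numpy()
    unique_pools = np.unique(pool_ids)
    pool_y = {pid: int(baf.units.loc[pool_ids == pid, "T2D"].iloc[0]) for pid in unique_pools}
    labels = np.array([pool_y[pid] for pid in unique_pools])
    n_surviving = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        units = baf.units.copy()
        units["T2D"] = units["pool_id"].map(dict(zip(unique_pools, perm)))
        baf_perm = PoolBAFMatrix(baf=shifted, true_af=baf.true_af,
                                 units=units, variant_ids=baf.variant_ids)
        try:
            rec, _ = run_gwas(baf_perm, pooling_error=False)
        except Exception:
            continue
        pv = rec["p"].iloc[probe]
        n_surviving += bool(np.isfinite(pv) and pv < alpha_star)
    return {
        "p_observed": p_obs,
        "significant_observed": p_obs < alpha_star,
        "n_permutations": n_permutations,
        "fraction_surviving": n_surviving / n_permutations,
    }
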