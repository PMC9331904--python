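"""Comorbidity-defined whole-blood pools and pooled B-allele frequencies.

The cohort is partitioned into the 16 combinations of the four binary traits
(T2D, CO, HTN, DL) in lexicographic order (No < Yes, DL varying fastest).
Combinations representing < 1% of the cohort are merged into the nearest
*preceding* retained combination with the same T2D status, so the pool
outcome stays constant; with the reference combination counts this yields 14
pools, measured in duplicate = 28 units.

The measurement model for a pool's observed B-allele frequency (BAF) has two
noise components:

* pipetting: per replicate, member contribution weights w ~ Dirichlet(c·1)
  over the pool's members (c -> inf recovers equal contributions); the true
  pooled allele frequency is sum_i w_i * g_i / 2;
* array: additive N(0, sigma^2) read noise, truncated to [0, 1].

Pooling error is estimated MacGregor-style from duplicate measurements: for
replicate differences d = BAF_rep1 - BAF_rep2, Var(d)/2 is the per-measurement
pooling/array variance component, and mean(d) the signed bias between
replicate runs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .exceptions import ConfigError, InputError
from .simulate import TRAITS, Cohort

#: Reference combination counts (lexicographic trait order) of the study
#: design this package emulates: 16 combinations over 1402 participants.
REFERENCE_COMBINATION_COUNTS = (190, 49, 65, 30, 230, 90, 224, 106, 22, 7, 19, 11, 38, 34, 179, 108)

_COMBOS = list(itertools.product((0, 1), repeat=4))  # (T2D, CO, HTN, DL)


# ---------------------------------------------------------------------------
# Trait combinations
# ---------------------------------------------------------------------------

def combination_table(counts) -> pd.DataFrame:
    """Build the 16-row combination table from counts in lexicographic order."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (16,) or (counts < 0).any():
        raise InputError("need 16 non-negative combination counts")
    df = pd.DataFrame(_COMBOS, columns=list(TRAITS))
    df["n"] = counts
    return df


def tabulate_combinations(cohort: Cohort) -> pd.DataFrame:
    """Count cohort members in each of the 16 trait combinations.

    Rows follow lexicographic (T2D, CO, HTN, DL) order with No < Yes. The
    returned frame has columns T2D, CO, HTN, DL, n; shares come from
    :func:`combination_shares` (which rejects an empty cohort).
    """
    traits = cohort.trait_matrix()
    if np.isnan(traits).any():  # pragma: no cover - int8 cannot hold NaN
        raise InputError("missing trait indicators")
    codes = traits @ np.array([8, 4, 2, 1])
    counts = np.bincount(codes, minlength=16)
    return combination_table(counts)


def combination_shares(combos: pd.DataFrame) -> pd.DataFrame:
    """Add a ``share`` column (n / total); error on an all-empty table."""
    total = int(combos["n"].sum())
    if total == 0:
        raise InputError("cannot compute combination shares of an empty cohort")
    out = combos.copy()
    out["share"] = out["n"] / total
    return out


# ---------------------------------------------------------------------------
# Pool plan
# ---------------------------------------------------------------------------

@dataclass
class PoolPlan:
    """Pools (one row per pool) and measurement units (one row per replicate).

    ``pools`` columns: pool_id, n, T2D, HT_prop, COB_prop, DL_prop, phi,
    merged_from (tuple of combination row indices 0–15).
    ``units`` (after :func:`replicate_and_batch`): unit_id, pool_id,
    replicate, chip plus the pool columns.
    ``members`` maps pool_id -> array of individual ids (empty when the plan
    was built from counts alone).
    """

    pools: pd.DataFrame
    units: pd.DataFrame | None = None
    members: dict[int, np.ndarray] = field(default_factory=dict)
    #: kinship-induced covariance coefficients of pool allele frequencies
    #: (pool_id x pool_id), present when the plan was built with a kinship
    #: matrix; see poolgwas.kinship.pool_af_covariance.
    pool_af_cov: pd.DataFrame | None = None

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_units(self) -> int:
        return 0 if self.units is None else len(self.units)

    def validate_partition(self, cohort_size: int) -> None:
        if int(self.pools["n"].sum()) != cohort_size:
            raise InputError("pool weights do not sum to cohort size")


def merge_rare_combinations(
    combos: pd.DataFrame, threshold: float = 0.01
) -> PoolPlan:
    """Merge combinations with share < ``threshold`` into earlier pools.

    Empty combinations are dropped. A rare combination is absorbed by the
    nearest preceding retained combination with the same T2D status (keeping
    the pool outcome constant); if none exists it merges forward with a
    warning. Repeats until every pool reaches the threshold. Covariate
    proportions of a merged pool are member-weighted trait proportions.
    """
    combos = combination_shares(combos)
    total = int(combos["n"].sum())
    # groups: list of (list of combo row indices); start with non-empty rows
    groups = [[i] for i in range(16) if combos["n"].iloc[i] > 0]

    def group_n(g):
        return int(combos["n"].iloc[g].sum())

    changed = True
    while changed:
        changed = False
        for gi, g in enumerate(groups):
            if group_n(g) / total >= threshold or threshold <= 0:
                continue
            t2d = combos["T2D"].iloc[g[0]]
            target = None
            for gj in range(gi - 1, -1, -1):
                if combos["T2D"].iloc[groups[gj][0]] == t2d:
                    target = gj
                    break
            if target is None:
                for gj in range(gi + 1, len(groups)):
                    if combos["T2D"].iloc[groups[gj][0]] == t2d:
                        target = gj
                        break
                if target is None:
                    raise InputError(
                        "no same-outcome pool available to absorb a rare combination"
                    )
                warnings.warn(
                    "rare combination merged forward (no preceding same-outcome pool)",
                    stacklevel=2,
                )
            groups[target] = sorted(groups[target] + g)
            del groups[gi]
            changed = True
            break

    rows = []
    for pid, g in enumerate(groups, start=1):
        sub = combos.iloc[g]
        n = int(sub["n"].sum())
        w = sub["n"] / n
        rows.append(
            {
                "pool_id": pid,
                "n": n,
                "T2D": int(sub["T2D"].iloc[0]),
                "HT_prop": float((w * sub["HTN"]).sum()),
                "COB_prop": float((w * sub["CO"]).sum()),
                "DL_prop": float((w * sub["DL"]).sum()),
                "phi": 0.0,
                "merged_from": tuple(g),
            }
        )
    return PoolPlan(pools=pd.DataFrame(rows))


def build_pool_plan(
    cohort: Cohort,
    threshold: float = 0.01,
    kinship: pd.DataFrame | None = None,
) -> PoolPlan:
    """Tabulate, merge and attach members (and PHI if kinship is given)."""
    from .kinship import pool_phi  # local import to avoid cycle

    combos = tabulate_combinations(cohort)
    plan = merge_rare_combinations(combos, threshold=threshold)
    traits = cohort.trait_matrix()
    codes = traits @ np.array([8, 4, 2, 1])
    ids = cohort.ids
    for _, row in plan.pools.iterrows():
        mask = np.isin(codes, list(row["merged_from"]))
        plan.members[int(row["pool_id"])] = ids[mask]
    plan.validate_partition(cohort.n)
    if kinship is not None:
        from .kinship import pool_af_covariance

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton pools are legitimate here
            plan.pools["phi"] = [
                pool_phi(kinship, plan.members[int(pid)])
                for pid in plan.pools["pool_id"]
            ]
        plan.pool_af_cov = pool_af_covariance(kinship, plan.members)
    return plan


def replicate_and_batch(
    plan: PoolPlan, n_replicates: int = 2, n_chips: int = 2, seed: int = 0
) -> PoolPlan:
    """Expand pools into replicate measurement units with chip labels.

    Replicates of one pool are spread over chips round-robin with a per-pool
    offset — chip = (pool_index + replicate) mod n_chips — so chip and
    replicate indicators are not aliased in the association design.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if n_chips < 1:
        raise ConfigError("n_chips must be >= 1")
    rows = []
    for pi, (_, pool) in enumerate(plan.pools.iterrows()):
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "unit_id": f"P{int(pool['pool_id']):02d}_R{rep}",
                    "pool_id": int(pool["pool_id"]),
                    "replicate": rep,
                    "chip": (pi + rep - 1) % n_chips + 1,
                    "n": int(pool["n"]),
                    "T2D": int(pool["T2D"]),
                    "HT_prop": pool["HT_prop"],
                    "COB_prop": pool["COB_prop"],
                    "DL_prop": pool["DL_prop"],
                    "phi": pool["phi"],
                }
            )
    plan.units = pd.DataFrame(rows)
    del seed  # deterministic layout; kept in the signature for API stability
    return plan


# ---------------------------------------------------------------------------
# BAF measurement
# ---------------------------------------------------------------------------

@dataclass
class PoolBAFMatrix:
    """Observed pooled BAFs (units x variants) plus the noiseless truth."""

    baf: np.ndarray
    true_af: np.ndarray
    units: pd.DataFrame
    variant_ids: np.ndarray
    pool_af_cov: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.baf.shape != self.true_af.shape:
            raise InputError("baf and true_af shapes differ")
        if self.baf.shape[0] != len(self.units):
            raise InputError("row count does not match unit metadata")
        if ((self.baf < 0) | (self.baf > 1)).any():
            raise InputError("BAF entries must lie in [0, 1]")


def measure_baf(
    plan: PoolPlan,
    cohort: Cohort,
    genotypes: np.ndarray,
    variant_ids=None,
    dirichlet_concentration: float = 50.0,
    array_sd: float = 0.01,
    seed: int = 0,
) -> PoolBAFMatrix:
    """Generate observed pooled BAFs for every measurement unit.

    One Dirichlet contribution-weight vector is drawn per (pool, replicate) —
    the physical pipetting is shared across variants — then per-variant array
    noise is added and the result truncated to [0, 1].
    ``dirichlet_concentration=inf`` forces exactly equal contributions.
    """
    if plan.units is None:
        raise ConfigError("call replicate_and_batch before measure_baf")
    if dirichlet_concentration <= 0:
        raise ConfigError("dirichlet_concentration must be > 0")
    if array_sd < 0:
        raise ConfigError("array_sd must be >= 0")
    if not plan.members:
        raise ConfigError("pool plan has no member lists; build it from a cohort")
    rng_w = stream(seed, "pipette")
    rng_a = stream(seed, "array")
    n_units, m = len(plan.units), genotypes.shape[1]
    true_af = np.empty((n_units, m))
    for u, (_, unit) in enumerate(plan.units.iterrows()):
        members = plan.members[int(unit["pool_id"])]
        if len(members) == 0:
            raise InputError(f"pool {unit['pool_id']} is empty")
        g = genotypes[cohort.index_of(members), :]
        if np.isinf(dirichlet_concentration):
            w = np.full(len(members), 1.0 / len(members))
        else:
            w = rng_w.dirichlet(np.full(len(members), dirichlet_concentration))
        true_af[u] = (w @ g) / 2.0
    obs = true_af + rng_a.normal(0.0, array_sd, size=true_af.shape)
    np.clip(obs, 0.0, 1.0, out=obs)
    if variant_ids is None:
        variant_ids = np.array([f"v{i}" for i in range(m)])
    return PoolBAFMatrix(
        baf=obs, true_af=true_af, units=plan.units.copy(),
        variant_ids=np.asarray(variant_ids), pool_af_cov=plan.pool_af_cov,
    )


def estimate_pooling_error(baf_matrix: PoolBAFMatrix) -> dict:
    """MacGregor-style pooling-error report from duplicate measurements.

    Returns ``mean_signed_diff`` (mean of d = BAF_rep1 - BAF_rep2 over all
    pool/variant replicate pairs), ``ci95`` (mean ± 1.96 sd(d), the spread of
    per-variant error estimates), and ``variance_component`` (Var(d)/2, the
    per-measurement pooling + array variance).
    """
    units = baf_matrix.units
    diffs = []
    for _, grp in units.groupby("pool_id"):
        if len(grp) < 2:
            raise ConfigError("pooling-error estimation needs >= 2 replicates per pool")
        rows = grp.sort_values("replicate").index.to_numpy()
        pos = units.index.get_indexer(rows)
        for a, b in itertools.combinations(pos, 2):
            diffs.append(baf_matrix.baf[a] - baf_matrix.baf[b])
    d = np.concatenate(diffs)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_signed_diff": mean,
        "ci95": (mean - 1.96 * sd, mean + 1.96 * sd),
        "variance_component": float(d.var(ddof=1) / 2.0),
        "n_pairs": d.size,
    }
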