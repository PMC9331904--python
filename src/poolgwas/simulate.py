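"""Synthetic family cohort: pedigrees, genotypes and metabolic traits.

Emulates a family-based metabolic cohort: related individuals in nuclear
through three-generation pedigrees, biallelic autosomal variants with
MAF >= 1%, and four correlated binary traits — type 2 diabetes (T2D),
central obesity (CO), hypertension (HTN) and dyslipidemia (DL) — generated
under a liability-threshold model.

The liability of trait *t* for individual *i* is

    L_ti = lambda_t * F_i  +  sqrt(v_fam) * A_{f(i),t}  +  G_i * 1[t = T2D]
           + sqrt(v_resid_t) * eps_ti

where ``F_i ~ N(0,1)`` is a latent metabolic-syndrome factor shared by the
four traits within an individual, ``A_{f,t} ~ N(0,1)`` is a per-family,
per-trait polygenic deviate, and ``G_i`` is the standardized causal-variant
score. Each liability is normalized to unit variance and thresholded at the
standard-normal quantile of the target prevalence, so marginal prevalences
match their targets in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .exceptions import ConfigError, PedigreeError

TRAITS = ("T2D", "CO", "HTN", "DL")

#: Marginal prevalences of (T2D, CO, HTN, DL) used as simulation defaults.
DEFAULT_PREVALENCES = (0.2982, 0.7198, 0.5293, 0.3103)

PED_COLUMNS = ("family_id", "id", "father_id", "mother_id", "sex")


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Individuals table plus (optionally) genotypes and trait indicators.

    ``individuals`` columns: id, family_id, father_id, mother_id, sex, and —
    after :func:`assign_traits` — one 0/1 column per trait in :data:`TRAITS`.
    Rows are in topological order: parents always precede their children.
    """

    individuals: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> np.ndarray:
        return self.individuals["id"].to_numpy()

    def index_of(self, ids) -> np.ndarray:
        lookup = pd.Series(np.arange(self.n), index=self.individuals["id"])
        return lookup.loc[np.asarray(ids)].to_numpy()

    @property
    def founder_mask(self) -> np.ndarray:
        return self.individuals["father_id"].isna().to_numpy()

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (father, mother); -1 for founders."""
        lookup = pd.Series(np.arange(self.n), index=self.individuals["id"])
        fa = self.individuals["father_id"].map(lookup).fillna(-1).astype(int).to_numpy()
        mo = self.individuals["mother_id"].map(lookup).fillna(-1).astype(int).to_numpy()
        return fa, mo

    def trait_matrix(self) -> np.ndarray:
        missing = [t for t in TRAITS if t not in self.individuals]
        if missing:
            raise ConfigError(f"traits not assigned yet: {missing}")
        return self.individuals[list(TRAITS)].to_numpy(dtype=np.int8)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ind = self.individuals
        if ind["id"].duplicated().any():
            raise PedigreeError("duplicate individual ids")
        has_f = ind["father_id"].notna()
        has_m = ind["mother_id"].notna()
        if (has_f != has_m).any():
            raise PedigreeError("individuals must have either both or neither parent")
        known = set(ind["id"])
        for col in ("father_id", "mother_id"):
            ref = ind.loc[ind[col].notna(), col]
            unknown = set(ref) - known
            if unknown:
                raise PedigreeError(f"unknown parent id(s): {sorted(unknown)[:5]}")
        # parents in same family, never self
        fam = pd.Series(ind["family_id"].to_numpy(), index=ind["id"])
        for col in ("father_id", "mother_id"):
            sub = ind[ind[col].notna()]
            if (sub[col].to_numpy() == sub["id"].to_numpy()).any():
                raise PedigreeError("individual is its own parent")
            if (fam.loc[sub[col]].to_numpy() != sub["family_id"].to_numpy()).any():
                raise PedigreeError("parent belongs to a different family")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        """Kahn-style check; also caches a parents-first topological order."""
        ind = self.individuals
        idx = pd.Series(np.arange(self.n), index=ind["id"])
        fa = ind["father_id"].map(idx).fillna(-1).astype(int).to_numpy()
        mo = ind["mother_id"].map(idx).fillna(-1).astype(int).to_numpy()
        depth = np.full(self.n, -1, dtype=int)
        depth[(fa < 0)] = 0
        for _ in range(self.n):
            todo = depth < 0
            if not todo.any():
                break
            ready = todo & (depth[fa] >= 0) & (depth[mo] >= 0)
            if not ready.any():
                raise PedigreeError("pedigree contains a cycle")
            depth[ready] = np.maximum(depth[fa[ready]], depth[mo[ready]]) + 1
        self.metadata["generation_depth"] = depth

    def generation_depth(self) -> np.ndarray:
        if "generation_depth" not in self.metadata:
            self._check_acyclic()
        return self.metadata["generation_depth"]


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _build_family(fam: int, size: int, extended: bool, rng: np.random.Generator):
    """Rows for one family of exactly ``size`` members (size >= 3).

    A founder couple plus children; in extended families the eldest child
    acquires a married-in founder spouse and grandchildren until the target
    size is reached, giving a three-generation pedigree.
    """
    fid = f"F{fam:04d}"
    rows = []

    def add(k, father=None, mother=None, sex=None):
        iid = f"{fid}_I{k:03d}"
        if sex is None:
            sex = "M" if rng.random() < 0.5 else "F"
        rows.append((fid, iid, father, mother, sex))
        return iid

    father = add(1, sex="M")
    mother = add(2, sex="F")
    k = 3
    remaining = size - 2
    # Extended shape needs at least: 1 child + married-in spouse + 1 grandchild.
    if extended and remaining >= 3:
        c1 = add(k, father, mother)
        c1_sex = rows[-1][4]
        k += 1
        spouse = add(k, sex="F" if c1_sex == "M" else "M")
        k += 1
        remaining -= 2
        gp = (c1, spouse) if c1_sex == "M" else (spouse, c1)
        n_grand = int(rng.integers(1, remaining + 1))
        for _ in range(n_grand):
            add(k, gp[0], gp[1])
            k += 1
        remaining -= n_grand
    while remaining > 0:
        add(k, father, mother)
        k += 1
        remaining -= 1
    return rows


def simulate_pedigrees(
    n_families: int,
    family_size_distribution: dict | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate family skeletons (no genotypes or traits yet).

    Parameters
    ----------
    n_families:
        Number of independent families (>= 1).
    family_size_distribution:
        Keys: ``mean_size`` (mean family size, >= 3; sizes are
        ``3 + Poisson(mean_size - 3)``), ``p_extended`` (probability a family
        is three-generational rather than nuclear), or ``shape: "trio"`` to
        force father/mother/one-child trios.
    seed:
        Master seed; the pedigree stream is derived from it.
    """
    if n_families < 1:
        raise ConfigError("n_families must be >= 1")
    spec = dict(family_size_distribution or {})
    shape = spec.pop("shape", None)
    mean_size = float(spec.pop("mean_size", 4.0))
    p_extended = float(spec.pop("p_extended", 0.3))
    if spec:
        raise ConfigError(f"unknown family_size_distribution keys: {sorted(spec)}")
    if shape not in (None, "trio"):
        raise ConfigError(f"unknown family shape {shape!r}")
    if mean_size < 3:
        raise ConfigError("mean_size must be >= 3 (founder couple plus one child)")
    if not 0 <= p_extended <= 1:
        raise ConfigError("p_extended must be in [0, 1]")

    rng = stream(seed, "pedigree")
    rows = []
    for fam in range(1, n_families + 1):
        if shape == "trio":
            size, extended = 3, False
        else:
            size = 3 + int(rng.poisson(mean_size - 3))
            extended = bool(rng.random() < p_extended) and size >= 6
        rows.extend(_build_family(fam, size, extended, rng))
    ind = pd.DataFrame(rows, columns=list(PED_COLUMNS))[
        ["id", "family_id", "father_id", "mother_id", "sex"]
    ]
    return Cohort(ind, metadata={"seed": seed, "n_families": n_families})


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------

def default_panel(
    n_variants: int,
    seed: int = 0,
    maf_beta: tuple[float, float] = (1.0, 3.0),
    causal: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Biallelic autosomal variant panel with MAF on [0.01, 0.5].

    MAFs follow a Beta(a, b) truncated to [0.01, 0.5] (drawn by inverse-CDF
    on the truncated range), reproducing an array-like spectrum skewed toward
    low frequencies while respecting the 1% inclusion floor. ``causal`` maps
    variant row index -> liability-scale effect of one standardized alt-dosage
    unit on the T2D liability (default: all zero).
    """
    rng = stream(seed, "misc")
    a, b = maf_beta
    dist = stats.beta(a, b)
    lo, hi = dist.cdf(0.01), dist.cdf(0.5)
    maf = dist.ppf(rng.uniform(lo, hi, size=n_variants))
    chrom = np.sort(rng.integers(1, 23, size=n_variants))
    pos = np.empty(n_variants, dtype=np.int64)
    for c in range(1, 23):
        m = chrom == c
        pos[m] = np.sort(rng.choice(200_000_000, size=m.sum(), replace=False))
    alleles = np.array(list("ACGT"))
    ref = rng.choice(alleles, size=n_variants)
    alt = np.array([rng.choice([x for x in "ACGT" if x != r]) for r in ref])
    effect = np.zeros(n_variants)
    for i, beta in (causal or {}).items():
        effect[i] = beta
    panel = pd.DataFrame(
        {
            "id": [f"var{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": maf,
            "effect": effect,
        }
    )
    return panel


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def gene_drop(cohort: Cohort, panel: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Drop genotypes through the pedigree; returns (n_individuals, n_variants).

    Founders are drawn Hardy–Weinberg at the panel MAF (alt = B allele);
    every non-founder receives one uniformly chosen allele from each parent's
    pair, so the output is Mendelian-consistent by construction. Entries
    count B alleles (0/1/2, int8). Processing is vectorized by generation.
    """
    rng = stream(seed, "genedrop")
    n, m = cohort.n, len(panel)
    maf = panel["maf"].to_numpy()
    fa, mo = cohort.parent_indices()
    depth = cohort.generation_depth()

    # allele pair per individual: a[:, :, 0] paternal, a[:, :, 1] maternal
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    founders = fa < 0
    nf = int(founders.sum())
    alleles[founders] = (rng.random((nf, m, 2)) < maf[None, :, None]).astype(np.int8)
    for d in range(1, depth.max() + 1):
        lev = np.flatnonzero(depth == d)
        if lev.size == 0:
            continue
        pick_f = rng.integers(0, 2, size=(lev.size, m))
        pick_m = rng.integers(0, 2, size=(lev.size, m))
        alleles[lev, :, 0] = np.take_along_axis(alleles[fa[lev]], pick_f[:, :, None], 2)[:, :, 0]
        alleles[lev, :, 1] = np.take_along_axis(alleles[mo[lev]], pick_m[:, :, None], 2)[:, :, 0]
    return alleles.sum(axis=2, dtype=np.int8)


# ---------------------------------------------------------------------------
# Liability-threshold traits
# ---------------------------------------------------------------------------

@dataclass
class LiabilityModel:
    """Variance decomposition of the four trait liabilities.

    ``shared_loading`` is the loading of the latent common factor (variance
    contribution = loading**2); ``family_variance`` the per-family polygenic
    variance; causal-variant effects come from the panel's ``effect`` column
    and act on the T2D liability only. The residual variance absorbs the
    remainder so each liability has unit variance.
    """

    shared_loading: float = 0.4
    family_variance: float = 0.2

    def residual_variance(self, genetic_variance: float = 0.0) -> float:
        v = 1.0 - self.shared_loading**2 - self.family_variance - genetic_variance
        if v <= 0:
            raise ConfigError(
                "liability variance not normalizable: shared^2 + family + genetic >= 1"
            )
        return v


def assign_traits(
    cohort: Cohort,
    genotypes: np.ndarray | None = None,
    liability_model: LiabilityModel | None = None,
    target_prevalences=DEFAULT_PREVALENCES,
    seed: int = 0,
    panel: pd.DataFrame | None = None,
    require_t2d_case: bool = False,
) -> Cohort:
    """Assign the four binary traits in place (returns the same cohort).

    Thresholds are standard-normal quantiles of the target prevalences; see
    the module docstring for the liability decomposition. With
    ``require_t2d_case`` the simulation is rejected-and-redrawn per family
    until every family carries at least one T2D case (an enrollment-style
    ascertainment; off by default).
    """
    model = liability_model or LiabilityModel()
    targets = np.asarray(target_prevalences, dtype=float)
    if targets.shape != (4,) or not ((targets > 0) & (targets < 1)).all():
        raise ConfigError("target_prevalences must be four values in (0, 1)")
    rng = stream(seed, "traits")
    n = cohort.n

    g_score = np.zeros(n)
    genetic_var = 0.0
    if genotypes is not None and panel is not None:
        eff = panel["effect"].to_numpy()
        nz = np.flatnonzero(eff)
        if nz.size:
            p = panel["maf"].to_numpy()[nz]
            std = (genotypes[:, nz] - 2 * p) / np.sqrt(2 * p * (1 - p))
            g_score = std @ eff[nz]
            genetic_var = float((eff[nz] ** 2).sum())
    v_resid_t2d = model.residual_variance(genetic_var)
    v_resid = model.residual_variance(0.0)

    fam_codes, fam_index = pd.factorize(cohort.individuals["family_id"])
    thresholds = stats.norm.isf(targets)

    def draw(active: np.ndarray) -> np.ndarray:
        k = int(active.sum())
        F = rng.standard_normal(k)
        A = rng.standard_normal((len(fam_index), 4))[fam_codes[active]]
        eps = rng.standard_normal((k, 4))
        liab = model.shared_loading * F[:, None] + np.sqrt(model.family_variance) * A
        liab[:, 0] += g_score[active] + np.sqrt(v_resid_t2d) * eps[:, 0]
        liab[:, 1:] += np.sqrt(v_resid) * eps[:, 1:]
        return (liab > thresholds).astype(np.int8)

    traits = draw(np.ones(n, dtype=bool))
    if require_t2d_case:
        for _ in range(1000):
            has_case = pd.Series(traits[:, 0]).groupby(fam_codes).transform("max").to_numpy()
            redo = has_case == 0
            if not redo.any():
                break
            traits[redo] = draw(redo)
        else:  # pragma: no cover - pathological prevalence
            raise ConfigError("could not ascertain a T2D case in every family")

    for j, t in enumerate(TRAITS):
        cohort.individuals[t] = traits[:, j]
    cohort.metadata["trait_seed"] = seed
    cohort.metadata["target_prevalences"] = tuple(targets)
    return cohort
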