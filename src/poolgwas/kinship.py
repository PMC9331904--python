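"""Pedigree kinship coefficients and the within-pool kinship covariate (PHI).

The kinship coefficient phi(i, j) is the probability that an allele drawn at
random from *i* and one drawn from *j* at the same locus are identical by
descent. It is computed by the standard pedigree recursion (founders are
mutually unrelated and non-inbred unless declared otherwise):

    phi(i, i) = 1/2 * (1 + phi(father_i, mother_i))
    phi(i, j) = 1/2 * (phi(father_i, j) + phi(mother_i, j))   (j not a
                descendant of i)

processed parents-before-children so each row only references finished rows.
The pool-level covariate PHI summarizes relatedness inside a DNA pool as the
mean of phi over all unordered distinct member pairs (configurable to the
median).

:func:`monte_carlo_kinship` is an algorithmically independent estimator —
repeated gene-dropping of uniquely labeled founder alleles — intended for
validating the recursion on small pedigrees.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._rng import stream
from .exceptions import PedigreeError
from .simulate import Cohort


def pedigree_kinship(cohort: Cohort) -> pd.DataFrame:
    """Kinship matrix (id x id DataFrame) from the pedigree recursion."""
    n = cohort.n
    fa, mo = cohort.parent_indices()
    depth = cohort.generation_depth()
    order = np.argsort(depth, kind="stable")
    K = np.zeros((n, n))
    done = np.zeros(n, dtype=bool)
    for i in order:
        if fa[i] < 0:
            K[i, i] = 0.5
        else:
            if not (done[fa[i]] and done[mo[i]]):  # pragma: no cover
                raise PedigreeError("parents must precede children")
            row = 0.5 * (K[fa[i]] + K[mo[i]])
            row[~done] = 0.0
            K[i, :] = row
            K[:, i] = row
            K[i, i] = 0.5 * (1.0 + K[fa[i], mo[i]])
        done[i] = True
    ids = cohort.ids
    return pd.DataFrame(K, index=ids, columns=ids)


def pool_phi(kinship: pd.DataFrame, pool_members, summary: str = "mean") -> float:
    """Pool-level kinship covariate: mean (or median) pairwise phi.

    A singleton pool has no pairs; it gets PHI = 0 with a warning.
    """
    members = list(pool_members)
    m = len(members)
    if m < 2:
        warnings.warn("pool has fewer than 2 members; PHI defined as 0", stacklevel=2)
        return 0.0
    sub = kinship.loc[members, members].to_numpy()
    iu = np.triu_indices(m, k=1)
    pairs = sub[iu]
    if summary == "mean":
        return float(pairs.mean())
    if summary == "median":
        return float(np.median(pairs))
    raise ValueError(f"unknown PHI summary {summary!r}")


def monte_carlo_kinship(
    cohort: Cohort, n_replicates: int = 100_000, seed: int = 0, chunk: int = 2_000
) -> pd.DataFrame:
    """Estimate kinship by gene-dropping uniquely labeled founder alleles.

    Each replicate drops one locus whose 2 * n_founders founder alleles carry
    distinct labels; phi(i, j) is estimated as the average over replicates of
    the fraction of the four cross-individual allele pairs that match. Only
    practical for small pedigrees (quadratic in cohort size, linear in
    replicates); serves as a validation oracle for
    :func:`pedigree_kinship`.
    """
    rng = stream(seed, "misc")
    n = cohort.n
    fa, mo = cohort.parent_indices()
    depth = cohort.generation_depth()
    founders = fa < 0
    founder_rank = np.cumsum(founders) - 1

    total = np.zeros((n, n))
    done = 0
    while done < n_replicates:
        r = min(chunk, n_replicates - done)
        lab = np.zeros((r, n, 2), dtype=np.int32)
        f_idx = np.flatnonzero(founders)
        lab[:, f_idx, 0] = 2 * founder_rank[f_idx]
        lab[:, f_idx, 1] = 2 * founder_rank[f_idx] + 1
        for d in range(1, depth.max() + 1):
            lev = np.flatnonzero(depth == d)
            if lev.size == 0:
                continue
            pf = rng.integers(0, 2, size=(r, lev.size))
            pm = rng.integers(0, 2, size=(r, lev.size))
            lab[:, lev, 0] = np.take_along_axis(lab[:, fa[lev], :], pf[:, :, None], 2)[:, :, 0]
            lab[:, lev, 1] = np.take_along_axis(lab[:, mo[lev], :], pm[:, :, None], 2)[:, :, 0]
        # phi_hat(i,j) = mean over the 4 allele pairs of IBD match
        match = (
            (lab[:, :, None, :, None] == lab[:, None, :, None, :])
            .sum(axis=(3, 4))
            .astype(np.float64)
        )
        total += match.sum(axis=0) / 4.0
        done += r
    est = total / n_replicates
    # self-kinship: the diagonal counted both self-pairs twice; recompute as
    # 1/2 * (1 + P(the two alleles of i are IBD)). The loop above gives
    # diag = (2 + 2 * P(a1 == a2)) / 4 = 1/2 * (1 + F_i) already.
    ids = cohort.ids
    return pd.DataFrame(est, index=ids, columns=ids)


def pool_af_covariance(kinship: pd.DataFrame, members_by_pool: dict) -> pd.DataFrame:
    """Kinship-induced covariance coefficients of pool allele frequencies.

    Under Hardy–Weinberg founders, the genotype covariance matrix is
    4 p(1-p) K (with K_ii = (1+F_i)/2), so the mean allele frequency of
    pool g, q_g = sum_{i in g} g_i / (2 n_g), satisfies

        Cov(q_g, q_h) = p(1-p) * (M' K M)_{gh} / (n_g n_h),

    where M is the pool membership indicator. This returns the coefficient
    matrix (M' K M)_{gh} / (n_g n_h), indexed by pool id; its diagonal is
    the familiar (1 + 2 (n_g - 1) phi_g) / (2 n_g) inflation and its
    off-diagonal captures relatives split across pools (e.g. a T2D-dense
    family contributing members to several case pools).
    """
    pool_ids = sorted(members_by_pool)
    K = kinship.to_numpy()
    idx = {iid: k for k, iid in enumerate(kinship.index)}
    cols = []
    for pid in pool_ids:
        v = np.zeros(len(K))
        for iid in members_by_pool[pid]:
            v[idx[iid]] = 1.0
        cols.append(v)
    M = np.column_stack(cols)
    n = M.sum(axis=0)
    coef = (M.T @ K @ M) / np.outer(n, n)
    return pd.DataFrame(coef, index=pool_ids, columns=pool_ids)


def kinship_to_long(kinship: pd.DataFrame) -> pd.DataFrame:
    """Long-format (id1, id2, phi) table of the upper triangle incl. diagonal."""
    ids = kinship.index.to_numpy()
    iu = np.triu_indices(len(ids))
    return pd.DataFrame(
        {"id1": ids[iu[0]], "id2": ids[iu[1]], "phi": kinship.to_numpy()[iu]}
    )
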