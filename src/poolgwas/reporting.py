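"""QQ/Manhattan plot data, top-hit pool summaries and nearest-gene annotation.

Coordinate contract: variant positions are 1-based (VCF convention), gene
intervals are 0-based half-open [start, end) (BED convention). The
conversion lives in one place (:func:`_gap_bp`): a variant at 1-based
position p occupies the half-open interval [p-1, p), and the distance to a
gene is the interval gap — the number of bases strictly between them, 0 for
overlap or direct adjacency. Strand is carried through but ignored for
distances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .pooling import PoolBAFMatrix


# ---------------------------------------------------------------------------
# QQ / Manhattan data
# ---------------------------------------------------------------------------

def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) with 95% order-statistic bands.

    The i-th smallest of m uniform p-values has expectation i/(m+1) and is
    Beta(i, m-i+1)-distributed; the bands are that Beta's 2.5% and 97.5%
    quantiles on the -log10 scale.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 2:
        raise InputError("qq_data needs at least 2 p-values")
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in (0, 1]")
    p = np.sort(p)
    m = p.size
    i = np.arange(1, m + 1)
    expected = i / (m + 1.0)
    lower = stats.beta.ppf(0.025, i, m - i + 1)
    upper = stats.beta.ppf(0.975, i, m - i + 1)
    return pd.DataFrame(
        {
            "expected": -np.log10(expected),
            "observed": -np.log10(p),
            "band_lower": -np.log10(upper),
            "band_upper": -np.log10(lower),
        }
    )


def manhattan_data(records: pd.DataFrame) -> pd.DataFrame:
    """Per-variant plot rows (converged records only) with cumulative position."""
    need = {"chrom", "pos", "p"}
    if not need <= set(records.columns):
        raise InputError("records need chrom, pos and p columns")
    df = records.loc[records["p"].notna(), ["variant", "chrom", "pos", "p"]].copy()
    df["chrom_num"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True).astype(int)
    df = df.sort_values(["chrom_num", "pos"], kind="stable").reset_index(drop=True)
    offset, cum = 0, []
    for _, grp in df.groupby("chrom_num", sort=True):
        cum.append(grp["pos"].to_numpy() + offset)
        offset += int(grp["pos"].max()) + 1
    df["cum_pos"] = np.concatenate(cum) if cum else np.array([], dtype=int)
    df["neglog10p"] = -np.log10(df["p"])
    return df.drop(columns="chrom_num")


# ---------------------------------------------------------------------------
# Nearest-gene annotation
# ---------------------------------------------------------------------------

def _gap_bp(pos_1based: np.ndarray, start0: float, end0: float) -> np.ndarray:
    """Interval gap between a 1-based point and a 0-based half-open interval."""
    v0 = pos_1based - 1  # variant occupies [v0, v0 + 1)
    return np.maximum(0, np.maximum(start0 - (v0 + 1), v0 - end0 + 0))


def annotate_nearest(
    variants: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    max_distance: int = 1_000_000,
) -> tuple[pd.DataFrame, dict]:
    """Nearest gene for each variant, plus a distance summary.

    ``variants`` needs id/chrom/pos (1-based); ``gene_intervals`` needs
    chrom/start/end (BED half-open) and name. Ties in distance go to the gene
    with the smaller start. Variants farther than ``max_distance`` from any
    gene are labeled intergenic; variants on chromosomes absent from the
    interval file are labeled unannotated with a warning.

    The summary reports the within-gene count/fraction and, over annotated
    non-overlapping variants, the mean distance with a normal-approximation
    95% confidence interval.
    """
    for col in ("chrom", "start", "end"):
        if col not in gene_intervals:
            raise InputError(f"gene_intervals missing column {col!r}")
    if (gene_intervals["start"] >= gene_intervals["end"]).any():
        raise InputError("gene intervals must satisfy start < end")
    genes = {
        str(c).removeprefix("chr"): g.sort_values(["start", "end"]).reset_index(drop=True)
        for c, g in gene_intervals.groupby("chrom")
    }
    rows = []
    missing_chroms = set()
    for _, v in variants.iterrows():
        chrom = str(v["chrom"]).removeprefix("chr")
        pos = int(v["pos"])
        g = genes.get(chrom)
        if g is None or len(g) == 0:
            missing_chroms.add(chrom)
            rows.append((v["id"], False, None, np.nan, "unannotated"))
            continue
        gaps = _gap_bp(np.full(len(g), pos), g["start"].to_numpy(), g["end"].to_numpy())
        best = np.flatnonzero(gaps == gaps.min())
        # ties: smaller start wins (frame is start-sorted, take the first)
        j = best[0]
        dist = int(gaps[j])
        if dist > max_distance:
            rows.append((v["id"], False, None, np.nan, "intergenic"))
            continue
        name = g["name"].iloc[j] if "name" in g else f"{chrom}:{g['start'].iloc[j]}"
        rows.append((v["id"], dist == 0, name, dist, "within" if dist == 0 else "near"))
    if missing_chroms:
        warnings.warn(
            f"no gene intervals for chromosome(s) {sorted(missing_chroms)}", stacklevel=2
        )
    ann = pd.DataFrame(
        rows, columns=["variant", "within_gene", "nearest_gene", "distance_bp", "label"]
    )
    annotated = ann["distance_bp"].notna()
    nonzero = ann.loc[annotated & (ann["distance_bp"] > 0), "distance_bp"]
    if len(nonzero) >= 2:
        mean = float(nonzero.mean())
        sem = float(nonzero.std(ddof=1) / np.sqrt(len(nonzero)))
        ci = (mean - 1.96 * sem, mean + 1.96 * sem)
    else:
        mean, ci = (float(nonzero.mean()) if len(nonzero) else float("nan")), (
            float("nan"),
            float("nan"),
        )
    summary = {
        "n_variants": len(ann),
        "n_within": int(ann["within_gene"].sum()),
        "fraction_within": float(ann["within_gene"].sum() / max(1, annotated.sum())),
        "mean_distance": mean,
        "ci95_distance": ci,
        "n_unannotated": int((ann["label"] == "unannotated").sum()),
        "n_intergenic": int((ann["label"] == "intergenic").sum()),
    }
    return ann, summary


# ---------------------------------------------------------------------------
# Top hits
# ---------------------------------------------------------------------------

def top_hits_summary(
    records: pd.DataFrame, baf_matrix: PoolBAFMatrix, k: int = 5
) -> list[dict]:
    """Replicate-level BAFs by pool T2D status for the k smallest p-values.

    Ranking ties are broken by variant id so top lists are reproducible.
    ``k`` beyond the converged-record count is truncated with a warning.
    """
    conv = records.loc[records["converged"] & records["p"].notna()]
    if k < 0:
        raise InputError("k must be >= 0")
    if k > len(conv):
        warnings.warn(f"only {len(conv)} converged records; truncating k", stacklevel=2)
        k = len(conv)
    ranked = conv.sort_values(["p", "variant"], kind="stable").head(k)
    vid_index = {v: i for i, v in enumerate(baf_matrix.variant_ids)}
    case = baf_matrix.units["T2D"].to_numpy() == 1
    out = []
    for _, row in ranked.iterrows():
        col = baf_matrix.baf[:, vid_index[row["variant"]]]
        out.append(
            {
                "variant": row["variant"],
                "p": float(row["p"]),
                "beta": float(row["beta"]),
                "baf_case_pools": col[case].tolist(),
                "baf_control_pools": col[~case].tolist(),
                "mean_case": float(col[case].mean()),
                "mean_control": float(col[~case].mean()),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Optional rendering (side-effect-free: draws onto a provided/created figure)
# ---------------------------------------------------------------------------

def plot_qq(qq: pd.DataFrame, ax=None):
    """Render QQ data; requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(qq["expected"], qq["band_lower"], qq["band_upper"], alpha=0.2)
    ax.plot(qq["expected"], qq["observed"], ".", ms=3)
    lim = qq["expected"].max()
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    return ax


def plot_manhattan(mh: pd.DataFrame, threshold: float | None = None, ax=None):
    """Render Manhattan data; requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for i, (_, grp) in enumerate(mh.groupby("chrom", sort=False)):
        ax.plot(grp["cum_pos"], grp["neglog10p"], ".", ms=2, color=f"C{i % 2}")
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=1)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("$-\\log_{10} p$")
    return ax
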