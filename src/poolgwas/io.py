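"""Readers and writers for the standard interchange formats.

Genotypes travel as VCF (GT field, autosomes, 1-based positions; pysam),
phenotypes as TSV, pedigrees as whitespace-delimited PED-like files, gene
intervals as BED (0-based half-open), kinship as long-format TSV, and the
pool plan / BAF matrix / summary statistics as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .exceptions import InputError
from .simulate import PED_COLUMNS, TRAITS, Cohort


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(path, cohort: Cohort, panel: pd.DataFrame, genotypes: np.ndarray) -> None:
    """Write the genotype matrix as an uncompressed VCF with GT records."""
    if genotypes.shape != (cohort.n, len(panel)):
        raise InputError("genotype matrix shape does not match cohort/panel")
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Panel allele frequency">')
    for c in sorted({str(c) for c in panel["chrom"]}, key=lambda x: int(x)):
        maxpos = int(panel.loc[panel["chrom"].astype(str) == c, "pos"].max())
        header.add_line(f"##contig=<ID={c},length={maxpos + 1000}>")
    for s in cohort.ids:
        header.add_sample(str(s))
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in panel.reset_index(drop=True).iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(row["id"]),
            )
            rec.info["AF"] = float(row["maf"])
            col = genotypes[:, j]
            for s, g in zip(header.samples, col):
                rec.samples[s]["GT"] = gt_codes[int(g)]
            vcf.write(rec)


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Read a VCF into (panel frame, genotype matrix, sample ids).

    MAF is taken from INFO/AF when present, otherwise computed from the
    genotypes (folded to the minor allele)."""
    panel_rows, columns = [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise InputError(f"variant {rec.id} is not biallelic")
            g = np.array(
                [sum(a or 0 for a in rec.samples[s]["GT"]) for s in samples], dtype=np.int8
            )
            af = rec.info.get("AF")
            if af is not None:
                maf = float(af[0] if isinstance(af, tuple) else af)
            else:
                f = g.sum() / (2 * len(g))
                maf = min(f, 1 - f)
            panel_rows.append(
                (rec.id or f"{rec.chrom}:{rec.pos}", str(rec.chrom), rec.pos,
                 rec.ref, rec.alts[0], maf, 0.0)
            )
            columns.append(g)
    panel = pd.DataFrame(
        panel_rows, columns=["id", "chrom", "pos", "ref", "alt", "maf", "effect"]
    )
    genotypes = np.column_stack(columns) if columns else np.zeros((len(samples), 0), np.int8)
    return panel, genotypes, samples


# ---------------------------------------------------------------------------
# PED / phenotypes / BED / TSV artifacts
# ---------------------------------------------------------------------------

def write_ped(path, cohort: Cohort) -> None:
    ind = cohort.individuals
    out = pd.DataFrame(
        {
            "family_id": ind["family_id"],
            "id": ind["id"],
            "father_id": ind["father_id"].fillna("0"),
            "mother_id": ind["mother_id"].fillna("0"),
            "sex": ind["sex"],
        }
    )
    out.to_csv(path, sep=" ", header=False, index=False)


def read_ped(path) -> Cohort:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=list(PED_COLUMNS), dtype=str)
    df = df.replace({"father_id": {"0": None}, "mother_id": {"0": None}})
    return Cohort(df[["id", "family_id", "father_id", "mother_id", "sex"]])


def write_phenotypes(path, cohort: Cohort) -> None:
    cols = ["id", "family_id", *TRAITS]
    cohort.individuals[cols].to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"id", *TRAITS} - set(df.columns)
    if missing:
        raise InputError(f"phenotype file missing columns: {sorted(missing)}")
    return df


def read_bed(path) -> pd.DataFrame:
    """BED3+ reader: chrom, start, end, [name, score, strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    return df


def write_pool_plan(path, plan) -> None:
    if plan.units is None:
        raise InputError("pool plan has no measurement units yet")
    plan.units.to_csv(path, sep="\t", index=False)


def write_baf_long(path, baf_matrix) -> None:
    """Long-format BAF table: unit_id, variant, baf."""
    units = baf_matrix.units["unit_id"].to_numpy()
    df = pd.DataFrame(
        {
            "unit_id": np.repeat(units, len(baf_matrix.variant_ids)),
            "variant": np.tile(baf_matrix.variant_ids, len(units)),
            "baf": baf_matrix.baf.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summary_stats(path, records: pd.DataFrame) -> None:
    cols = [c for c in ("variant", "chrom", "pos", "beta", "se", "stat", "p", "tau2",
                        "converged", "aliased") if c in records.columns]
    records[cols].to_csv(path, sep="\t", index=False)
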