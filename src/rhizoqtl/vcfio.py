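"""Variant-table and phenotype-table file adapters.

The on-disk variant format is a two-sample VCF (samples ``LOW`` and ``HIGH``,
allele depths in the per-sample ``AD`` field, 1-based positions) or an
equivalent TSV with explicit depth columns.  A bulk whose AD is absent or
sums to zero is treated as missing at that site; a record with more than one
alternate allele is flagged multiallelic, with the second alternate's depth
preserved.
"""

from __future__ import annotations

import pysam
import numpy as np
import pandas as pd

from .errors import FormatError

VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "alt2",
    "ref_depth_low", "alt_depth_low", "alt2_depth_low",
    "ref_depth_high", "alt_depth_high", "alt2_depth_high",
    "missing_low", "missing_high", "multiallelic",
]

LOW_SAMPLE = "LOW"
HIGH_SAMPLE = "HIGH"


def write_vcf(table: pd.DataFrame, path, contig_lengths: dict | None = None):
    """Write a variant table as an uncompressed two-sample VCF."""
    header = pysam.VariantHeader()
    header.add_meta("source", "rhizoqtl")
    chroms = list(pd.unique(table["chrom"]))
    for name in chroms:
        if contig_lengths and name in contig_lengths:
            length = int(contig_lengths[name])
        else:
            length = int(table.loc[table["chrom"] == name, "pos"].max()) + 1
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer",
                       "Read depth for each allele (ref, alt[, alt2])")
    header.add_sample(LOW_SAMPLE)
    header.add_sample(HIGH_SAMPLE)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            alleles = [row.ref, row.alt]
            if row.multiallelic and row.alt2:
                alleles.append(row.alt2)
            rec = vcf.new_record(contig=row.chrom, start=int(row.pos) - 1,
                                 alleles=tuple(alleles))
            for sample, tag in ((LOW_SAMPLE, "low"), (HIGH_SAMPLE, "high")):
                depths = [int(getattr(row, f"ref_depth_{tag}")),
                          int(getattr(row, f"alt_depth_{tag}"))]
                if len(alleles) == 3:
                    depths.append(int(getattr(row, f"alt2_depth_{tag}")))
                if getattr(row, f"missing_{tag}"):
                    rec.samples[sample]["AD"] = tuple([None] * len(alleles))
                else:
                    rec.samples[sample]["AD"] = tuple(depths)
            vcf.write(rec)


def read_vcf(path, low_sample: str = LOW_SAMPLE,
             high_sample: str = HIGH_SAMPLE) -> pd.DataFrame:
    """Read a two-sample VCF into the variant-table layout, sorted by site."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for sample in (low_sample, high_sample):
            if sample not in vcf.header.samples:
                raise FormatError(f"sample {sample!r} absent from {path}")
        for rec in vcf:
            alts = rec.alts or ()
            n_alleles = 1 + len(alts)
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alts[0] if alts else "",
                "alt2": alts[1] if len(alts) > 1 else "",
                "multiallelic": len(alts) > 1,
            }
            for sample, tag in ((low_sample, "low"), (high_sample, "high")):
                fmt = rec.samples[sample]
                if "AD" not in fmt or fmt.get("AD") is None:
                    raise FormatError(
                        f"sample {sample!r} lacks AD at {rec.contig}:{rec.pos}"
                    )
                ad = [0 if v is None else int(v) for v in fmt["AD"]]
                ad += [0] * (n_alleles - len(ad))
                row[f"ref_depth_{tag}"] = ad[0]
                row[f"alt_depth_{tag}"] = ad[1] if n_alleles > 1 else 0
                row[f"alt2_depth_{tag}"] = ad[2] if n_alleles > 2 else 0
                row[f"missing_{tag}"] = sum(ad) == 0
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    out = pd.DataFrame(rows)[VARIANT_COLUMNS]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_variants_tsv(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(VARIANT_COLUMNS) - set(t.columns)
    # alt2 columns are optional in hand-made tables
    optional = {"alt2", "alt2_depth_low", "alt2_depth_high"}
    if missing - optional:
        raise FormatError(f"variant TSV lacks columns {sorted(missing - optional)}")
    for col in optional & missing:
        t[col] = 0 if "depth" in col else ""
    t["alt2"] = t["alt2"].fillna("")
    for col in ("missing_low", "missing_high", "multiallelic"):
        t[col] = t[col].astype(bool)
    return t[VARIANT_COLUMNS].sort_values(
        ["chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)


def write_phenotypes_tsv(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    needed = {"id", "block", "ras_g", "rt_g"}
    if not needed.issubset(t.columns):
        raise FormatError(f"phenotype TSV lacks columns {sorted(needed - set(t.columns))}")
    return t


def read_gwas_hits_tsv(path) -> pd.DataFrame:
    """GWAS hit list: columns chrom, pos and optionally p_value."""
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos"}.issubset(t.columns):
        raise FormatError("GWAS hits TSV needs columns chrom, pos")
    t["pos"] = t["pos"].astype(np.int64)
    return t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
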