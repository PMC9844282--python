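"""Reading and writing dosage matrices (VCF or TSV + sidecar metadata)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DosageMatrix


def write_dosage_tsv(geno: DosageMatrix, dosage_path: str | Path, variants_path: str | Path) -> None:
    """Dosages as a samples x variants TSV plus a variant-metadata sidecar TSV."""
    var_ids = [f"{c}:{p}" for c, p in geno.variant_keys()]
    df = pd.DataFrame(geno.dosages, index=geno.samples, columns=var_ids)
    df.index.name = "sample"
    df.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%.6g")
    geno.variants.to_csv(variants_path, sep="\t", index=False, float_format="%.8g")


def read_dosage_tsv(dosage_path: str | Path, variants_path: str | Path) -> DosageMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col="sample", na_values=["NA"])
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return DosageMatrix(
        samples=[str(s) for s in df.index],
        variants=variants,
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf(path: str | Path, info_field: str = "INFO") -> DosageMatrix:
    """Load a VCF into a DosageMatrix; DS preferred over GT when present.

    The imputation-quality score is taken from the INFO column entry named
    ``info_field`` (default ``INFO``; ``R2`` is a common alternative) and
    defaults to 1.0 when absent.  Multiallelic sites are skipped.
    """
    from cyvcf2 import VCF  # deferred: only needed on the VCF path

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        fmt = rec.FORMAT
        if "DS" in fmt:
            ds = np.asarray(rec.format("DS"), dtype=float).reshape(-1)
        else:
            gt = rec.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            ds = np.where(gt == 3, 2.0, gt)
            ds[gt == 2] = np.nan
        try:
            info_val = float(rec.INFO.get(info_field, 1.0))
        except (TypeError, ValueError):
            info_val = 1.0
        chrom = rec.CHROM[3:] if rec.CHROM.lower().startswith("chr") else rec.CHROM
        rows.append(
            {
                "chrom": chrom,
                "pos": rec.POS,
                "counted_allele": rec.ALT[0],
                "other_allele": rec.REF,
                "info": info_val,
                "freq": np.nan,
            }
        )
        dosage_cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    geno = DosageMatrix(samples=samples, variants=variants, dosages=dosages)
    geno.variants["freq"] = geno.recompute_freq()
    return geno


def write_vcf(geno: DosageMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF with a DS (dosage) FORMAT field.

    The counted allele is written as ALT so dosages round-trip unchanged.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        v = geno.variants
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
        for j in order:
            row = v.iloc[j]
            ds = geno.dosages[:, j]
            ds_str = "\t".join("." if np.isnan(d) else f"{d:.4g}" for d in ds)
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['chrom']}:{int(row['pos'])}\t"
                f"{row['other_allele']}\t{row['counted_allele']}\t.\t.\t"
                f"INFO={row['info']:.4g}\tDS\t{ds_str}\n"
            )
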