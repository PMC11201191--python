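"""Readers and writers for the cohort's on-disk formats.

Two plain-text inputs describe a cohort:

* a phenotype/covariate CSV with columns
  ``id, score, age_months, sex, pe_father, pe_mother`` (PE is derived as
  the mean of the two parent levels);
* an additive dosage table in the PLINK ``.raw`` style — tab-delimited,
  ``FID`` and ``IID`` columns followed by one column per SNP named
  ``<snp_id>_<risk_allele>`` holding risk-allele counts 0/1/2 (blank or
  ``NA`` for missing) — or a VCF whose GT fields are mapped to risk-allele
  dosages via the SNP metadata.

SNP metadata travels as a CSV with columns ``snp_id, risk_allele,
other_allele, source_beta, source_trait, gene_label, base_pair``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from gxecross.cohort import Cohort
from gxecross.qc import SnpInfo, compute_cgs

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_dosages_raw",
    "write_dosages_raw",
    "read_vcf_dosages",
    "read_snp_info",
    "write_snp_info",
]

PHENOTYPE_COLUMNS = ["id", "score", "age_months", "sex", "pe_father", "pe_mother"]


def write_dosages_raw(dosages: pd.DataFrame, ids, path, snp_info: pd.DataFrame | None = None):
    """Write a tab-delimited additive dosage table (PLINK-.raw style)."""
    out = pd.DataFrame({"FID": ids, "IID": ids})
    for snp in dosages.columns:
        name = snp
        if snp_info is not None and snp in snp_info.index:
            name = f"{snp}_{snp_info.loc[snp, 'risk_allele']}"
        col = dosages[snp].to_numpy(dtype=float)
        out[name] = [("" if np.isnan(v) else str(int(v))) for v in col]
    out.to_csv(path, sep="\t", index=False)


def read_dosages_raw(path) -> pd.DataFrame:
    """Read a PLINK-.raw-style dosage table; index = IID, columns = snp ids."""
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    if "IID" not in df.columns:
        raise ValueError(f"{path}: missing IID column (not a .raw-style table)")
    ids = df["IID"]
    dose = df.drop(columns=[c for c in ("FID", "IID") if c in df.columns])
    # strip the _<allele> suffix PLINK appends to counted-allele columns
    renames = {}
    for c in dose.columns:
        if "_" in c:
            stem, suffix = c.rsplit("_", 1)
            if suffix.isalpha() and suffix.isupper() and len(suffix) <= 2:
                renames[c] = stem
    dose = dose.rename(columns=renames).apply(pd.to_numeric, errors="coerce")
    dose.index = ids
    return dose


def write_cohort(cohort: Cohort, out_dir, snp_info: pd.DataFrame | None = None):
    """Write phenotype CSV and dosage table; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pheno_path = out_dir / "phenotypes.csv"
    geno_path = out_dir / "genotypes.raw"
    cohort.phenotype_frame().to_csv(pheno_path, index=False, float_format="%.10g")
    write_dosages_raw(cohort.dosages, cohort.ids, geno_path, snp_info)
    return pheno_path, geno_path


def read_cohort(phenotype_csv, genotype_path, snp_info: list[SnpInfo] | None = None) -> Cohort:
    """Assemble the complete-case analysis set from on-disk files.

    Rows with any missing phenotype, covariate or dosage value are dropped
    (complete-case contract); individuals are matched between the two
    files by id.
    """
    pheno = pd.read_csv(phenotype_csv, dtype={"id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"{phenotype_csv}: missing columns {missing}")
    genotype_path = Path(genotype_path)
    if genotype_path.suffix.lower() == ".vcf":
        if snp_info is None:
            raise ValueError("reading VCF genotypes requires SNP metadata")
        dose = read_vcf_dosages(genotype_path, snp_info)
    else:
        dose = read_dosages_raw(genotype_path)
    merged = pheno.set_index("id").join(dose, how="inner")
    merged = merged.dropna()
    if len(merged) == 0:
        raise ValueError("no complete cases after matching phenotype and genotype files")
    snp_cols = [c for c in dose.columns]
    pe = (merged["pe_father"].to_numpy(float) + merged["pe_mother"].to_numpy(float)) / 2.0
    return Cohort(
        ids=merged.index.to_numpy(dtype=str),
        phenotype=merged["score"].to_numpy(float),
        pe=pe,
        age=merged["age_months"].to_numpy(float),
        sex=merged["sex"].to_numpy(int),
        dosages=merged[snp_cols].astype(float).reset_index(drop=True),
        cgs=compute_cgs(merged[snp_cols]),
        pe_father=merged["pe_father"].to_numpy(int),
        pe_mother=merged["pe_mother"].to_numpy(int),
    )


def read_vcf_dosages(path, snp_info: list[SnpInfo]) -> pd.DataFrame:
    """Risk-allele dosages from a VCF's GT fields.

    For each SNP in ``snp_info`` present in the VCF, genotype allele
    indices are mapped to REF/ALT bases and the declared risk allele is
    counted.  Missing GTs become NaN.
    """
    from cyvcf2 import VCF

    info = {s.snp_id: s for s in snp_info}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        snp = info.get(var.ID)
        if snp is None:
            continue
        alleles = [var.REF] + list(var.ALT)
        declared = {snp.risk_allele, snp.other_allele}
        if not set(alleles) <= declared:
            raise ValueError(
                f"{snp.snp_id}: VCF alleles {alleles} do not match declared {sorted(declared)}"
            )
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            dos[i] = sum(1 for idx in (a, b) if alleles[idx] == snp.risk_allele)
        cols[snp.snp_id] = dos
    if not cols:
        raise ValueError(f"{path}: none of the panel SNPs found in VCF")
    return pd.DataFrame(cols, index=pd.Index(samples, name="IID"))


def read_snp_info(path) -> list[SnpInfo]:
    """SNP metadata CSV -> list of :class:`~gxecross.qc.SnpInfo`."""
    df = pd.read_csv(path)
    required = {"snp_id", "risk_allele", "other_allele"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: SNP metadata needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SnpInfo(
                snp_id=str(row["snp_id"]),
                risk_allele=str(row["risk_allele"]),
                other_allele=str(row["other_allele"]),
                source_beta=float(row["source_beta"]) if "source_beta" in df.columns and pd.notna(row.get("source_beta")) else None,
                source_trait=str(row.get("source_trait", "") or ""),
                gene_label=str(row.get("gene_label", "") or ""),
                base_pair=int(row["base_pair"]) if "base_pair" in df.columns and pd.notna(row.get("base_pair")) else None,
            )
        )
    return out


def write_snp_info(snps: list[SnpInfo] | pd.DataFrame, path):
    """Write SNP metadata CSV."""
    if isinstance(snps, pd.DataFrame):
        snps.to_csv(path, index=False)
        return
    pd.DataFrame(
        [
            dict(
                snp_id=s.snp_id,
                risk_allele=s.risk_allele,
                other_allele=s.other_allele,
                source_beta=s.source_beta,
                source_trait=s.source_trait,
                gene_label=s.gene_label,
                base_pair=s.base_pair,
            )
            for s in snps
        ]
    ).to_csv(path, index=False)
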