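"""Readers and writers for the pipeline's file formats.

Genotypes travel as minimal VCF v4.2 (GT, optionally AD); allele-balance
profiles as VCF with AD or as a four-column table (chrom, pos, ref_count,
alt_count); phenotypes, truth and all stage reports as tab-separated tables
with documented headers.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aortic import AorticMeasure, SubjectRecord, Vessel
from .karyotype import ReadCountSite
from .qc import MISSING, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_read_counts_vcf",
    "write_read_counts_table",
    "read_read_counts_table",
    "write_phenotype_table",
    "read_phenotype_table",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_CODE_GT = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
            "1/1": 2, "1|1": 2, "./.": MISSING, ".": MISSING}


def write_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as minimal VCF v4.2 with GT calls."""
    path = Path(path)
    contigs = list(dict.fromkeys(m.variants["chromosome"].astype(str)))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tsaorta\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.subjects)
            + "\n"
        )
        for j, row in m.variants.iterrows():
            calls = "\t".join(_GT_CODE[int(c)] for c in m.calls[:, j])
            fh.write(
                f"{row['chromosome']}\t{row['position']}\t{row['id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT calls from a VCF into a genotype matrix (cyvcf2 if present)."""
    path = str(path)
    try:
        return _read_vcf_cyvcf2(path)
    except ImportError:
        return _read_vcf_text(path)


def _read_vcf_cyvcf2(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = list(vcf.samples)
    rows, calls = [], []
    for var in vcf:
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chromosome": var.CHROM,
                "position": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        g = var.gt_types.astype(np.int8)  # 0=hom ref,1=het,2=unknown,3=hom alt
        col = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, MISSING)))
        calls.append(col.astype(np.int8))
    variants = pd.DataFrame(rows)
    mat = (
        np.stack(calls, axis=1) if calls else np.zeros((len(subjects), 0), np.int8)
    )
    return GenotypeMatrix(subjects, variants, mat)


def _read_vcf_text(path: str) -> GenotypeMatrix:
    subjects: list[str] = []
    rows, calls = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                subjects = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            col = [
                _CODE_GT.get(sample.split(":")[gt_i], MISSING)
                for sample in parts[9:]
            ]
            rows.append(
                {"id": vid if vid != "." else f"{chrom}:{pos}", "chromosome": chrom,
                 "position": pos, "ref": ref, "alt": alt}
            )
            calls.append(np.array(col, dtype=np.int8))
    variants = pd.DataFrame(rows)
    mat = (
        np.stack(calls, axis=1) if calls else np.zeros((len(subjects), 0), np.int8)
    )
    return GenotypeMatrix(subjects, variants, mat)


def read_read_counts_vcf(path: str | Path, sample: Optional[str] = None,
                         chromosome: Optional[str] = None) -> list[ReadCountSite]:
    """Extract per-site REF/ALT depths (AD field) for one sample from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    idx = samples.index(sample) if sample is not None else 0
    sites = []
    for var in vcf:
        if chromosome is not None and var.CHROM != chromosome:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        ref_c, alt_c = int(ad[idx][0]), int(ad[idx][1])
        sites.append(ReadCountSite(var.CHROM, var.POS, max(ref_c, 0), max(alt_c, 0)))
    sites.sort(key=lambda s: (s.chromosome, s.position))
    return sites


def write_read_counts_table(sites: Sequence[ReadCountSite], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["chromosome", "position", "ref_count", "alt_count"])
        for s in sites:
            w.writerow([s.chromosome, s.position, s.ref_count, s.alt_count])


def read_read_counts_table(path: str | Path) -> list[ReadCountSite]:
    df = pd.read_csv(path, sep="\t")
    required = {"chromosome", "position", "ref_count", "alt_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"read-count table needs columns {sorted(required)}")
    return [
        ReadCountSite(str(r.chromosome), int(r.position), int(r.ref_count),
                      int(r.alt_count))
        for r in df.itertuples()
    ]


_PHENO_COLUMNS = [
    "id", "bav", "coarctation", "lymphedema", "broad_chest", "webbed_neck",
    "poi", "hypertension", "dissection", "age_years", "height_cm", "weight_kg",
    "sbp", "dbp", "ar_cm", "aao_cm", "karyotype", "timp1_copies",
    "timp3_rs11547635_carrier",
]


def write_phenotype_table(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    """Phenotypes as TSV; booleans as 0/1, missing values as empty fields."""

    def cell(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return int(v)
        return v

    rows = []
    for s in subjects:
        rows.append(
            {
                **{c: cell(getattr(s, c)) for c in _PHENO_COLUMNS
                   if c not in ("ar_cm", "aao_cm")},
                "ar_cm": s.ar.actual_cm if s.ar else "",
                "aao_cm": s.aao.actual_cm if s.aao else "",
            }
        )
    pd.DataFrame(rows, columns=_PHENO_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path, mse_ar: float = 0.01,
                         mse_aao: float = 0.01) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "karyotype": str})
    missing_cols = set(_PHENO_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing_cols)}")

    def flag(v):
        return None if pd.isna(v) else bool(int(v))

    def num(v):
        return None if pd.isna(v) else float(v)

    subjects = []
    for r in df.itertuples():
        height, weight = num(r.height_cm), num(r.weight_kg)
        ar = aao = None
        if num(r.ar_cm) is not None and height and weight:
            from .aortic import haycock_bsa

            ar = AorticMeasure(Vessel.AR, float(r.ar_cm),
                               haycock_bsa(height, weight), mse_ar)
        if num(r.aao_cm) is not None and height and weight:
            from .aortic import haycock_bsa

            aao = AorticMeasure(Vessel.AAO, float(r.aao_cm),
                                haycock_bsa(height, weight), mse_aao)
        subjects.append(
            SubjectRecord(
                id=str(r.id),
                bav=flag(r.bav), coarctation=flag(r.coarctation),
                lymphedema=flag(r.lymphedema), broad_chest=flag(r.broad_chest),
                webbed_neck=flag(r.webbed_neck), poi=flag(r.poi),
                hypertension=flag(r.hypertension), dissection=flag(r.dissection),
                age_years=num(r.age_years), height_cm=height, weight_kg=weight,
                sbp=num(r.sbp), dbp=num(r.dbp), ar=ar, aao=aao,
                karyotype=None if pd.isna(r.karyotype) else str(r.karyotype),
                timp1_copies=num(r.timp1_copies),
                timp3_rs11547635_carrier=flag(r.timp3_rs11547635_carrier),
            )
        )
    return subjects
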