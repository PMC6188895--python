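"""Variant-level annotation filters and Xp candidate-gene ranking.

An Xp gene can plausibly contribute to aortopathy under haploinsufficiency
when it escapes X inactivation (at least variably), has no Y homologue or
pseudogene masking its dosage, and is actually expressed in the aortic wall.
Qualifying genes are ranked with known aortic-valve-development genes first
and then by descending aortic expression.  A curated annotation table for
the candidate Xp genes ships with the package; custom tables in the same
schema are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAnnotationResult",
    "load_xp_gene_annotations",
    "flag_deleterious",
    "case_control_allele_test",
    "rank_xp_candidates",
]

CADD_DELETERIOUS_THRESHOLD = 15.0

_ANNOTATION_COLUMNS = {
    "gene",
    "xci_status",
    "y_homolog_or_pseudogene",
    "aorta_expression_rpkm",
    "valve_development",
}


def load_xp_gene_annotations() -> pd.DataFrame:
    """Packaged annotation table for candidate Xp genes."""
    with resources.files("tsaorta.data").joinpath(
        "xp_gene_annotations.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def flag_deleterious(
    cadd_phred: Optional[float], threshold: float = CADD_DELETERIOUS_THRESHOLD
) -> bool:
    """Likely-deleterious call: CADD PHRED >= threshold (inclusive).

    A missing score is treated as not flaggable (returns False); callers log
    such variants rather than guessing.
    """
    if cadd_phred is None or (isinstance(cadd_phred, float) and np.isnan(cadd_phred)):
        return False
    if cadd_phred < 0:
        raise ValueError(f"CADD PHRED scores are non-negative, got {cadd_phred}")
    return cadd_phred >= threshold


@dataclass
class VariantAnnotationResult:
    variant: str
    case_alt_alleles: int
    case_total_alleles: int
    control_alt_alleles: int
    control_total_alleles: int
    chi2_p: float
    deleterious: Optional[bool] = None

    @property
    def case_frequency(self) -> float:
        return self.case_alt_alleles / self.case_total_alleles

    @property
    def control_frequency(self) -> float:
        return self.control_alt_alleles / self.control_total_alleles


def case_control_allele_test(
    genotypes: Sequence[int],
    status: Sequence[bool],
    variant: str = "",
    cadd_phred: Optional[float] = None,
) -> VariantAnnotationResult:
    """Allele-count case/control comparison for a single variant.

    Counts ALT alleles over 2N chromosomes per group (missing calls, coded
    negative, are dropped) and computes a Pearson chi-squared p on the 2x2
    allele table.  Monomorphic variants return p = 1.
    """
    g = np.asarray(genotypes, dtype=float)
    s = np.asarray(status, dtype=bool)
    if g.shape != s.shape:
        raise ValueError("genotypes and status must align")
    if not s.any() or s.all():
        raise ValueError("need at least one case and one control")
    ok = g >= 0
    case_alt = int(g[ok & s].sum())
    case_tot = int(2 * (ok & s).sum())
    ctrl_alt = int(g[ok & ~s].sum())
    ctrl_tot = int(2 * (ok & ~s).sum())
    table = np.array(
        [[case_alt, case_tot - case_alt], [ctrl_alt, ctrl_tot - ctrl_alt]]
    )
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p = 1.0
    else:
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return VariantAnnotationResult(
        variant, case_alt, case_tot, ctrl_alt, ctrl_tot, float(p),
        deleterious=flag_deleterious(cadd_phred) if cadd_phred is not None else None,
    )


def rank_xp_candidates(
    annotations: pd.DataFrame, require_escape: bool = False
) -> pd.DataFrame:
    """Rank Xp genes by their plausibility as aortopathy candidates.

    Excludes genes flagged as pseudogenes/Y-homologues or with zero aortic
    expression; the rest sort by (known valve-development role first, then
    aortic expression descending, then gene symbol for determinism) and get
    ranks 1..n.  ``require_escape`` additionally restricts to genes with
    Variable X-inactivation status.
    """
    if annotations.empty:
        raise ValueError("annotation table is empty")
    missing = _ANNOTATION_COLUMNS - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    df = annotations.copy()
    excluded = df["y_homolog_or_pseudogene"].astype(str).str.lower().isin(
        ("yes", "true", "1")
    ) | (df["aorta_expression_rpkm"] <= 0)
    if require_escape:
        excluded |= df["xci_status"] != "Variable"
    df = df.loc[~excluded].copy()
    df["_valve"] = (df["valve_development"].astype(str).str.lower() == "yes").astype(int)
    df = df.sort_values(
        by=["_valve", "aorta_expression_rpkm", "gene"],
        ascending=[False, False, True],
        kind="stable",
    ).drop(columns="_valve")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
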