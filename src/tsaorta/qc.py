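"""Variant and sample quality control for exome call sets.

The cleaning chain mirrors standard exome practice: drop variants with a low
genotyping rate, drop samples with excess missingness, exclude markers out of
Hardy-Weinberg equilibrium (exact test), then LD-prune common variants and
run a genotype PCA with iterative removal of population outliers.  Every
stage reports its removal count so the bookkeeping identity
``input - removed = retained`` can be audited end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PcaResult",
    "FilterReport",
    "filter_by_call_rate",
    "filter_by_sample_missingness",
    "hwe_exact_test",
    "filter_by_hwe",
    "ld_prune",
    "pca_with_outlier_removal",
    "qc_chain",
]

MISSING = -1  # sentinel in the int8 call matrix


@dataclass
class GenotypeMatrix:
    """Subjects x variants ALT-allele dosage matrix (0/1/2, -1 missing)."""

    subjects: list[str]
    variants: pd.DataFrame  # columns: id, chromosome, position, ref, alt, ...
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.subjects), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.variants)} variants"
            )
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        """Per-subject fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def allele_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency over observed calls."""
        observed = self.calls != MISSING
        alt = np.where(observed, self.calls, 0).sum(axis=0)
        denom = 2 * observed.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / denom, np.nan)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        col = self.calls[:, j]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def subset(self, subject_idx: Optional[np.ndarray] = None,
               variant_idx: Optional[np.ndarray] = None) -> "GenotypeMatrix":
        si = np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in si],
            variants=self.variants.iloc[vi].reset_index(drop=True),
            calls=self.calls[np.ix_(si, vi)],
        )


@dataclass
class FilterReport:
    stage: str
    n_input: int
    n_removed: int
    removed_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def filter_by_call_rate(
    m: GenotypeMatrix, min_rate: float = 0.99
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants whose genotyping rate falls below ``min_rate``."""
    if not 0 <= min_rate <= 1:
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    keep = m.call_rate() >= min_rate
    removed = m.variants.loc[~keep, "id"].tolist()
    report = FilterReport("call_rate", m.n_variants, int((~keep).sum()), removed)
    return m.subset(variant_idx=np.flatnonzero(keep)), report


def filter_by_sample_missingness(
    m: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove subjects with more than ``max_missing`` missing genotypes."""
    if not 0 <= max_missing <= 1:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    keep = m.sample_missingness() <= max_missing
    removed = [s for s, k in zip(m.subjects, keep) if not k]
    report = FilterReport("sample_missingness", m.n_subjects, len(removed), removed)
    return m.subset(subject_idx=np.flatnonzero(keep)), report


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, enumeration).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one — the
    standard exact formulation for biallelic markers.  Computed with the
    stable recurrence over heterozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible het counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    if het_max < het_min:
        return 1.0
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized probabilities via the recurrence
    # P(h+2)/P(h) = 4*nA(h)*nB(h) / ((h+2)*(h+1)) with nA, nB the hom counts
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = logp[i - 1] + np.log(4.0 * rare_hom * common_hom) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = int(n_het)
    p_obs = p[(hets == obs)][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def filter_by_hwe(
    m: GenotypeMatrix, alpha: float = 1e-6
) -> tuple[GenotypeMatrix, FilterReport]:
    """Exclude markers failing the exact HWE test at level ``alpha``."""
    keep = np.ones(m.n_variants, dtype=bool)
    for j in range(m.n_variants):
        counts = m.genotype_counts(j)
        if sum(counts) == 0:
            continue
        if hwe_exact_test(*counts) < alpha:
            keep[j] = False
    removed = m.variants.loc[~keep, "id"].tolist()
    report = FilterReport("hwe", m.n_variants, int((~keep).sum()), removed)
    return m.subset(variant_idx=np.flatnonzero(keep)), report


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns (missing dropped)."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_prune(
    m: GenotypeMatrix,
    r2_max: float = 0.2,
    window_bp: int = 50_000,
    step_variants: int = 5,
    maf_min: float = 0.05,
) -> list[str]:
    """Greedy windowed LD pruning; returns the retained variant ids.

    Only common variants (MAF > ``maf_min``) are considered.  Within each
    ``window_bp`` window ([start, start+window) on physical position) every
    pair with genotype-correlation r^2 > ``r2_max`` loses its later member
    (the lower-position variant is kept), then the window advances
    ``step_variants`` variants.
    """
    af = m.allele_frequency()
    maf = np.minimum(af, 1 - af)
    common = np.flatnonzero(maf > maf_min)
    kept = set()
    dropped = set()
    for chrom, grp in m.variants.iloc[common].groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["position"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        start = 0
        while start < len(idx):
            w_end = pos[start] + window_bp
            in_win = [k for k in range(start, len(idx)) if pos[k] < w_end]
            for ai in range(len(in_win)):
                i = idx[in_win[ai]]
                if i in dropped:
                    continue
                for bi in range(ai + 1, len(in_win)):
                    j = idx[in_win[bi]]
                    if j in dropped:
                        continue
                    if _pairwise_r2(m.calls[:, i], m.calls[:, j]) > r2_max:
                        dropped.add(j)
            start += step_variants
        kept.update(i for i in idx if i not in dropped)
    return m.variants.loc[sorted(kept), "id"].tolist()


@dataclass
class PcaResult:
    eigenvectors: pd.DataFrame  # index: subject ids, columns EV1..EVk
    kept_subjects: list[str]
    removal_history: list[list[str]]
    n_iterations: int


def _standardized(calls: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls, centre and scale by sqrt(2p(1-p))."""
    g = calls.astype(float)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    z = np.zeros_like(g)
    z[:, ok] = (g[:, ok] - mean[ok]) / scale[ok]
    return z


def _leading_eigenvectors(z: np.ndarray, k: int) -> np.ndarray:
    """Unit-norm subject-space eigenvectors with a fixed sign convention."""
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(k, u.shape[1])
    ev = u[:, :k]
    for c in range(k):
        pivot = np.argmax(np.abs(ev[:, c]))
        if ev[pivot, c] < 0:
            ev[:, c] = -ev[:, c]
    return ev


def pca_with_outlier_removal(
    m: GenotypeMatrix,
    ev1_cut: float = -0.3,
    ev2_cut: float = 0.3,
    n_components: int = 3,
    max_iter: int = 10,
) -> PcaResult:
    """Genotype PCA with iterative removal of population outliers.

    Each round standardizes genotype columns, extracts the leading subject
    eigenvectors (sign fixed so the largest-magnitude loading is positive)
    and removes subjects with EV1 < ``ev1_cut`` and EV2 > ``ev2_cut``; it
    stops when a round removes nobody or ``max_iter`` is reached.
    """
    current = m
    history: list[list[str]] = []
    ev = None
    for _ in range(max_iter):
        if current.n_subjects < 3:
            raise ValueError("fewer than 3 subjects remain during PCA outlier removal")
        z = _standardized(current.calls)
        ev = _leading_eigenvectors(z, max(n_components, 2))
        outlier = (ev[:, 0] < ev1_cut) & (ev[:, 1] > ev2_cut)
        if not outlier.any():
            break
        removed = [s for s, o in zip(current.subjects, outlier) if o]
        history.append(removed)
        current = current.subset(subject_idx=np.flatnonzero(~outlier))
    else:
        # max_iter exhausted; report the final projection as-is
        z = _standardized(current.calls)
        ev = _leading_eigenvectors(z, max(n_components, 2))
    cols = [f"EV{i + 1}" for i in range(ev.shape[1])]
    table = pd.DataFrame(ev[:, :n_components], index=current.subjects,
                         columns=cols[:n_components])
    return PcaResult(table, list(current.subjects), history, len(history) + 1)


def qc_chain(
    m: GenotypeMatrix,
    min_call_rate: float = 0.99,
    max_sample_missing: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, list[FilterReport]]:
    """Run the variant/sample filter chain and return the audit trail."""
    reports = []
    m, rep = filter_by_call_rate(m, min_call_rate)
    reports.append(rep)
    m, rep = filter_by_sample_missingness(m, max_sample_missing)
    reports.append(rep)
    m, rep = filter_by_hwe(m, hwe_alpha)
    reports.append(rep)
    return m, reports
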