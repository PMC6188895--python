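"""Gene-based variant-set association testing.

For each gene the variants it contains are tested jointly against a
dichotomous outcome (optionally with covariates) using an omnibus statistic
that interpolates between a variance-component kernel statistic and a
collapsing burden statistic,

    Q_rho = (1 - rho) * Q_SKAT + rho * Q_burden,
    Q_SKAT   = sum_j w_j^2 (g_j' r)^2,
    Q_burden = (sum_j w_j g_j' r)^2,

where ``r`` are residuals from the null model (logistic regression of the
outcome on the covariates) and ``w_j`` are variant weights, by default the
Beta(1, 25) density evaluated at the sample minor-allele frequency so that
rare variants are up-weighted.  The omnibus p-value is the minimum over a
rho grid of the per-rho p-values, calibrated by permuting the residual
vector jointly across the grid (a min-p permutation null), which keeps the
test exact at small sample sizes without distributional approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NullModel",
    "GeneTestResult",
    "SeparationError",
    "DEFAULT_RHO_GRID",
    "assign_variants_to_genes",
    "fit_null_model",
    "beta_maf_weights",
    "skat_o_test",
    "exome_wide_threshold",
    "qq_data",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class SeparationError(RuntimeError):
    """Null-model fit failed (perfect separation or constant outcome)."""


@dataclass
class NullModel:
    """Fitted null regression of the outcome on covariates only."""

    outcome: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    covariate_names: list[str]
    params: np.ndarray

    @property
    def n(self) -> int:
        return len(self.outcome)


def fit_null_model(
    outcome: Sequence[int],
    covariates: Optional[np.ndarray] = None,
    covariate_names: Optional[Sequence[str]] = None,
) -> NullModel:
    """Logistic regression of a binary outcome on covariates (plus intercept).

    Residuals are ``y - p_hat``; with no covariates this reduces to centring
    on the phenotype prevalence.  Degenerate outcomes and separated fits
    raise :class:`SeparationError` so the caller can skip the gene with a
    reason instead of reporting a spurious p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be a flat 0/1 vector")
    if y.min() == y.max():
        raise SeparationError("constant outcome: null model undefined")
    if covariates is None:
        x = np.ones((len(y), 1))
        names = ["const"]
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if np.isnan(cov).any():
            raise ValueError("covariates contain missing values")
        x = sm.add_constant(cov, has_constant="add")
        names = ["const"] + (
            list(covariate_names)
            if covariate_names is not None
            else [f"x{i + 1}" for i in range(cov.shape[1])]
        )
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise SeparationError(str(exc)) from exc
    p = np.asarray(fit.predict(x))
    if np.any(p < 1e-10) or np.any(p > 1 - 1e-10):
        raise SeparationError("fitted probabilities at the boundary (separation)")
    return NullModel(y, p, y - p, names, np.asarray(fit.params))


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density at the MAF — the conventional rare-variant weight."""
    maf = np.clip(np.asarray(maf, dtype=float), 1e-8, 1 - 1e-8)
    return stats.beta.pdf(maf, a, b)


@dataclass
class GeneTestResult:
    gene: str
    n_variants: int
    p_value: float
    rho_selected: float
    method: str = "permutation"
    note: str = ""


def _q_statistics(
    scores: np.ndarray, weights: np.ndarray, rho_grid: np.ndarray
) -> np.ndarray:
    """Q_rho for each rho given per-variant score components g_j' r.

    ``scores`` may be (m,) for the observed data or (B, m) for permutations;
    returns matching (len(grid),) or (B, len(grid)).
    """
    s = np.atleast_2d(scores)
    q_skat = (weights**2 * s**2).sum(axis=1)
    q_burden = (s @ weights) ** 2
    q = np.outer(1.0 - rho_grid, q_skat).T + np.outer(rho_grid, q_burden).T
    return q[0] if scores.ndim == 1 else q


def skat_o_test(
    genotypes: np.ndarray,
    null: NullModel,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    weights: Optional[np.ndarray] = None,
    n_perm: int = 999,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    gene: str = "",
) -> GeneTestResult:
    """Omnibus kernel/burden association test for one gene.

    ``genotypes`` is the subjects x variants dosage matrix for the gene
    (missing calls as -1 are imputed to twice the sample allele frequency).
    The per-rho p-values and the omnibus minimum are all calibrated on the
    same ``n_perm`` permutations of the null residuals, giving
    ``p >= 1/(n_perm + 1)`` by construction.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] != null.n:
        raise ValueError("genotype rows do not match null-model subjects")
    missing = g < 0
    if missing.any():
        observed = ~missing
        af = np.where(
            observed.sum(axis=0) > 0,
            np.where(observed, g, 0).sum(axis=0) / np.maximum(observed.sum(axis=0), 1) / 2.0,
            0.0,
        )
        g = np.where(missing, 2.0 * af, g)

    af = g.mean(axis=0) / 2.0
    polymorphic = g.std(axis=0) > 0
    m = g.shape[1]
    if not polymorphic.any():
        return GeneTestResult(gene, m, 1.0, float("nan"), note="monomorphic gene")

    if weights is None:
        maf = np.minimum(af, 1 - af)
        w = beta_maf_weights(maf)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,):
            raise ValueError("weights must align with variants")
    grid = np.asarray(rho_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("rho grid values must lie in [0, 1]")

    r = null.residuals
    obs_scores = g.T @ r  # (m,)
    q_obs = _q_statistics(obs_scores, w, grid)  # (n_rho,)

    generator = rng if rng is not None else np.random.default_rng(seed)
    perm_idx = np.array(
        [generator.permutation(null.n) for _ in range(n_perm)]
    )
    perm_scores = r[perm_idx] @ g  # (B, m)
    q_perm = _q_statistics(perm_scores, w, grid)  # (B, n_rho)

    # per-rho permutation p-values for the observation and for each permutation
    ge_obs = (q_perm >= q_obs[None, :] - 1e-12).sum(axis=0)
    p_obs = (1.0 + ge_obs) / (n_perm + 1.0)
    # rank each permutation's Q within the permutation set (including itself):
    # count of permutations with Q >= own Q, per rho column
    ge_counts = n_perm - (stats.rankdata(q_perm, axis=0, method="min") - 1)
    p_perm = ge_counts / float(n_perm)

    min_p_obs = p_obs.min()
    rho_sel = float(grid[int(p_obs.argmin())])
    min_p_perm = p_perm.min(axis=1)
    p_final = (1.0 + (min_p_perm <= min_p_obs + 1e-12).sum()) / (n_perm + 1.0)
    return GeneTestResult(gene, m, float(p_final), rho_sel)


def assign_variants_to_genes(
    variants: pd.DataFrame, gene_intervals: pd.DataFrame
) -> tuple[dict[str, list[str]], list[str]]:
    """Map variants into every gene interval that overlaps them.

    ``variants`` needs columns id/chromosome/position; ``gene_intervals``
    needs gene/chromosome/start/end (1-based inclusive).  A variant may land
    in several overlapping genes.  Returns (gene -> variant ids, unassigned
    variant ids).
    """
    by_gene: dict[str, list[str]] = {}
    assigned = set()
    for _, row in gene_intervals.iterrows():
        mask = (
            (variants["chromosome"].astype(str) == str(row["chromosome"]))
            & (variants["position"] >= row["start"])
            & (variants["position"] <= row["end"])
        )
        ids = variants.loc[mask, "id"].tolist()
        if ids:
            by_gene[str(row["gene"])] = ids
            assigned.update(ids)
    unassigned = [v for v in variants["id"] if v not in assigned]
    return by_gene, unassigned


def exome_wide_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni exome-wide significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    return alpha / n_genes


def qq_data(p_values: Sequence[float]) -> pd.DataFrame:
    """Expected-vs-observed quantile pairs for a Q-Q plot.

    Observed p-values sorted ascending against (i - 0.5)/n; the -log10
    transform columns are included for direct plotting.
    """
    p = np.asarray(sorted(p_values), dtype=float)
    if p.size and (p.min() <= 0 or p.max() > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n if n else np.array([])
    return pd.DataFrame(
        {
            "expected": expected,
            "observed": p,
            "neglog10_expected": -np.log10(expected) if n else expected,
            "neglog10_observed": -np.log10(p) if n else p,
        }
    )
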