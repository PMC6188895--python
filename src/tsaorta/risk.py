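"""Contingency-table statistics and TIMP1 x TIMP3 combinatorial risk models.

All 2x2 tables are oriented (exposed-affected, exposed-unaffected,
unexposed-affected, unexposed-unaffected), so an odds ratio above 1 means the
exposure is enriched among the affected.  Point estimates use the
cross-product ratio with a Woolf (log-scale) confidence interval; zero cells
get the Haldane-Anscombe 0.5 correction with a flag.  Association p-values
follow the classical decision rule: chi-squared with Yates continuity
correction when every expected cell count is at least 5, otherwise Fisher's
exact test.  A logistic model with a single binary predictor reproduces the
cross-product odds ratio and is used for the four-group combinatorial
analysis of TIMP1 copy number and the TIMP3 rs11547635 variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aortic import SubjectRecord, classify_aortopathy

__all__ = [
    "ContingencyTable",
    "OddsRatioResult",
    "ComboGroup",
    "odds_ratio",
    "association_test",
    "two_sample_t",
    "logistic_or",
    "combinatorial_analysis",
    "attribute_profile",
    "reconstruct_total",
]

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Oriented 2x2 counts: a,b = exposed +/-, c,d = unexposed +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped(self) -> "ContingencyTable":
        """Exposure orientation inverted (unexposed become exposed)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class OddsRatioResult:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: Optional[float] = None
    test_used: Optional[str] = None
    corrected: bool = False
    undefined: bool = False


def odds_ratio(t: ContingencyTable, apply_haldane: bool = True) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf 95% confidence interval.

    With any zero cell the raw ratio is inestimable; 0.5 is added to every
    cell (Haldane-Anscombe) and the result flagged ``corrected``.  A zero
    diagonal (both a,d or both b,c zero) is reported as undefined even after
    correction, mirroring how such rows are printed as '-'.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return OddsRatioResult(float("nan"), float("nan"), float("nan"),
                               corrected=False, undefined=True)
    corrected = False
    if min(a, b, c, d) == 0:
        if not apply_haldane:
            return OddsRatioResult(float("nan"), float("nan"), float("nan"),
                                   undefined=True)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(point)
    return OddsRatioResult(
        point,
        math.exp(log_or - Z_95 * se),
        math.exp(log_or + Z_95 * se),
        corrected=corrected,
    )


def _expected_counts(t: ContingencyTable) -> np.ndarray:
    arr = t.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def association_test(t: ContingencyTable) -> tuple[float, str]:
    """(p-value, test name) using the expected-cell-count rule.

    Chi-squared with Yates correction when all four expected counts are
    >= 5, else two-sided Fisher exact.
    """
    if t.total == 0:
        raise ValueError("empty contingency table")
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        # degenerate margin: no association measurable
        return 1.0, "fisher"
    if (_expected_counts(t) >= 5).all():
        _, p, _, _ = stats.chi2_contingency(arr, correction=True)
        return float(p), "chi2_yates"
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p), "fisher"


def two_sample_t(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Pooled-variance two-sided t-test; returns (p, mean difference)."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if np.concatenate([x, y]).std() == 0:
        raise ValueError("zero variance in both groups: t undefined")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue), float(x.mean() - y.mean())


def logistic_or(
    predictor: Sequence[bool], outcome: Sequence[bool]
) -> OddsRatioResult:
    """Odds ratio from a single-binary-predictor logistic regression.

    exp(slope) with a Wald 95% interval; equals the cross-product estimate on
    the corresponding 2x2 up to solver tolerance.  Separation (a zero cell)
    is reported as undefined rather than a runaway estimate.
    """
    import statsmodels.api as sm

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.min() == x.max():
        raise ValueError("predictor must have both levels present")
    t = ContingencyTable(
        int(((x == 1) & (y == 1)).sum()),
        int(((x == 1) & (y == 0)).sum()),
        int(((x == 0) & (y == 1)).sum()),
        int(((x == 0) & (y == 0)).sum()),
    )
    if min(t.a, t.b, t.c, t.d) == 0:
        return OddsRatioResult(float("nan"), float("nan"), float("nan"),
                               test_used="logistic", undefined=True)
    design = sm.add_constant(x)
    fit = sm.Logit(y, design).fit(disp=0)
    slope = fit.params[1]
    se = fit.bse[1]
    p = fit.pvalues[1]
    return OddsRatioResult(
        math.exp(slope),
        math.exp(slope - Z_95 * se),
        math.exp(slope + Z_95 * se),
        p_value=float(p),
        test_used="logistic",
    )


def reconstruct_total(n_affected: int, percent_affected: float) -> int:
    """Group size implied by an affected count and a printed percentage."""
    if not 0 < percent_affected <= 100:
        raise ValueError("percent must be in (0, 100]")
    return round(n_affected / (percent_affected / 100.0))


@dataclass
class ComboGroup:
    label: str
    n: int
    n_affected: int
    odds_ratio: Optional[OddsRatioResult] = None

    @property
    def percent_affected(self) -> float:
        return 100.0 * self.n_affected / self.n if self.n else float("nan")


COMBO_LABELS = (
    "no-SNP/>1 copy",
    "no-SNP/1 copy",
    "SNP/>1 copy",
    "SNP/1 copy",
)


def combinatorial_analysis(
    subjects: Sequence[SubjectRecord],
    outcome: str = "bav",
    copy_threshold: float = 1.1,
    min_group_n: int = 5,
) -> list[ComboGroup]:
    """Four-group TIMP1 copy x TIMP3 carrier analysis against a reference.

    Groups cross rs11547635 carriage with the 1-copy/>1-copy TIMP1 split;
    the no-SNP/>1-copy group is the reference and every other group gets an
    odds ratio against it.  ``outcome`` is ``"bav"`` or ``"bav_with_tad"``;
    for the latter, subjects without any aortic measurement are excluded.
    Groups smaller than ``min_group_n`` (or with a zero diagonal) are left
    without an estimate, as printed tables flag with '-'.
    """
    if outcome not in ("bav", "bav_with_tad"):
        raise ValueError(f"unknown outcome {outcome!r}")
    members: dict[str, list[bool]] = {lbl: [] for lbl in COMBO_LABELS}
    for s in subjects:
        if s.timp1_copies is None or s.timp3_rs11547635_carrier is None or s.bav is None:
            continue
        flags = classify_aortopathy(s)
        if outcome == "bav_with_tad":
            if flags["bav_with_tad"] is None:
                continue
            affected = bool(flags["bav_with_tad"])
        else:
            affected = bool(s.bav)
        one_copy = s.timp1_copies <= copy_threshold
        snp = bool(s.timp3_rs11547635_carrier)
        label = f"{'SNP' if snp else 'no-SNP'}/{'1 copy' if one_copy else '>1 copy'}"
        members[label].append(affected)

    ref = members["no-SNP/>1 copy"]
    if not ref:
        raise ValueError("reference group (no-SNP/>1 copy) is empty; analysis aborted")
    ref_aff, ref_n = sum(ref), len(ref)
    groups = []
    for label in COMBO_LABELS:
        vals = members[label]
        grp = ComboGroup(label, len(vals), sum(vals))
        if label != "no-SNP/>1 copy" and grp.n >= min_group_n:
            table = ContingencyTable(
                grp.n_affected, grp.n - grp.n_affected, ref_aff, ref_n - ref_aff
            )
            if not ((table.a == 0 and table.d == 0) or (table.b == 0 and table.c == 0)):
                result = odds_ratio(table)
                result.p_value, result.test_used = association_test(table)
                grp.odds_ratio = result
        groups.append(grp)
    return groups


_CONTINUOUS_ATTRS = (
    ("height_cm", "Height (cm)"),
    ("weight_kg", "Weight (kg)"),
    ("bsa_m2", "BSA (m2)"),
    ("sbp", "BP, systolic"),
    ("dbp", "BP, diastolic"),
)
_CATEGORICAL_ATTRS = (
    ("lymphedema", "Lymphedema"),
    ("broad_chest", "Broad chest"),
    ("webbed_neck", "Webbed neck"),
    ("poi", "POI"),
    ("hypertension", "Hypertension"),
    ("dissection", "Any Dissection"),
    ("coarctation", "Coarctation"),
    ("bav", "BAV"),
    ("tad", "TAD"),
    ("bav_with_tad", "BAV with TAD"),
    ("any_aortic_risk", "Any aortic risk factor"),
)


def _stratifier_value(s: SubjectRecord, stratifier: str, copy_threshold: float):
    if stratifier == "rs11547635":
        return s.timp3_rs11547635_carrier
    if stratifier == "timp1":
        if s.timp1_copies is None:
            return None
        return s.timp1_copies <= copy_threshold
    raise ValueError(f"unknown stratifier {stratifier!r}")


def attribute_profile(
    subjects: Sequence[SubjectRecord],
    stratifier: str = "rs11547635",
    copy_threshold: float = 1.1,
    poi_min_age: float = 13.0,
) -> pd.DataFrame:
    """Per-phenotype comparison across a binary genotype stratifier.

    ``stratifier`` is ``"rs11547635"`` (carrier vs non-carrier) or ``"timp1"``
    (1 copy vs >1 copy).  Continuous attributes get a pooled-variance t-test;
    categorical ones a 2x2 odds ratio with the chi-squared/Fisher decision
    rule.  Each row carries its own N (subjects with the attribute observed);
    primary ovarian insufficiency excludes subjects younger than
    ``poi_min_age``, and TAD-dependent rows are restricted to subjects with
    at least one aortic measurement.
    """
    strat = {
        s.id: _stratifier_value(s, stratifier, copy_threshold) for s in subjects
    }
    rows = []
    for attr, label in _CONTINUOUS_ATTRS:
        g1, g2 = [], []
        for s in subjects:
            if strat[s.id] is None:
                continue
            val = getattr(s, attr)
            if val is None:
                continue
            (g1 if strat[s.id] else g2).append(val)
        if len(g1) < 2 or len(g2) < 2:
            continue
        try:
            p, diff = two_sample_t(g1, g2)
        except ValueError:  # degenerate (zero-variance) attribute
            continue
        rows.append(
            {
                "attribute": label, "kind": "continuous", "n": len(g1) + len(g2),
                "mean_exposed": float(np.mean(g1)), "mean_unexposed": float(np.mean(g2)),
                "mean_difference": diff, "odds_ratio": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p_value": p, "test_used": "t_equal_var",
            }
        )
    for attr, label in _CATEGORICAL_ATTRS:
        counts = [0, 0, 0, 0]  # a, b, c, d
        for s in subjects:
            if strat[s.id] is None:
                continue
            if attr == "poi" and (s.age_years is None or s.age_years < poi_min_age):
                continue
            if attr in ("tad", "bav_with_tad"):
                flags = classify_aortopathy(s)
                val = flags[attr]
            elif attr == "any_aortic_risk":
                val = classify_aortopathy(s)["any_aortic_risk"]
            else:
                val = getattr(s, attr)
            if val is None:
                continue
            i = (0 if val else 1) if strat[s.id] else (2 if val else 3)
            counts[i] += 1
        t = ContingencyTable(*counts)
        if t.total == 0:
            continue
        orr = odds_ratio(t)
        p, test = association_test(t)
        rows.append(
            {
                "attribute": label, "kind": "categorical", "n": t.total,
                "mean_exposed": np.nan, "mean_unexposed": np.nan,
                "mean_difference": np.nan, "odds_ratio": orr.or_point,
                "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                "p_value": p, "test_used": test,
            }
        )
    return pd.DataFrame(rows)
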