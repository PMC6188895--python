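"""Synthetic Turner-syndrome cohort generator.

Registry exomes are access-controlled, so every downstream stage of the
pipeline is exercised on simulated cohorts carrying the statistical structure
the analysis assumes:

* karyotypes drawn from the clinical spectrum of a published 188-subject
  cohort, parsed to TIMP1 copy number and a true 45,X cell fraction;
* X-chromosome read counts whose allele balance shows the three-band
  structure of 45,X/46,XX mosaicism — at a heterozygous site with 45,X cell
  fraction ``f`` the ALT-read fraction is ``1/(2-f)`` or ``(1-f)/(2-f)``
  depending on which haplotype carries ALT — plus pseudoautosomal
  heterozygosity and Y reads for XY-bearing lines;
* TIMP3 genotypes drawn under Hardy-Weinberg at published control allele
  frequencies;
* BAV risk from a logistic model combining TIMP1 hemizygosity, rs11547635
  carriage and their interaction, and aortic z-scores shifted in BAV so that
  diameters back-computed by inverting the z-score equation reproduce the
  latent z exactly when re-scored.

All randomness flows from one seed through named substreams, so any stage
can be regenerated independently and identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import aortic
from .aortic import AorticMeasure, SubjectRecord, Vessel
from .datasets import TIMP3_VARIANT_PANEL, cohort_karyotype_spectrum
from .karyotype import (
    PAR1_HG19,
    KaryotypeSpec,
    ReadCountSite,
    locus_copy_number,
    parse_iscn,
)
from .qc import GenotypeMatrix

import pandas as pd

__all__ = [
    "EffectConfig",
    "SyntheticTruth",
    "sample_karyotypes",
    "simulate_x_read_counts",
    "simulate_y_read_counts",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
]

_X_LENGTH = 155_270_560


@dataclass
class EffectConfig:
    """Generative parameters; defaults are the published cohort conditions.

    The odds ratios parameterize BAV risk on the logit scale relative to the
    no-variant, >1-TIMP1-copy reference group (prevalence 6/33).  The default
    trio (3.97, 4.50, 1.0) reproduces the four published combinatorial group
    prevalences.  Aortic z-scores are Normal with a BAV-dependent shift
    (0.98 root / 1.44 ascending) and group SDs as published; heights and
    weights are truncated Normals matching the cohort means.
    """

    baseline_bav_prevalence: float = 6 / 33
    or_timp1_single_copy: float = 3.97
    or_timp3_carrier: float = 4.50
    or_interaction: float = 1.0
    base_z_ar: float = 0.31
    base_z_aao: float = 0.61
    bav_z_shift_ar: float = 0.98
    bav_z_shift_aao: float = 1.44
    z_sd_ar: float = 1.08
    z_sd_aao: float = 1.18
    z_sd_ar_bav: float = 1.59
    z_sd_aao_bav: float = 1.99
    mse_ar: float = aortic.DEFAULT_MSE
    mse_aao: float = aortic.DEFAULT_MSE
    mean_depth: float = 71.0
    n_x_sites: int = 300
    depth_overdispersion: Optional[float] = None  # NB size parameter; None = Poisson
    site_class_probs: tuple[float, float, float] = (0.45, 0.30, 0.25)
    height_mean_cm: float = 142.6
    height_sd_cm: float = 15.6
    weight_mean_kg: float = 55.8
    weight_sd_kg: float = 20.1
    p_ar_measured: float = 113 / 188
    p_aao_measured: float = 106 / 188
    copy_threshold: float = 1.1
    karyotype_spectrum: list[tuple[str, float]] = field(
        default_factory=cohort_karyotype_spectrum
    )

    def __post_init__(self) -> None:
        if not 0 < self.baseline_bav_prevalence < 1:
            raise ValueError("baseline prevalence must be in (0, 1)")
        for name in ("or_timp1_single_copy", "or_timp3_carrier", "or_interaction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_depth < 1:
            raise ValueError("mean depth must be >= 1")
        if abs(sum(p for _, p in self.karyotype_spectrum) - 1.0) > 1e-9:
            raise ValueError("karyotype spectrum fractions must sum to 1")
        if abs(sum(self.site_class_probs) - 1.0) > 1e-9:
            raise ValueError("site class probabilities must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth stored beside simulated outputs; never fed to inference."""

    subject_ids: list[str]
    fraction_45X: np.ndarray
    timp1_copies: np.ndarray
    timp3_carrier: np.ndarray
    bav_probability: np.ndarray
    latent_z_ar: np.ndarray
    latent_z_aao: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.subject_ids,
                "fraction_45X": self.fraction_45X,
                "timp1_copies": self.timp1_copies,
                "timp3_carrier": self.timp3_carrier.astype(int),
                "bav_probability": self.bav_probability,
                "latent_z_ar": self.latent_z_ar,
                "latent_z_aao": self.latent_z_aao,
            }
        )


def _rng(seed: int, *stream: str | int) -> np.random.Generator:
    """Named substream of the global seed (stage names keyed into the seed)."""
    return np.random.default_rng([seed, *map(_key, stream)])


def _key(s: str | int) -> int:
    if isinstance(s, int):
        return s
    return int.from_bytes(s.encode()[:8].ljust(8, b"\0"), "little")


def sample_karyotypes(
    n: int,
    spectrum: Optional[Sequence[tuple[str, float]]] = None,
    seed: int = 0,
) -> list[KaryotypeSpec]:
    """Multinomial draw of parsed karyotypes from an (ISCN, fraction) spectrum."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spectrum = list(spectrum) if spectrum is not None else cohort_karyotype_spectrum()
    fractions = np.array([f for _, f in spectrum], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"spectrum fractions sum to {fractions.sum()}, not 1")
    rng = _rng(seed, "karyotypes")
    idx = rng.choice(len(spectrum), size=n, p=fractions)
    return [parse_iscn(spectrum[i][0]) for i in idx]


def true_45x_fraction(kspec: KaryotypeSpec) -> float:
    """Fraction of cells carrying no second sex chromosome at all.

    A cell line counts as 45,X when it has exactly one intact X, no Y, and no
    structural second-X chromosome (markers and autosomal additions do not
    count as sex-chromosome material).
    """
    frac = 0.0
    for cl in kspec.cell_lines:
        second = (
            cl.n_intact_x >= 2
            or cl.y_present
            or any(
                not t.startswith("add(") and t not in ("+mar", "mar")
                for t in cl.structural_terms
            )
        )
        if not second:
            frac += cl.fraction
    return min(1.0, frac)


def _draw_depths(rng: np.random.Generator, n: int, cfg_mean: float,
                 overdispersion: Optional[float]) -> np.ndarray:
    if overdispersion is None:
        return rng.poisson(cfg_mean, size=n)
    # negative binomial with mean cfg_mean and size (dispersion) parameter
    size = overdispersion
    p = size / (size + cfg_mean)
    return rng.negative_binomial(size, p, size=n)


def simulate_x_read_counts(
    kspec: KaryotypeSpec,
    n_sites: int = 300,
    mean_depth: float = 71.0,
    seed: int = 0,
    site_class_probs: tuple[float, float, float] = (0.45, 0.30, 0.25),
    overdispersion: Optional[float] = None,
) -> list[ReadCountSite]:
    """Simulate X-chromosome REF/ALT read counts for one karyotype.

    Each site draws a class (hom-REF / heterozygous-on-the-two-haplotypes /
    hom-ALT); the het-site ALT allele sits on the always-retained X with
    probability 0.5 (phase is random per site).  Expected ALT fraction at a
    site is the ALT-bearing copy mass over the total X copy mass across cell
    lines, which for a 45,X fraction f reduces to 1/(2-f) (retained) or
    (1-f)/(2-f) (non-retained).  In the pseudoautosomal region Y-bearing
    lines contribute an extra copy, so XY material is heterozygous only
    there.  Total depth is Poisson(mean_depth) (negative binomial when
    ``overdispersion`` is set); ALT reads are Binomial(depth, q).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = _rng(seed, "x_reads")
    positions = np.sort(
        rng.choice(_X_LENGTH - PAR1_HG19[0], size=n_sites, replace=False)
        + PAR1_HG19[0]
    )
    classes = rng.choice(3, size=n_sites, p=list(site_class_probs))
    on_retained = rng.random(n_sites) < 0.5
    depths = _draw_depths(rng, n_sites, mean_depth, overdispersion)
    sites = []
    for pos, cls, retained, depth in zip(positions, classes, on_retained, depths):
        locus = (int(pos), int(pos))
        total_mass = 0.0
        second_mass = 0.0  # copy mass beyond the retained X
        for cl in kspec.cell_lines:
            copies = cl.x_locus_copies(locus)
            if cl.y_present and PAR1_HG19[0] <= pos <= PAR1_HG19[1]:
                copies += 1
            copies = max(copies, 1)  # the retained X is always present
            total_mass += cl.fraction * copies
            second_mass += cl.fraction * (copies - 1)
        if cls == 0:
            q = 0.0
        elif cls == 2:
            q = 1.0
        else:
            if second_mass <= 0:
                # no second copy anywhere: the site is effectively homozygous
                q = 1.0 if retained else 0.0
            else:
                q = (
                    (total_mass - second_mass) / total_mass
                    if retained
                    else second_mass / total_mass
                )
        alt = rng.binomial(depth, q) if depth > 0 else 0
        sites.append(
            ReadCountSite("X", int(pos), int(depth) - int(alt), int(alt))
        )
    return sites


def simulate_y_read_counts(
    kspec: KaryotypeSpec,
    n_sites: int = 50,
    mean_depth: float = 71.0,
    seed: int = 0,
) -> list[ReadCountSite]:
    """Y-target read counts: depth scales with the Y-bearing cell fraction."""
    rng = _rng(seed, "y_reads")
    y_frac = sum(cl.fraction for cl in kspec.cell_lines if cl.y_present)
    positions = np.sort(
        rng.choice(55_000_000, size=n_sites, replace=False) + 2_700_000
    )
    depths = rng.poisson(mean_depth * y_frac, size=n_sites)
    out = []
    for pos, depth in zip(positions, depths):
        alt = rng.binomial(depth, 0.05) if depth > 0 else 0  # stray ALT noise
        out.append(ReadCountSite("Y", int(pos), int(depth) - int(alt), int(alt)))
    return out


def simulate_genotypes(
    n: int,
    variant_panel: Optional[Sequence[tuple]] = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotype draws for a variant panel.

    The default panel is the four TIMP3 coding variants at their published
    control allele frequencies.  Panel rows are (id, chromosome, position,
    ref, alt, allele_frequency[, cadd]).
    """
    panel = list(variant_panel) if variant_panel is not None else [
        (v[0], v[1], v[2], v[3], v[4], v[5]) for v in TIMP3_VARIANT_PANEL
    ]
    ids = [row[0] for row in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant ids in panel")
    afs = np.array([row[5] for row in panel], dtype=float)
    if np.any((afs < 0) | (afs > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    rng = _rng(seed, "genotypes")
    calls = rng.binomial(1, afs[None, :], size=(n, len(panel))) + rng.binomial(
        1, afs[None, :], size=(n, len(panel))
    )
    variants = pd.DataFrame(
        {
            "id": ids,
            "chromosome": [str(row[1]) for row in panel],
            "position": [int(row[2]) for row in panel],
            "ref": [row[3] for row in panel],
            "alt": [row[4] for row in panel],
            "allele_frequency": afs,
        }
    )
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(subjects, variants, calls.astype(np.int8))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_phenotypes(
    copies: Sequence[float],
    carriers: Sequence[bool],
    cfg: Optional[EffectConfig] = None,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> tuple[list[SubjectRecord], SyntheticTruth]:
    """Draw BAV status, morphometrics and aortic measures per subject.

    BAV ~ Bernoulli(p) with logit(p) = logit(baseline) + log(OR_timp1) *
    [1 copy] + log(OR_timp3) * [carrier] + log(OR_interaction) * [both].
    Latent z-scores are Normal with the BAV shift; diameters are the exact
    inverse of the z-score equation, so re-scoring returns the latent z.
    """
    cfg = cfg or EffectConfig()
    copies = np.asarray(copies, dtype=float)
    carr = np.asarray(carriers, dtype=bool)
    if copies.shape != carr.shape:
        raise ValueError("copies and carriers must have equal length")
    n = len(copies)
    subject_ids = list(ids) if ids is not None else [f"S{i + 1:04d}" for i in range(n)]
    rng = _rng(seed, "phenotypes")

    one_copy = copies <= cfg.copy_threshold
    logit = (
        math.log(cfg.baseline_bav_prevalence / (1 - cfg.baseline_bav_prevalence))
        + np.log(cfg.or_timp1_single_copy) * one_copy
        + np.log(cfg.or_timp3_carrier) * carr
        + np.log(cfg.or_interaction) * (one_copy & carr)
    )
    p_bav = 1.0 / (1.0 + np.exp(-logit))
    bav = rng.random(n) < p_bav

    z_ar = rng.normal(
        cfg.base_z_ar + cfg.bav_z_shift_ar * bav,
        np.where(bav, cfg.z_sd_ar_bav, cfg.z_sd_ar),
    )
    z_aao = rng.normal(
        cfg.base_z_aao + cfg.bav_z_shift_aao * bav,
        np.where(bav, cfg.z_sd_aao_bav, cfg.z_sd_aao),
    )
    heights = _truncated_normal(rng, cfg.height_mean_cm, cfg.height_sd_cm, 80, 200, n)
    weights = _truncated_normal(rng, cfg.weight_mean_kg, cfg.weight_sd_kg, 15, 180, n)
    ages = _truncated_normal(rng, 30.0, 15.0, 2, 80, n)
    ar_measured = rng.random(n) < cfg.p_ar_measured
    aao_measured = rng.random(n) < cfg.p_aao_measured
    sbp = rng.normal(116, 16, size=n)
    dbp = rng.normal(70, 11, size=n)

    # ancillary phenotypes at cohort marginal prevalences, independent of
    # genotype (null effects) unless the risk model above drives them
    marginals = {
        "lymphedema": 44 / 188,
        "broad_chest": 58 / 188,
        "webbed_neck": 85 / 188,
        "poi": 90 / 154,
        "hypertension": 71 / 178,
        "dissection": 6 / 188,
        "coarctation": 45 / 188,
    }
    extra = {k: rng.random(n) < p for k, p in marginals.items()}

    records = []
    for i in range(n):
        ar = aao = None
        if ar_measured[i]:
            expected = aortic.expected_dimension(
                aortic.haycock_bsa(heights[i], weights[i]), Vessel.AR
            )
            actual = aortic.invert_z(z_ar[i], expected, cfg.mse_ar)
            if actual > 0:
                ar = AorticMeasure(Vessel.AR, actual,
                                   aortic.haycock_bsa(heights[i], weights[i]),
                                   cfg.mse_ar)
        if aao_measured[i]:
            expected = aortic.expected_dimension(
                aortic.haycock_bsa(heights[i], weights[i]), Vessel.AAO
            )
            actual = aortic.invert_z(z_aao[i], expected, cfg.mse_aao)
            if actual > 0:
                aao = AorticMeasure(Vessel.AAO, actual,
                                    aortic.haycock_bsa(heights[i], weights[i]),
                                    cfg.mse_aao)
        records.append(
            SubjectRecord(
                id=subject_ids[i],
                bav=bool(bav[i]),
                coarctation=bool(extra["coarctation"][i]),
                lymphedema=bool(extra["lymphedema"][i]),
                broad_chest=bool(extra["broad_chest"][i]),
                webbed_neck=bool(extra["webbed_neck"][i]),
                poi=bool(extra["poi"][i]),
                hypertension=bool(extra["hypertension"][i]),
                dissection=bool(extra["dissection"][i]),
                age_years=float(ages[i]),
                height_cm=float(heights[i]),
                weight_kg=float(weights[i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                ar=ar,
                aao=aao,
                timp1_copies=float(copies[i]),
                timp3_rs11547635_carrier=bool(carr[i]),
            )
        )
    truth = SyntheticTruth(
        subject_ids=subject_ids,
        fraction_45X=np.full(n, np.nan),
        timp1_copies=copies.copy(),
        timp3_carrier=carr.copy(),
        bav_probability=p_bav,
        latent_z_ar=z_ar,
        latent_z_aao=z_aao,
    )
    return records, truth


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    karyotypes: list[KaryotypeSpec]
    genotypes: GenotypeMatrix
    truth: SyntheticTruth


def simulate_cohort(
    n: int = 188, cfg: Optional[EffectConfig] = None, seed: int = 0
) -> SyntheticCohort:
    """Full cohort: karyotypes -> copy number -> genotypes -> phenotypes."""
    cfg = cfg or EffectConfig()
    kspecs = sample_karyotypes(n, cfg.karyotype_spectrum, seed=seed)
    copies = [locus_copy_number(k) for k in kspecs]
    genos = simulate_genotypes(n, seed=seed)
    rs_idx = genos.variants.index[genos.variants["id"] == "rs11547635"]
    carriers = (
        genos.calls[:, rs_idx[0]] > 0
        if len(rs_idx)
        else np.zeros(n, dtype=bool)
    )
    subjects, truth = simulate_phenotypes(
        copies, carriers, cfg, seed=seed, ids=genos.subjects
    )
    truth.fraction_45X = np.array([true_45x_fraction(k) for k in kspecs])
    for s, k in zip(subjects, kspecs):
        s.karyotype = k.iscn
    return SyntheticCohort(subjects, kspecs, genos, truth)
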