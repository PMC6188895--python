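"""Second-sex-chromosome status, 45,X mosaicism and locus copy number.

In Turner syndrome the second sex chromosome may be absent (45,X), present
(46,XX), structurally abnormal (isochromosome Xq, ring X, Xp/Xq deletions), or
mosaic.  Exome allele balance reveals which: on a single X every variant is
homozygous (alternate-allele frequency 0 or 1); a retained second X adds a
heterozygous band at 0.5; a 45,X/46,XX mixture displaces that band into two
bands.  For a 45,X cell fraction ``f`` the expected alternate-allele fraction
at a heterozygous site is

    q_upper = 1 / (2 - f)        (ALT on the X retained in every cell)
    q_lower = (1 - f) / (2 - f)  (ALT on the X lost from the 45,X line)

which invert to ``f = 2 - 1/u`` and ``f = (1 - 2l)/(1 - l)``.  The mosaic
fraction is estimated as the mean of the two band inversions.

XY material shows up as heterozygosity confined to the pseudoautosomal region
plus reads on Y.  Clinical ISCN karyotype strings, when available, override
the molecular call; they are parsed into cell lines from which the fractional
copy number of any Xp locus (here, TIMP1 at Xp11.23) is computed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ReadCountSite",
    "AAFProfile",
    "SexChromStatus",
    "SexChromCategory",
    "MosaicEstimate",
    "CellLine",
    "KaryotypeSpec",
    "IscnParseError",
    "PAR1_HG19",
    "TIMP1_LOCUS_HG19",
    "compute_aaf_profile",
    "classify_second_sex_chromosome",
    "estimate_mosaic_fraction",
    "parse_iscn",
    "locus_copy_number",
    "dichotomize_copy_number",
]

# hg19, 1-based inclusive
PAR1_HG19 = (60001, 2_699_520)
TIMP1_LOCUS_HG19 = (47_442_814, 47_446_090)

# Approximate hg19 cytoband boundaries for Xp (start, end), 1-based, used to
# decide whether a banded deletion/ring removes a queried locus.  Bands are
# ordered from the telomere toward the centromere.
_XP_BANDS = {
    "p22.33": (1, 4_300_000),
    "p22.32": (4_300_001, 6_000_000),
    "p22.31": (6_000_001, 9_500_000),
    "p22.3": (1, 9_500_000),  # umbrella band
    "p22.2": (9_500_001, 17_100_000),
    "p22.13": (17_100_001, 19_300_000),
    "p22.12": (19_300_001, 21_900_000),
    "p22.11": (21_900_001, 24_900_000),
    "p22.1": (17_100_001, 24_900_000),
    "p21.3": (24_900_001, 29_300_000),
    "p21.2": (29_300_001, 31_500_000),
    "p21.1": (31_500_001, 37_600_000),
    "p21": (24_900_001, 37_600_000),
    "p11.4": (37_600_001, 42_400_000),
    "p11.3": (42_400_001, 46_400_000),
    "p11.23": (46_400_001, 49_800_000),
    "p11.22": (49_800_001, 54_800_000),
    "p11.21": (54_800_001, 58_100_000),
    "p11.2": (46_400_001, 58_100_000),
    "p11.1": (58_100_001, 60_600_000),
    "p11": (37_600_001, 60_600_000),
}
_X_CENTROMERE = 60_600_000


# ---------------------------------------------------------------------------
# Allele-balance profiles


@dataclass(frozen=True)
class ReadCountSite:
    """REF/ALT read depths at one variant site."""

    chromosome: str
    position: int
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def aaf(self) -> float:
        """Alternate-allele frequency; NaN at zero depth."""
        if self.depth == 0:
            return float("nan")
        return self.alt_count / self.depth


@dataclass
class AAFProfile:
    """Depth-filtered, position-ordered allele-balance profile of one subject."""

    sites: list[ReadCountSite]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("sites must have strictly increasing positions")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=np.int64)

    @property
    def aaf(self) -> np.ndarray:
        return np.array([s.aaf for s in self.sites], dtype=float)


def compute_aaf_profile(
    sites: Sequence[ReadCountSite], min_depth: int = 10
) -> AAFProfile:
    """Drop sites below ``min_depth`` and package the rest as a profile."""
    kept = [s for s in sites if s.depth >= min_depth]
    return AAFProfile(sites=kept)


# ---------------------------------------------------------------------------
# Second-sex-chromosome classification


class SexChromCategory(str, Enum):
    MONOSOMY_X = "MONOSOMY_X"
    XX = "XX"
    XX_MOSAIC = "XX_MOSAIC"
    XXX_MOSAIC = "XXX_MOSAIC"
    XY_MATERIAL = "XY_MATERIAL"
    STRUCTURAL_SECOND_X = "STRUCTURAL_SECOND_X"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class SexChromStatus:
    category: SexChromCategory
    het_band_mass: float
    par_het_mass: float
    y_depth_fraction: float
    n_sites: int


@dataclass
class MosaicEstimate:
    """45,X cell-fraction estimate from displaced heterozygous bands."""

    fraction_45X: Optional[float]
    upper_band_estimate: Optional[float]
    lower_band_estimate: Optional[float]
    n_informative_sites: int

    @property
    def defined(self) -> bool:
        return self.fraction_45X is not None


@dataclass
class ClassifierThresholds:
    """Numeric cutoffs for the allele-balance classifier.

    het_window: AAF interval counted as "intermediate" (heterozygous-looking).
    min_het_mass: below this fraction of intermediate sites outside the PAR a
        profile is called monosomic.
    xx_center_tol: maximum displacement of the intermediate-band median from
        0.5 still called a plain 46,XX.
    y_depth_fraction: fraction of Y target sites with depth >= y_min_depth
        above which Y material is called.
    """

    het_window: tuple[float, float] = (0.10, 0.90)
    min_het_mass: float = 0.05
    mosaic_fraction_min: float = 0.15
    y_depth_fraction: float = 0.10
    y_min_depth: int = 5


def _het_mask(aaf: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (aaf > lo) & (aaf < hi)


def classify_second_sex_chromosome(
    x_profile: AAFProfile,
    y_profile: Optional[AAFProfile] = None,
    par_interval: tuple[int, int] = PAR1_HG19,
    thresholds: Optional[ClassifierThresholds] = None,
) -> SexChromStatus:
    """Call the second-sex-chromosome status group from allele balance.

    Monosomy X: effectively no intermediate-AAF sites outside the PAR and no
    Y evidence.  XY material: Y reads present (heterozygosity confined to the
    PAR corroborates).  XX: a strong intermediate band centred at 0.5.
    XX mosaic: intermediate bands displaced from 0.5.  Structural second-X
    categories cannot be separated from mosaicism on allele balance alone and
    are assigned only through a clinical-karyotype override.
    """
    cfg = thresholds or ClassifierThresholds()
    aaf = x_profile.aaf
    pos = x_profile.positions
    n = len(x_profile)
    covered = ~np.isnan(aaf)
    if n == 0 or not covered.any():
        return SexChromStatus(SexChromCategory.UNDETERMINED, 0.0, 0.0, 0.0, n)

    in_par = (pos >= par_interval[0]) & (pos <= par_interval[1])
    het = _het_mask(aaf, cfg.het_window) & covered
    non_par_cov = covered & ~in_par
    het_mass = het[non_par_cov].mean() if non_par_cov.any() else 0.0
    par_cov = covered & in_par
    par_het_mass = het[par_cov].mean() if par_cov.any() else 0.0

    y_frac = 0.0
    if y_profile is not None and len(y_profile) > 0:
        depths = np.array([s.depth for s in y_profile.sites])
        y_frac = float((depths >= cfg.y_min_depth).mean())

    if y_frac > cfg.y_depth_fraction:
        cat = SexChromCategory.XY_MATERIAL
    elif het_mass < cfg.min_het_mass:
        cat = SexChromCategory.MONOSOMY_X
    else:
        # displaced het bands are symmetric about 0.5, so the band-displacement
        # estimate (depth-noise corrected) separates XX from XX mosaic
        non_par_profile = AAFProfile(
            [s for s, keep in zip(x_profile.sites, ~in_par) if keep]
        )
        est = estimate_mosaic_fraction(non_par_profile)
        mosaic = est.defined and est.fraction_45X > cfg.mosaic_fraction_min
        cat = SexChromCategory.XX_MOSAIC if mosaic else SexChromCategory.XX
    return SexChromStatus(cat, float(het_mass), float(par_het_mass), y_frac, n)


@dataclass
class BandConfig:
    """Windows and guards for the mosaic-fraction band estimator.

    ``upper_window``/``lower_window`` bound the per-band medians of the
    "median" method; ``informative_window`` is the AAF interval in which a
    site counts as intermediate (heterozygous-looking); ``mixture_window``
    is the wider interval handed to the mixture likelihood, which models the
    band overlap explicitly and so tolerates tails beyond the band windows.
    """

    upper_window: tuple[float, float] = (0.5, 0.90)
    lower_window: tuple[float, float] = (0.10, 0.5)
    informative_window: tuple[float, float] = (0.10, 0.90)
    mixture_window: tuple[float, float] = (0.02, 0.98)
    n_min: int = 10


def _mixture_band_center(
    alt: np.ndarray, depth: np.ndarray
) -> Optional[float]:
    """Upper-band centre u by symmetric binomial-mixture maximum likelihood.

    Heterozygous sites carry ALT on either haplotype with equal probability,
    so ALT counts follow 0.5*Binom(d, u) + 0.5*Binom(d, 1-u); the two bands
    are mirror images about 0.5 and only their displacement is free.  The
    likelihood handles the band overlap near u = 0.5 that defeats hard
    assignment of sites to bands.
    """
    from scipy.optimize import minimize_scalar
    from scipy.stats import binom

    def nll(u: float) -> float:
        lik = 0.5 * binom.pmf(alt, depth, u) + 0.5 * binom.pmf(alt, depth, 1 - u)
        return -float(np.log(lik + 1e-300).sum())

    res = minimize_scalar(nll, bounds=(0.5, 0.999), method="bounded")
    return float(res.x) if res.success else None


def estimate_mosaic_fraction(
    x_profile: AAFProfile,
    band_config: Optional[BandConfig] = None,
    method: str = "mixture",
) -> MosaicEstimate:
    """Estimate the 45,X cell fraction from the displaced heterozygous bands.

    Band centres u (upper) and l (lower) are inverted analytically —
    ``f = 2 - 1/u`` and ``f = (1 - 2l)/(1 - l)`` — and the estimate is the
    mean of the defined inversions, clamped to [0, 1].

    ``method`` selects how the centres are located: ``"mixture"`` (default)
    fits the symmetric binomial mixture to intermediate-site ALT counts,
    which stays accurate when the two bands overlap at low mosaicism;
    ``"median"`` takes per-window medians, the exact choice for noise-free
    profiles.  Profiles with fewer than ``n_min`` intermediate sites return
    an undefined estimate with the site count recorded.
    """
    cfg = band_config or BandConfig()
    aaf_all = x_profile.aaf
    ok = ~np.isnan(aaf_all)
    aaf = aaf_all[ok]
    lo, hi = cfg.informative_window
    n_inf = int(((aaf > lo) & (aaf < hi)).sum())
    if n_inf < cfg.n_min:
        return MosaicEstimate(None, None, None, n_inf)

    if method == "mixture":
        alt = np.array([s.alt_count for s in x_profile.sites])[ok]
        depth = np.array([s.depth for s in x_profile.sites])[ok]
        mlo, mhi = cfg.mixture_window
        sel = (aaf > mlo) & (aaf < mhi)
        u = _mixture_band_center(alt[sel], depth[sel])
        if u is None:
            return MosaicEstimate(None, None, None, n_inf)
        l = 1.0 - u
        est_u = 2.0 - 1.0 / u
        est_l = (1.0 - 2.0 * l) / (1.0 - l)
        f = float(np.clip(0.5 * (est_u + est_l), 0.0, 1.0))
        return MosaicEstimate(f, est_u, est_l, n_inf)

    if method != "median":
        raise ValueError(f"unknown method {method!r}")
    upper = aaf[(aaf >= cfg.upper_window[0]) & (aaf < cfg.upper_window[1])]
    lower = aaf[(aaf > cfg.lower_window[0]) & (aaf <= cfg.lower_window[1])]
    est_u = est_l = None
    if upper.size:
        u = float(np.median(upper))
        est_u = 2.0 - 1.0 / u
    if lower.size:
        l = float(np.median(lower))
        est_l = (1.0 - 2.0 * l) / (1.0 - l)
    defined = [e for e in (est_u, est_l) if e is not None]
    if not defined:
        return MosaicEstimate(None, est_u, est_l, n_inf)
    f = float(np.clip(np.mean(defined), 0.0, 1.0))
    return MosaicEstimate(f, est_u, est_l, n_inf)


def mosaic_fraction_linear_fit(
    x_profile: AAFProfile, band_config: Optional[BandConfig] = None
) -> MosaicEstimate:
    """Alternative band estimator in the style of a fitted linear trend.

    Fits straight lines of mosaic fraction on band AAF through the model's
    exact anchor points (f in 0..1 at 0.1 steps) by least squares and
    evaluates them at the observed band centres.  Provided for comparison
    with the analytic inversion, which is the default estimator.
    """
    cfg = band_config or BandConfig()
    base = estimate_mosaic_fraction(x_profile, cfg)
    if base.upper_band_estimate is None and base.lower_band_estimate is None:
        return base
    f_grid = np.linspace(0.0, 1.0, 11)[:-1]  # f=1 has no het band
    q_upper = 1.0 / (2.0 - f_grid)
    q_lower = (1.0 - f_grid) / (2.0 - f_grid)
    aaf = x_profile.aaf
    aaf = aaf[~np.isnan(aaf)]
    ests = []
    upper = aaf[(aaf > cfg.upper_window[0]) & (aaf < cfg.upper_window[1])]
    lower = aaf[(aaf > cfg.lower_window[0]) & (aaf < cfg.lower_window[1])]
    est_u = est_l = None
    if upper.size:
        bu, au = np.polyfit(q_upper, f_grid, 1)
        est_u = float(bu * np.median(upper) + au)
        ests.append(est_u)
    if lower.size:
        bl, al = np.polyfit(q_lower, f_grid, 1)
        est_l = float(bl * np.median(lower) + al)
        ests.append(est_l)
    f = float(np.clip(np.mean(ests), 0.0, 1.0))
    return MosaicEstimate(f, est_u, est_l, base.n_informative_sites)


# ---------------------------------------------------------------------------
# ISCN karyotype parsing


class IscnParseError(ValueError):
    """Unparseable ISCN term; carries the offending token."""


@dataclass
class CellLine:
    """One cell line of a (possibly mosaic) karyotype."""

    iscn_term: str
    fraction: float
    n_intact_x: int
    y_present: bool
    structural_terms: list[str] = field(default_factory=list)

    def x_locus_copies(self, locus: tuple[int, int]) -> int:
        """Copies of an Xp locus carried by this cell line."""
        copies = self.n_intact_x
        for term in self.structural_terms:
            if _structural_carries_locus(term, locus):
                copies += 1
        return copies


@dataclass
class KaryotypeSpec:
    """Parsed ISCN karyotype: cell lines with fractions and X/Y content."""

    iscn: str
    cell_lines: list[CellLine]
    fractions_reported: bool

    def __post_init__(self) -> None:
        if not self.cell_lines:
            raise ValueError("at least one cell line required")
        total = sum(cl.fraction for cl in self.cell_lines)
        # printed percentage columns occasionally sum to 99 or 101
        if abs(total - 1.0) > 0.02:
            raise ValueError(
                f"cell-line fractions sum to {total:.3f}, outside 1 +/- 0.02: {self.iscn!r}"
            )

    @property
    def y_present(self) -> bool:
        return any(cl.y_present for cl in self.cell_lines)

    def format(self) -> str:
        parts = []
        for cl in self.cell_lines:
            term = cl.iscn_term
            if self.fractions_reported:
                term += f"[{round(cl.fraction * 100):.0f}%]"
            parts.append(term)
        return "/".join(parts)


# structural-term patterns of the clinical dialect used in TS cohorts
_STRUCT_RE = re.compile(
    r"""^(
        i\(Xq[0-9.]*\)            # isochromosome Xq
      | psu\s*idic\(Xq[0-9.]*\)   # pseudodicentric
      | idic\(Xq[0-9.]*\)
      | r(?:ing)?\(X[pq0-9.]*\)(?:,\s*small)?   # ring X, optional banded segment
      | del\(X[pq][0-9.]*(?:[pq][0-9.]*)?\)     # deletion, one or two breakpoints
      | \+?mar                    # marker chromosome
      | add\(\d+\)\([pq0-9.]+\)   # addition to an autosome
    )$""",
    re.VERBOSE,
)


def _parse_cell_line(term: str) -> tuple[int, bool, list[str]]:
    """Return (n_intact_x, y_present, structural_terms) for one ISCN cell line."""
    raw = term
    s = term.replace(" ", "")
    # tolerate "ring(X), small" whose comma splits the token
    s = s.replace("ring(X),small", "SMALLRING")
    tokens = s.split(",")
    if not tokens or not re.fullmatch(r"\d+[A-Za-z]*", tokens[0]):
        raise IscnParseError(f"cell line {raw!r}: missing chromosome count")
    # "45X" appears without the comma; peel trailing sex letters off the count
    m = re.fullmatch(r"(\d+)([XY]*)", tokens[0])
    if m is None:
        raise IscnParseError(f"cell line {raw!r}: bad count token {tokens[0]!r}")
    rest = list(tokens[1:])
    if m.group(2):
        rest.insert(0, m.group(2))

    n_x = 0
    y = False
    structural: list[str] = []
    for tok in rest:
        if tok == "":
            continue
        if tok == "SMALLRING":
            structural.append("ring(X),small")
            continue
        if re.fullmatch(r"[XY]+", tok):
            n_x += tok.count("X")
            y = y or "Y" in tok
            continue
        # "46,X+mar" appears without the comma before +mar
        m2 = re.fullmatch(r"(X+)(\+mar)", tok)
        if m2:
            n_x += len(m2.group(1))
            structural.append("+mar")
            continue
        tok_norm = tok.replace("psuidic", "psu idic")
        if _STRUCT_RE.match(tok_norm):
            structural.append(tok_norm)
            continue
        raise IscnParseError(f"cell line {raw!r}: unrecognized token {tok!r}")

    # clinical shorthand sometimes omits the intact X ("46,del(Xq13.1)");
    # infer it from the chromosome count: count - 44 sex-chromosome slots,
    # filled by X/Y letters, X-derived structural chromosomes and markers
    # (autosomal add(..) terms describe chromosome material, not a slot)
    count = int(m.group(1))
    slots = sum(1 for t in structural if not t.startswith("add("))
    declared = n_x + (1 if y else 0) + slots
    expected = count - 44
    if expected > declared:
        n_x += expected - declared
    return n_x, y, structural


def parse_iscn(karyotype: str) -> KaryotypeSpec:
    """Parse a slash-separated clinical ISCN karyotype string.

    Handles the mosaic dialect seen in Turner-syndrome reports: cell lines
    separated by ``/`` with optional ``[NN%]`` fractions, intact X/Y content,
    and the structural second-X terms i(Xq), ring(X) (plain, banded or
    "small"), del(Xp..)/del(Xq..), psu idic(Xq..), +mar and add(autosome).
    When no fractions are printed they are assigned so that mosaic summaries
    fall midway between the extreme cell lines (see ``locus_copy_number``).
    Unparseable tokens raise :class:`IscnParseError` naming the token.
    """
    if not karyotype or not karyotype.strip():
        raise IscnParseError("empty karyotype string")
    line_terms = [t.strip() for t in karyotype.split("/")]
    parsed = []
    fractions: list[Optional[float]] = []
    for term in line_terms:
        m = re.search(r"\[\s*(\d+(?:\.\d+)?)\s*%\s*\]\s*$", term)
        if m:
            fractions.append(float(m.group(1)) / 100.0)
            core = term[: m.start()].strip()
        else:
            fractions.append(None)
            core = term
        parsed.append((core, _parse_cell_line(core)))

    reported = [f for f in fractions if f is not None]
    fractions_reported = len(reported) == len(fractions) and len(fractions) > 0
    if not fractions_reported:
        if reported:
            # mixed labelling: spread the remaining mass equally
            remaining = max(0.0, 1.0 - sum(reported))
            n_un = fractions.count(None)
            fractions = [f if f is not None else remaining / n_un for f in fractions]
        else:
            fractions = [1.0 / len(fractions)] * len(fractions)

    cells = [
        CellLine(core, frac, n_x, y, structural)
        for (core, (n_x, y, structural)), frac in zip(parsed, fractions)
    ]
    return KaryotypeSpec(iscn=karyotype, cell_lines=cells,
                         fractions_reported=fractions_reported)


def _band_interval(band: str) -> tuple[int, int]:
    if band in _XP_BANDS:
        return _XP_BANDS[band]
    raise IscnParseError(f"unknown Xp band {band!r}")


def _structural_carries_locus(term: str, locus: tuple[int, int]) -> bool:
    """Does a structural second-X term carry the queried Xp locus?

    Rules for an Xp locus: i(Xq) lacks the p arm; del(Xq..) keeps it;
    del(Xp) (whole arm) loses it; a banded del(Xp A B) loses it only when the
    locus lies inside the deleted segment; plain ring(X) is counted as
    carrying it, while a "small" ring or a banded ring whose segment excludes
    the locus is not; markers, autosomal additions and Y carry nothing.
    psu idic(Xq..) is counted as a single carrier, matching how such
    chromosomes are tallied in clinical copy-number tables.
    """
    lo, hi = locus
    mid = (lo + hi) // 2
    t = term.replace(" ", "")
    if t.startswith("i(Xq") or t.startswith("idic(Xq"):
        return False
    if t.startswith("psuidic(Xq"):
        return True
    if t in ("+mar", "mar") or t.startswith("add("):
        return False
    m = re.fullmatch(r"r(?:ing)?\(X([pq0-9.]*)\)(,small)?", t)
    if m:
        if m.group(2):  # explicitly small ring: assume the locus is lost
            return False
        seg = m.group(1)
        if not seg:
            return True  # size unspecified: counted as carrying
        return _segment_contains(seg, mid)
    m = re.fullmatch(r"del\(X([pq][0-9.]*)([pq][0-9.]*)?\)", t)
    if m:
        arm1 = m.group(1)
        if arm1.startswith("q") and (m.group(2) is None or m.group(2).startswith("q")):
            return True  # q-arm deletion spares Xp entirely
        if m.group(2) is None:
            # single p breakpoint or bare "del(Xp)": terminal deletion from
            # the breakpoint band out to the telomere
            if arm1 == "p":
                return False
            _, b_hi = _band_interval(arm1)
            return mid > b_hi
        # two breakpoints: interstitial deletion between them
        start = _interval_of(m.group(1))
        end = _interval_of(m.group(2))
        seg_lo = min(start[0], end[0])
        seg_hi = max(start[1], end[1])
        return not (seg_lo <= mid <= seg_hi)
    raise IscnParseError(f"unrecognized structural term {term!r}")


def _interval_of(armband: str) -> tuple[int, int]:
    if armband.startswith("q"):
        # q-arm coordinates are only needed relative to Xp loci: anything on q
        # lies centromere-ward of every Xp position
        return (_X_CENTROMERE + 1, 155_270_560)
    return _band_interval(armband)


def _segment_contains(seg: str, pos: int) -> bool:
    """Is ``pos`` inside a ring segment written as e.g. ``p11.1q28``?"""
    m = re.fullmatch(r"([pq][0-9.]+)([pq][0-9.]+)?", seg)
    if not m:
        raise IscnParseError(f"unparseable ring segment {seg!r}")
    first = _interval_of(m.group(1))
    second = _interval_of(m.group(2)) if m.group(2) else first
    lo = min(first[0], second[0])
    hi = max(first[1], second[1])
    return lo <= pos <= hi


def locus_copy_number(
    kspec: KaryotypeSpec,
    locus: tuple[int, int] = TIMP1_LOCUS_HG19,
    rounding: Optional[int] = 1,
) -> float:
    """Fraction-weighted copy number of an Xp locus across cell lines.

    With printed cell-line fractions this is the plain weighted sum of
    per-line locus copies.  When a clinical string reports no fractions the
    mixture proportions are unknown; the copy number is then taken as the
    midpoint of the extreme cell lines (identical to an equal split for
    two-line mosaics), which is how unquantified mosaics are tallied in
    clinical copy-number tables.
    """
    per_line = [cl.x_locus_copies(locus) for cl in kspec.cell_lines]
    if kspec.fractions_reported or len(per_line) == 1:
        value = sum(cl.fraction * c for cl, c in zip(kspec.cell_lines, per_line))
    else:
        value = (min(per_line) + max(per_line)) / 2.0
    if rounding is not None:
        value = round(value + 1e-12, rounding)
    return value


def dichotomize_copy_number(copies: float, threshold: float = 1.1) -> str:
    """Group label '1 copy' (copies <= threshold) or '>1 copy'."""
    if copies < 0:
        raise ValueError(f"copy number must be non-negative, got {copies}")
    return "1 copy" if copies <= threshold else ">1 copy"
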