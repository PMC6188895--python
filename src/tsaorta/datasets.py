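"""Reference fixtures: cohort karyotype spectrum and TIMP3 variant panel.

These tables summarize the published characteristics of a 188-subject Turner
syndrome registry cohort and are the default generative conditions of the
synthetic-cohort simulator: the clinical karyotype spectrum with per-class
TIMP1 copy numbers, and the four TIMP3 coding variants with their
control-group allele frequencies and CADD deleteriousness scores.
"""

from __future__ import annotations

from .candidates import load_xp_gene_annotations  # re-exported convenience

__all__ = [
    "COHORT_KARYOTYPE_COUNTS",
    "cohort_karyotype_spectrum",
    "TIMP3_VARIANT_PANEL",
    "load_xp_gene_annotations",
]

# (ISCN string, number of subjects) for the 188-subject discovery cohort.
COHORT_KARYOTYPE_COUNTS: tuple[tuple[str, int], ...] = (
    ("45,X", 109),
    ("45,X/46,XY", 15),
    ("46,X,i(Xq)", 13),
    ("45,X/46,X,i(Xq)", 7),
    ("45,X[50%]/47,XXX[50%]", 4),
    ("45,X [50%]/46,X,ring(X)[50%]", 2),
    ("46,X,ring(X), small", 2),
    ("45X/46,X,i(Xq)/47,XXX", 1),
    ("46,X,ring(Xp11.1q28)[11%]/46,XX[89%]", 1),
    ("45,X[30%]/46,XX[70%]", 2),
    ("45,X[32%]/46,XX[68%]", 1),
    ("45,X[35%]/46,XX[65%]", 1),
    ("45,X[41%]/46,XX[59%]", 1),
    ("45,X/46,X,del(Xq21.1)", 1),
    ("45,X[55%]/46,XX[45%]", 1),
    ("45,X[65%]/46,XX[35%]", 1),
    ("45,X[63%]/46,X,del(Xq11.23)[37%]", 1),
    ("45,X[64%]/46,X,del(Xq22q24)[36%]", 1),
    ("45,X[72%]/46,XX[28%]", 1),
    ("45,X[75%]/46,XX[25%]", 1),
    ("45,X[74%]/46,del(Xq13.1)[26%]", 1),
    ("45,X[75%]/46,X,ring(X)[25%]", 1),
    ("45, X[80%]/46,X,ring(X)[20%]", 1),
    ("45,X[82%]/46,XX[18%]", 1),
    ("45,X[84%]/46,XX[16%]", 1),
    ("45,X[85%]/46,XX[15%]", 1),
    ("45,X[85%]/46,XX[16%]", 1),
    ("45,X[81%]/46,X,psuidic(Xq21)[19%]", 1),
    ("45,X[82%]/46,del(Xq22)[18%]", 1),
    ("45,X[82%]/46,X,del(Xp22.3p11.4)[18%]", 1),
    ("45,X[83%]/46,X,ring(X)[17%]", 1),
    ("45,X[85%]/46X,ring(X)[15%]", 1),
    ("45,X[88%]/46,XX[12%]", 1),
    ("45,X[88%]/46,X,del(Xq13.1)[12%]", 1),
    ("45,X,add(15)(p11.2)", 1),
    ("45,X/46,X,+mar", 1),
    ("45,X[20%]/46,X,i(Xq)[80%]", 1),
    ("45,X[82%]/46,X,del(Xp)[18%]", 1),
    ("45,X [86%]/ 46,X +mar [13%]", 1),
)


def cohort_karyotype_spectrum() -> list[tuple[str, float]]:
    """Karyotype spectrum as (ISCN string, cohort fraction) pairs."""
    total = sum(n for _, n in COHORT_KARYOTYPE_COUNTS)
    return [(k, n / total) for k, n in COHORT_KARYOTYPE_COUNTS]


# (rsID, chromosome, hg19 position, REF, ALT, control allele frequency,
#  CADD PHRED).  Control frequencies are the no-BAV group values; the
# rs11547635 synonymous variant is the deleterious risk allele (CADD 16.67).
TIMP3_VARIANT_PANEL: tuple[tuple[str, str, int, str, str, float, float], ...] = (
    ("rs9862", "22", 33_253_280, "T", "C", 0.505, 2.597),
    ("rs11547635", "22", 33_253_292, "C", "T", 0.035, 16.67),
    ("rs149161075", "22", 33_255_244, "C", "T", 0.0, 5.801),
    ("rs369072080", "22", 33_255_247, "G", "A", 0.0, 0.002),
)
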