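import numpy as np
import pytest
from hypothesis import settings

from tsaorta.datasets import COHORT_KARYOTYPE_COUNTS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cohort_karyotype_rows():
    """(ISCN string, printed TIMP1 copy number) for every cohort karyotype."""
    printed = {
        "45,X": 1.0,
        "45,X/46,XY": 1.0,
        "46,X,i(Xq)": 1.0,
        "45,X/46,X,i(Xq)": 1.0,
        "45,X[50%]/47,XXX[50%]": 2.0,
        "45,X [50%]/46,X,ring(X)[50%]": 1.5,
        "46,X,ring(X), small": 1.0,
        "45X/46,X,i(Xq)/47,XXX": 2.0,
        "46,X,ring(Xp11.1q28)[11%]/46,XX[89%]": 1.9,
        "45,X[30%]/46,XX[70%]": 1.7,
        "45,X[32%]/46,XX[68%]": 1.7,
        "45,X[35%]/46,XX[65%]": 1.7,
        "45,X[41%]/46,XX[59%]": 1.6,
        "45,X/46,X,del(Xq21.1)": 1.5,
        "45,X[55%]/46,XX[45%]": 1.5,
        "45,X[65%]/46,XX[35%]": 1.4,
        "45,X[63%]/46,X,del(Xq11.23)[37%]": 1.4,
        "45,X[64%]/46,X,del(Xq22q24)[36%]": 1.4,
        "45,X[72%]/46,XX[28%]": 1.3,
        "45,X[75%]/46,XX[25%]": 1.3,
        "45,X[74%]/46,del(Xq13.1)[26%]": 1.3,
        "45,X[75%]/46,X,ring(X)[25%]": 1.3,
        "45, X[80%]/46,X,ring(X)[20%]": 1.2,
        "45,X[82%]/46,XX[18%]": 1.2,
        "45,X[84%]/46,XX[16%]": 1.2,
        "45,X[85%]/46,XX[15%]": 1.2,
        "45,X[85%]/46,XX[16%]": 1.2,
        "45,X[81%]/46,X,psuidic(Xq21)[19%]": 1.2,
        "45,X[82%]/46,del(Xq22)[18%]": 1.2,
        "45,X[82%]/46,X,del(Xp22.3p11.4)[18%]": 1.2,
        "45,X[83%]/46,X,ring(X)[17%]": 1.2,
        "45,X[85%]/46X,ring(X)[15%]": 1.2,
        "45,X[88%]/46,XX[12%]": 1.1,
        "45,X[88%]/46,X,del(Xq13.1)[12%]": 1.1,
        "45,X,add(15)(p11.2)": 1.0,
        "45,X/46,X,+mar": 1.0,
        "45,X[20%]/46,X,i(Xq)[80%]": 1.0,
        "45,X[82%]/46,X,del(Xp)[18%]": 1.0,
        "45,X [86%]/ 46,X +mar [13%]": 1.0,
    }
    assert set(printed) == {k for k, _ in COHORT_KARYOTYPE_COUNTS}
    return sorted(printed.items())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
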