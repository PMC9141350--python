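import numpy as np
import pytest

from cardiophase.cohort_model import fit_cohorts, load_reference_slopes
from cardiophase.pmld_core import BeatSeries, SmoothingConfig, build_pmld, discriminant


@pytest.fixture(scope="session")
def reference_slopes():
    """Packaged per-person slope tables of the two study cohorts."""
    return load_reference_slopes()


@pytest.fixture(scope="session")
def reference_model(reference_slopes):
    """Cohort model fitted from the packaged slope tables."""
    return fit_cohorts(reference_slopes)


@pytest.fixture()
def smoothing():
    return SmoothingConfig()


def brute_force_smooth(x, y, ri=3, re=4):
    """Literal triple-loop implementation of the smoothed discriminant.

    Written independently of the vectorised path: iterates centre beats k,
    window positions j and lags delta, building every matrix explicitly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    ks, values = [], []
    for k in range(1 + ri + re, n - ri - re + 1):  # 1-based centre index
        total = 0.0
        for j in range(k - re, k + re + 1):
            for delta in range(1, ri + 1):
                total += discriminant(build_pmld(x, y, j, delta))
        ks.append(k)
        values.append(total / (ri * (2 * re + 1)))
    return np.array(ks), np.array(values)


def make_beats(rr, jt, n_load=None):
    """BeatSeries with the first ``n_load`` beats tagged load, rest recovery."""
    rr = np.asarray(rr, dtype=float)
    if n_load is None:
        n_load = len(rr)
    phase = np.array(
        ["load"] * n_load + ["recovery"] * (len(rr) - n_load), dtype=object
    )
    return BeatSeries(rr=rr, jt=np.asarray(jt, dtype=float), phase=phase)
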