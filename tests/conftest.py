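import numpy as np
import pytest

from zdiscquant.synthgen import (
    CrossSectionParams,
    LongitudinalParams,
    NoiseParams,
)

#: noise regime used throughout for "moderate noise" checks:
#: Poisson photon noise at 50 photons per intensity unit plus Gaussian
#: read noise at 2% of the 100-unit signal level.
MODERATE_NOISE = dict(poisson_gain=50.0, gaussian_sd=2.0)


@pytest.fixture
def clean_band_params():
    """One myofibril, one 1.4 µm band at 0.07 µm/px, no blur, no noise."""
    return LongitudinalParams(
        field_size_um=(3.0, 3.0),
        pixel_size_um=0.07,
        n_myofibrils=1,
        sarcomere_length_um=2.8,
        disc_diameter_um=1.4,
    )


@pytest.fixture
def noisy_field_params():
    """Full 36×36 µm field, mixed diameters, PSF + moderate noise."""
    return LongitudinalParams(
        disc_diameter_um=(0.98, 1.4, 1.82),
        psf_sigma_um=0.0703,
        noise=NoiseParams(seed=11, **MODERATE_NOISE),
    )


@pytest.fixture
def center_peaked_params():
    return CrossSectionParams(profile_kind="center_peaked", profile_scale_um=0.6)


@pytest.fixture
def ring_params():
    return CrossSectionParams(profile_kind="ring", profile_scale_um=1.0)


def oracle_intermeans_scan(hist: np.ndarray) -> int:
    """Independent exhaustive-scan oracle for the intermeans threshold.

    Vectorized over all candidate cut positions: the threshold is the
    rounded intermeans value at the first cut t (scanning upward from the
    lowest occupied bin) whose mean-of-class-means falls below t + 2 — the
    iteration's continuation rule checked after advancing the cut — never
    scanning past two bins below the highest occupied bin. Extreme-bin
    trimming matches the documented preprocessing.
    """
    hist = np.asarray(hist, dtype=float).copy()
    trimmed = hist.copy()
    trimmed[0] = 0
    trimmed[-1] = 0
    if np.count_nonzero(trimmed) >= 2:
        hist = trimmed
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    bins = np.arange(256, dtype=float)
    csum = np.cumsum(hist)
    cwsum = np.cumsum(bins * hist)
    ts = np.arange(lo, max(hi - 1, lo + 1))  # cuts lo .. hi-2, at least lo
    m1 = cwsum[ts] / csum[ts]
    m2 = (cwsum[hi] - cwsum[ts]) / (csum[hi] - csum[ts])
    r = (m1 + m2) / 2.0
    stop = np.nonzero(r < ts + 2)[0]
    idx = stop[0] if stop.size else ts.size - 1
    return int(np.floor(r[idx] + 0.5))


def fisher_2x2_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for a 2×2 table by integer enumeration.

    Sums hypergeometric probabilities no larger than the observed table's,
    using exact integer binomials so ties are resolved without epsilons.
    """
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            total += w
    return total / denom
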