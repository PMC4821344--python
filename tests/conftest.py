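"""Shared fixtures and independent oracles for the test suite."""

import logging

import numpy as np
import pytest

from fcskit import FitParams

logging.getLogger("fcskit").setLevel(logging.ERROR)


def naive_acf(counts: np.ndarray, lag_bins) -> np.ndarray:
    """Brute-force O(N*L) correlator with symmetric normalization.

    Independent oracle for the multi-tau correlator: G at integer lags,
    computed directly from the definition on the raw (uncoarsened)
    signal.
    """
    counts = np.asarray(counts, dtype=float)
    out = []
    for n in lag_bins:
        a, b = counts[:-n], counts[n:]
        out.append(np.dot(a, b) / a.size / (a.mean() * b.mean()))
    return np.asarray(out)


@pytest.fixture(scope="session")
def wt_params() -> FitParams:
    """Three-component wild-type parameter set (PSG measurements)."""
    return FitParams(
        N=1.0,
        fractions=(0.451, 0.414, 0.135),
        taus=(343.2e-6, 3.28e-3, 98.2e-3),
        S=5.0,
    )


@pytest.fixture(scope="session")
def lag_grid() -> np.ndarray:
    """Logarithmic lag grid spanning the standard fit window."""
    return np.geomspace(50e-6, 3.4, 160)
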