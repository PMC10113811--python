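"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately independent of the package's own
implementations: solar altitude via the Michalsky (1988) Astronomical Almanac
algorithm, and the pooled logistic MLE via a plain damped Newton solver.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pytest
from scipy.special import expit

from findiel import scene


# ---------------------------------------------------------------------------
# independent solar oracle (Michalsky 1988 approximate almanac algorithm)

def michalsky_altitude(lat: float, lon: float, t: datetime) -> float:
    """Geometric solar altitude in degrees, Michalsky's almanac algorithm."""
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    t = t.astimezone(timezone.utc)
    # days from J2000.0
    jd = t.timestamp() / 86400.0 + 2440587.5
    n = jd - 2451545.0
    rad = np.pi / 180.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = (357.528 + 0.9856003 * n) % 360.0
    lam = L + 1.915 * np.sin(g * rad) + 0.020 * np.sin(2 * g * rad)
    eps = 23.439 - 0.0000004 * n
    dec = np.arcsin(np.sin(eps * rad) * np.sin(lam * rad)) / rad
    ra = np.degrees(np.arctan2(np.cos(eps * rad) * np.sin(lam * rad), np.cos(lam * rad))) % 360.0
    ut_hours = t.hour + t.minute / 60.0 + t.second / 3600.0
    gmst = (6.697375 + 0.0657098242 * (jd - 2451545.0 - ut_hours / 24.0) + 1.0027379 * ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = (lmst * 15.0 - ra + 180.0) % 360.0 - 180.0
    alt = np.arcsin(
        np.sin(lat * rad) * np.sin(dec * rad) + np.cos(lat * rad) * np.cos(dec * rad) * np.cos(ha * rad)
    ) / rad
    return float(alt)


def michalsky_declination(t: datetime) -> float:
    """Solar declination (degrees) from the same independent algorithm."""
    jd = t.replace(tzinfo=timezone.utc).timestamp() / 86400.0 + 2440587.5
    n = jd - 2451545.0
    rad = np.pi / 180.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = (357.528 + 0.9856003 * n) % 360.0
    lam = L + 1.915 * np.sin(g * rad) + 0.020 * np.sin(2 * g * rad)
    eps = 23.439 - 0.0000004 * n
    return float(np.arcsin(np.sin(eps * rad) * np.sin(lam * rad)) / rad)


# ---------------------------------------------------------------------------
# independent pooled logistic MLE oracle

def pooled_logistic_newton(X: np.ndarray, y: np.ndarray, maxiter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Damped Newton-Raphson on the pooled (independence) logistic likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = expit(X @ beta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        # damping: halve while the log-likelihood decreases
        def ll(b):
            eta = X @ b
            return float(np.sum(y * eta - np.log1p(np.exp(eta))))
        base = ll(beta)
        scale = 1.0
        while ll(beta + scale * step) < base and scale > 1e-6:
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def quiet_noise() -> scene.NoiseSpec:
    return scene.NoiseSpec()


@pytest.fixture(scope="session")
def pulse_scene_10min(quiet_noise):
    """600 s scene with pulses at a fixed ~15 s interval, 12 dB SNR."""
    train = scene.PulseTrainSpec(snr_db=12.0, ipi_min=15.0, ipi_max=15.0, ipi_mode="fixed")
    return scene.render_scene(train, quiet_noise, duration=600.0, fs=250.0, seed=11)


@pytest.fixture(scope="session")
def noise_scene_10min(quiet_noise):
    seg, _ = scene.render_scene(None, quiet_noise, duration=600.0, fs=250.0, seed=12)
    return seg
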