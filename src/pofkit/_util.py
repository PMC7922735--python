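"""Small numeric helpers shared across modules."""
from __future__ import annotations

import numpy as np

HOURS_PER_DAY = 24.0


def truncated_normal(rng: np.random.Generator, sd: float, bound: float, size: int) -> np.ndarray:
    """Zero-mean normal draws with |x| <= bound (resampled, not clipped)."""
    if sd == 0 or size == 0:
        return np.zeros(size)
    x = rng.normal(0.0, sd, size)
    bad = np.abs(x) > bound
    while bad.any():
        x[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(x) > bound
    return x


def lognormal_mean_one(rng: np.random.Generator, sigma: np.ndarray, trunc: np.ndarray,
                       size: int) -> np.ndarray:
    """Mean-one lognormal multipliers, one column per sigma, z truncated at +-trunc sd."""
    sigma = np.asarray(sigma, float)
    out = np.empty((size, sigma.size))
    for j, (s, t) in enumerate(zip(sigma, np.asarray(trunc, float))):
        z = truncated_normal(rng, 1.0, t, size)
        # E[exp(s z - s^2/2)] = 1 for untruncated z; truncation keeps it within ~1e-3
        out[:, j] = np.exp(s * z - s * s / 2.0)
    return out


def lognormal_from_mean_cv(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Lognormal draws parameterised by arithmetic mean and coefficient of variation."""
    mean = np.asarray(mean, float)
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(s2)))


def circular_mean_hours(hours: np.ndarray, weights: np.ndarray) -> float:
    """Weighted circular mean of clock offsets, in [0, 24)."""
    th = 2.0 * np.pi * np.asarray(hours, float) / HOURS_PER_DAY
    w = np.asarray(weights, float)
    c = float(np.sum(w * np.cos(th)))
    s = float(np.sum(w * np.sin(th)))
    return (np.arctan2(s, c) * HOURS_PER_DAY / (2.0 * np.pi)) % HOURS_PER_DAY


def unwrap_about(hours: np.ndarray, centre: float) -> np.ndarray:
    """Map clock offsets to the representative within +-12 h of ``centre``."""
    h = np.asarray(hours, float)
    return centre + ((h - centre + 12.0) % HOURS_PER_DAY) - 12.0


def longest_circular_run(flags: np.ndarray) -> int:
    """Length of the longest circular run of True values."""
    flags = np.asarray(flags, bool)
    n = flags.size
    if flags.all():
        return n
    ext = np.concatenate([flags, flags])
    best = run = 0
    for f in ext:
        run = run + 1 if f else 0
        best = max(best, run)
    return min(best, n)
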