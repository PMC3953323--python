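"""Mixing assessment and ensemble summaries.

MCMC samples are autocorrelated; a quasi-independent subsequence is obtained
by keeping every k-th sample, where the skip length k is the smallest lag at
which the autocorrelation statistic drops below a threshold (0.2 by
default).  Angle series use a circular autocorrelation based on sines of
deviations from the circular mean, which is insensitive to the +-pi seam.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MixingReport",
    "autocorrelation",
    "recommended_skip",
    "mixing_report",
    "rmsd",
    "kabsch_rmsd",
    "dihedral_statistics",
    "energy_distance",
    "energy_distance_test",
]


def autocorrelation(series, max_lag: int, circular: bool = False) -> np.ndarray:
    """Normalized autocovariance at lags 0..max_lag.

    ``circular=True`` uses the circular variant: correlations of
    sin(theta - circular mean), appropriate for angle series.  A constant
    series has undefined correlation; it is reported as 0 beyond lag 0.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n <= max_lag:
        raise ValueError("series length must exceed max_lag")
    if circular:
        mu = sps.circmean(x, high=math.pi, low=-math.pi)
        x = np.sin(x - mu)
    else:
        x = x - x.mean()
    denom = float(np.dot(x, x))
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    scale = float(np.max(np.abs(np.asarray(series, dtype=float)))) or 1.0
    if denom < n * (1e-12 * scale) ** 2:  # constant series (up to roundoff)
        import warnings

        warnings.warn("constant series: autocorrelation undefined, reported as 0")
        out[1:] = 0.0
        return out
    for k in range(1, max_lag + 1):
        out[k] = float(np.dot(x[:-k], x[k:])) / denom
    return out


def recommended_skip(series_list, threshold: float = 0.2, max_lag: int = 200) -> int:
    """Smallest lag at which the mean absolute autocorrelation over all
    series falls below the threshold (monotone non-increasing in the
    threshold by construction)."""
    acfs = np.stack([autocorrelation(s, max_lag, circular=True) for s in series_list])
    stat = np.mean(np.abs(acfs), axis=0)
    below = np.nonzero(stat < threshold)[0]
    return int(below[0]) if below.size else max_lag


@dataclass
class MixingReport:
    """Per-variable autocorrelation and the skip-length recommendation."""

    acf: np.ndarray  # (n_series, max_lag + 1)
    threshold: float
    recommended_skip: int
    acceptance_rate: float | None = None

    def to_frame(self) -> pd.DataFrame:
        lags = np.arange(self.acf.shape[1])
        df = pd.DataFrame(self.acf.T, columns=[f"series_{i}" for i in range(self.acf.shape[0])])
        df.insert(0, "lag", lags)
        return df


def mixing_report(
    samples: np.ndarray,
    threshold: float = 0.2,
    max_lag: int = 200,
    circular: bool = True,
    acceptance_rate: float | None = None,
) -> MixingReport:
    """Autocorrelation summary for an (n_samples, n_variables) angle array."""
    samples = np.asarray(samples, dtype=float)
    acfs = np.stack(
        [autocorrelation(samples[:, j], max_lag, circular=circular) for j in range(samples.shape[1])]
    )
    stat = np.mean(np.abs(acfs), axis=0)
    below = np.nonzero(stat < threshold)[0]
    skip = int(below[0]) if below.size else max_lag
    return MixingReport(acf=acfs, threshold=threshold, recommended_skip=skip,
                        acceptance_rate=acceptance_rate)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, atom_selection=None) -> float:
    """Root-mean-square deviation in the common fixed frame (no
    superposition: loop anchors are shared, so refitting would hide real
    displacement)."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if atom_selection is not None:
        a = a[np.asarray(atom_selection)]
        b = b[np.asarray(atom_selection)]
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal superposition (for free chains without shared
    anchors)."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("coordinate shapes differ")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return float(np.sqrt(np.mean(np.sum((ac @ R.T - bc) ** 2, axis=1))))


def dihedral_statistics(
    ensemble_angles: np.ndarray, reference: np.ndarray | None = None
) -> pd.DataFrame:
    """Circular mean and mean absolute circular deviation per angle series.

    ``ensemble_angles`` is (n_samples, n_angles) in radians.  Deviations are
    measured from ``reference`` when given (e.g. the native structure),
    otherwise from the per-angle circular mean.  The pooled average deviation
    is attached as ``DataFrame.attrs['mean_abs_deviation_deg']``.
    """
    X = np.asarray(ensemble_angles, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("ensemble must be a non-empty (n_samples, n_angles) array")
    mu = sps.circmean(X, high=math.pi, low=-math.pi, axis=0)
    ref = mu if reference is None else np.asarray(reference, dtype=float)
    dev = np.arctan2(np.sin(X - ref[None]), np.cos(X - ref[None]))
    mad = np.mean(np.abs(dev), axis=0)
    df = pd.DataFrame(
        {
            "angle_index": np.arange(X.shape[1]),
            "circular_mean_deg": np.degrees(mu),
            "mean_abs_deviation_deg": np.degrees(mad),
        }
    )
    df.attrs["mean_abs_deviation_deg"] = float(np.degrees(mad.mean()))
    return df


def energy_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """Szekely-Rizzo energy distance between two multivariate samples."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    dxy = _mean_cross_distance(X, Y)
    dxx = _mean_cross_distance(X, X)
    dyy = _mean_cross_distance(Y, Y)
    return float(2.0 * dxy - dxx - dyy)


def _mean_cross_distance(A: np.ndarray, B: np.ndarray) -> float:
    d = np.sqrt(np.maximum(
        np.sum(A ** 2, axis=1)[:, None] + np.sum(B ** 2, axis=1)[None] - 2.0 * (A @ B.T),
        0.0,
    ))
    return float(d.mean())


def energy_distance_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 300,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sample permutation test on the energy distance.

    Returns (statistic, p-value).  The pairwise distance matrix is computed
    once; permutations only re-partition it.
    """
    rng = rng or np.random.default_rng(0)
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n, m = X.shape[0], Y.shape[0]
    Z = np.vstack([X, Y])
    D = np.sqrt(np.maximum(
        np.sum(Z ** 2, axis=1)[:, None] + np.sum(Z ** 2, axis=1)[None] - 2.0 * (Z @ Z.T),
        0.0,
    ))

    def stat(idx_x: np.ndarray, idx_y: np.ndarray) -> float:
        dxy = D[np.ix_(idx_x, idx_y)].mean()
        dxx = D[np.ix_(idx_x, idx_x)].mean()
        dyy = D[np.ix_(idx_y, idx_y)].mean()
        return 2.0 * dxy - dxx - dyy

    obs = stat(np.arange(n), np.arange(n, n + m))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n + m)
        if stat(perm[:n], perm[n:]) >= obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return float(obs), float(p)
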