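"""Directional statistics on the sphere for samples of aiming axes.

Aiming axes are unit 3-vectors; groups of them are modelled as draws from
the von Mises-Fisher (vMF) distribution, the rotationally symmetric
distribution on the 2-sphere with density proportional to
``exp(kappa * mu . x)`` (mean direction ``mu``, concentration ``kappa``).

Estimation uses the standard moment approximation
``kappa_hat = Rbar (3 - Rbar^2) / (1 - Rbar^2)`` where ``Rbar`` is the
mean resultant length.  Two tests are provided:

* :func:`mean_direction_test` — equality of mean directions across g
  samples without assuming equal concentrations, via the weighted-
  resultant statistic ``T = 2 (sum_i k_i R_i - ||sum_i k_i r_i||)``
  referred to chi-square with ``(p - 1)(g - 1)`` degrees of freedom
  (p = 3 on the 2-sphere), optionally calibrated by a within-sample
  bootstrap under the common-mean null.

* :func:`specified_mean_test` — whether a given direction ``mu0`` can be
  the mean of a sample, via the vMF log-likelihood ratio of the free
  versus fixed mean, calibrated by parametric bootstrap from the
  null fit vMF(mu0, kappa0).

Alongside p-values both tests report the angular distance between the
compared mean directions in degrees, the natural effect size for
directions (a separation above 15 degrees — the task's accuracy
criterion — is considered large).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "KAPPA_CAP",
    "DegenerateSampleError",
    "SphericalSample",
    "SphericalTestResult",
    "fit_vmf",
    "sample_vmf",
    "mean_direction_test",
    "specified_mean_test",
]

#: Concentration estimates are capped here (all-identical axes give Rbar = 1).
KAPPA_CAP = 1e6


class DegenerateSampleError(ValueError):
    """Sample resultant vanishes; no mean direction can be estimated."""


@dataclass(frozen=True)
class SphericalSample:
    """A sample of unit 3-vectors with its fitted vMF parameters."""

    axes: np.ndarray
    mu: np.ndarray
    kappa: float
    n: int

    @property
    def resultant_length(self) -> float:
        return float(np.linalg.norm(self.axes.sum(axis=0)))


@dataclass(frozen=True)
class SphericalTestResult:
    """Test statistic, reference df, p-value and angular effect size."""

    statistic: float
    df: int
    p_value: float
    mean_separation: float  # degrees between the compared mean directions


def _unit_rows(axes) -> np.ndarray:
    axes = np.asarray(axes, dtype=float)
    if axes.ndim != 2 or axes.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of unit vectors")
    norms = np.linalg.norm(axes, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("axes must be unit vectors within 1e-6")
    return axes / norms[:, None]


def _kappa_from_rbar(rbar: float) -> float:
    """Banerjee-style moment estimate of the vMF concentration on S^2."""
    rbar = min(max(rbar, 0.0), 1.0)
    if rbar >= 1.0 - 1e-12:
        return KAPPA_CAP
    return min(rbar * (3.0 - rbar**2) / (1.0 - rbar**2), KAPPA_CAP)


def _log_c3(kappa) -> np.ndarray:
    """log of the vMF normalizing constant kappa / (4 pi sinh kappa), stable."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    small = kappa < 1e-8
    out[small] = -np.log(4.0 * np.pi)
    k = kappa[~small]
    # log sinh(k) = k + log(1 - exp(-2k)) - log 2
    out[~small] = np.log(k) - np.log(4.0 * np.pi) - (k + np.log1p(-np.exp(-2.0 * k)) - np.log(2.0))
    return out


def fit_vmf(axes) -> SphericalSample:
    """Fit a von Mises-Fisher distribution by moments.

    ``mu`` is the normalized vector sum; ``kappa`` uses
    ``Rbar (3 - Rbar^2) / (1 - Rbar^2)`` and is capped at
    :data:`KAPPA_CAP` when the axes are (numerically) identical.
    """
    axes = _unit_rows(axes)
    n = len(axes)
    if n < 2:
        raise ValueError("need at least two axes to fit")
    resultant = axes.sum(axis=0)
    R = float(np.linalg.norm(resultant))
    if R < 1e-12:
        raise DegenerateSampleError("zero resultant; mean direction undefined")
    return SphericalSample(axes=axes, mu=resultant / R, kappa=_kappa_from_rbar(R / n), n=n)


def sample_vmf(mu, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit vectors from vMF(mu, kappa); kappa = 0 is uniform."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if kappa < 1e-12:
        g = rng.standard_normal((n, 3))
        return g / np.linalg.norm(g, axis=1, keepdims=True)
    return stats.vonmises_fisher(mu, kappa).rvs(n, random_state=rng)


def _angle_deg(u, v) -> float:
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _het_statistic(samples: list[SphericalSample]) -> float:
    kR = np.array([s.kappa * s.resultant_length for s in samples])
    weighted = np.array([s.kappa * s.resultant_length * s.mu for s in samples])
    return float(2.0 * (kR.sum() - np.linalg.norm(weighted.sum(axis=0))))


def mean_direction_test(
    samples,
    n_boot: int = 0,
    seed: int | None = None,
) -> SphericalTestResult:
    """Equality of mean directions with unequal concentrations.

    Parameters
    ----------
    samples : sequence of SphericalSample or (n, 3) arrays
        g >= 2 samples, each with at least 5 axes.
    n_boot : int
        0 (default) refers the statistic to its chi-square asymptote with
        ``(p - 1)(g - 1)`` df; a positive value additionally calibrates the
        null by bootstrap: each sample is rotated to the pooled mean
        direction and resampled with replacement within sample.

    The reported ``mean_separation`` is the largest pairwise angular
    distance among the sample mean directions (for g = 2, simply the
    angle between the two means).
    """
    fitted = [s if isinstance(s, SphericalSample) else fit_vmf(s) for s in samples]
    if len(fitted) < 2:
        raise ValueError("need at least two samples")
    if any(s.n < 5 for s in fitted):
        raise ValueError("each sample needs at least 5 axes")
    g = len(fitted)
    df = 2 * (g - 1)
    T = _het_statistic(fitted)
    sep = max(
        _angle_deg(a.mu, b.mu) for i, a in enumerate(fitted) for b in fitted[i + 1 :]
    )
    if n_boot <= 0:
        p = float(stats.chi2.sf(T, df))
        return SphericalTestResult(statistic=T, df=df, p_value=p, mean_separation=sep)

    # bootstrap calibration: impose the common-mean null by rotating each
    # sample's mean onto the pooled weighted mean, then resample within sample
    rng = np.random.default_rng(seed)
    pooled = np.sum([s.kappa * s.resultant_length * s.mu for s in fitted], axis=0)
    pooled = pooled / np.linalg.norm(pooled)
    null_axes = []
    for s in fitted:
        rot = _rotation_between(s.mu, pooled)
        null_axes.append(s.axes @ rot.T)
    count = 0
    for _ in range(n_boot):
        boot = [fit_vmf(a[rng.integers(0, len(a), size=len(a))]) for a in null_axes]
        if _het_statistic(boot) >= T:
            count += 1
    p = (1.0 + count) / (n_boot + 1.0)
    return SphericalTestResult(statistic=T, df=df, p_value=p, mean_separation=sep)


def _rotation_between(u, v) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v (shortest arc)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    axis = np.cross(u, v)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return np.eye(3)
        raise DegenerateSampleError("antipodal mean directions; rotation undefined")
    axis = axis / n
    angle = np.arccos(c)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _llr_free_vs_fixed(axes: np.ndarray, mu0: np.ndarray) -> float:
    """2 * (max log-lik with free mean - max log-lik with mean fixed at mu0)."""
    n = len(axes)
    resultant = axes.sum(axis=0)
    R = float(np.linalg.norm(resultant))
    C = float(resultant @ mu0)
    k1 = _kappa_from_rbar(R / n)
    k0 = _kappa_from_rbar(max(C, 0.0) / n)
    l1 = n * _log_c3(k1) + k1 * R
    l0 = n * _log_c3(k0) + k0 * C
    return float(2.0 * (l1 - l0))


def specified_mean_test(
    sample,
    mu0,
    n_boot: int = 999,
    seed: int | None = None,
) -> SphericalTestResult:
    """Can ``mu0`` be the mean direction of the sample?

    A vMF log-likelihood ratio compares the free-mean fit against the fit
    with the mean fixed at ``mu0`` (concentration re-estimated under the
    null from the resultant component along ``mu0``).  The null
    distribution of the statistic is calibrated by parametric bootstrap:
    ``n_boot`` samples of the same size are drawn from vMF(mu0, kappa0)
    and the p-value is ``(1 + #{LLR_b >= LLR}) / (n_boot + 1)``.

    The asymptotic reference would be chi-square with p - 1 = 2 df; ``df``
    reports that convention although the p-value is bootstrap-based.
    """
    s = sample if isinstance(sample, SphericalSample) else fit_vmf(sample)
    if s.n < 5:
        raise ValueError("need at least 5 axes")
    mu0 = np.asarray(mu0, dtype=float)
    mu0 = mu0 / np.linalg.norm(mu0)
    if n_boot < 19:
        raise ValueError("n_boot must be at least 19")
    T = _llr_free_vs_fixed(s.axes, mu0)
    C = float(s.axes.sum(axis=0) @ mu0)
    k0 = _kappa_from_rbar(max(C, 0.0) / s.n)

    rng = np.random.default_rng(seed)
    draws = sample_vmf(mu0, k0, n_boot * s.n, rng).reshape(n_boot, s.n, 3)
    resultants = draws.sum(axis=1)
    R_b = np.linalg.norm(resultants, axis=1)
    C_b = resultants @ mu0
    k1_b = np.array([_kappa_from_rbar(r / s.n) for r in R_b])
    k0_b = np.array([_kappa_from_rbar(max(c, 0.0) / s.n) for c in C_b])
    llr_b = 2.0 * (
        s.n * _log_c3(k1_b) + k1_b * R_b - (s.n * _log_c3(k0_b) + k0_b * C_b)
    )
    p = float((1.0 + np.sum(llr_b >= T)) / (n_boot + 1.0))
    return SphericalTestResult(
        statistic=T, df=2, p_value=p, mean_separation=_angle_deg(s.mu, mu0)
    )
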