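"""Circular statistics and vector/angle conversion for pointing data.

Conventions
-----------
Angles are degrees throughout the public API.  The circular standard
deviation is ``sqrt(-2 ln R)`` (the dispersion circular-statistics
toolboxes report as "std"), where ``R`` is the mean resultant length; the
angular deviation ``sqrt(2 (1 - R))`` is also exposed.  The von Mises
concentration ``kappa`` is estimated by inverting ``A(kappa) =
I1(kappa)/I0(kappa) = R`` with the Best-Fisher piecewise approximation,
bias-corrected for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.special import logsumexp

from ._angles import (  # noqa: F401  (re-exported geometry helpers)
    AZIMUTH_UNDEFINED_ELEVATION_DEG,
    azel_to_enu,
    azimuth_defined,
    enu_to_azel,
    great_circle_deg,
    wrap_deg,
)
from .session_model import DirectionAngles, PointingVector

#: kappa reported when R is numerically 1 (perfectly concentrated sample).
KAPPA_MAX = 1e6

#: mixture components closer than this are merged (degenerate, unimodal fit)
MIN_COMPONENT_SEPARATION_DEG = 20.0


# ---------------------------------------------------------------------------
# Samples and summaries
# ---------------------------------------------------------------------------

@dataclass
class CircularSample:
    """Angles in degrees (any real values; wrapped internally) with optional
    nonnegative weights."""

    angles_deg: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if self.angles_deg.size < 1:
            raise ValueError("empty circular sample")
        if self.weights is not None:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
            if self.weights.shape != self.angles_deg.shape:
                raise ValueError("weights shape mismatch")
            if np.any(self.weights < 0) or self.weights.sum() <= 0:
                raise ValueError("weights must be nonnegative with positive sum")

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float
    resultant_length: float
    circ_sd_deg: float
    n: int
    mean_defined: bool = True


@dataclass(frozen=True)
class VonMisesFit:
    mu_deg: float
    kappa: float
    loglik: float
    n: int
    saturated: bool = False


@dataclass(frozen=True)
class VMComponent:
    mu_deg: float
    kappa: float
    weight: float


@dataclass(frozen=True)
class MixtureFit:
    components: tuple[VMComponent, ...]
    loglik: float
    converged: bool
    n_iter: int
    collapsed: bool = False


def _as_sample(s) -> CircularSample:
    if isinstance(s, CircularSample):
        return s
    return CircularSample(np.asarray(s, dtype=float))


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def vector_to_angles(v: PointingVector, facing_heading_deg: float = 0.0
                     ) -> DirectionAngles:
    """Convert an ENU unit vector to body-referenced (azimuth, elevation).

    Elevation is ``asin(u)``; azimuth is ``atan2(e, n)`` (compass heading)
    minus the facing heading, wrapped to (-180, 180].  Azimuth is flagged
    undefined within 0.1 deg of the poles.
    """
    az, el = enu_to_azel(v.e, v.n, v.u, facing_heading_deg)
    return DirectionAngles(az, el, azimuth_defined=azimuth_defined(el))


def angles_to_vector(a: DirectionAngles, facing_heading_deg: float = 0.0
                     ) -> PointingVector:
    """Inverse of :func:`vector_to_angles`."""
    e, n, u = azel_to_enu(a.azimuth_deg, a.elevation_deg, facing_heading_deg)
    return PointingVector(e, n, u)


def circ_distance(a_deg, b_deg):
    """Signed smallest rotation (degrees in (-180, 180]) taking ``b`` to ``a``."""
    return wrap_deg(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


# ---------------------------------------------------------------------------
# Moments and tests
# ---------------------------------------------------------------------------

def circ_sd_from_R(resultant_length: float) -> float:
    """Circular SD sqrt(-2 ln R), degrees (+inf at R = 0)."""
    if resultant_length <= 0:
        return math.inf
    return math.degrees(math.sqrt(max(-2.0 * math.log(min(resultant_length, 1.0)), 0.0)))


def angular_deviation_from_R(resultant_length: float) -> float:
    """Angular deviation sqrt(2 (1 - R)), degrees."""
    return math.degrees(math.sqrt(max(2.0 * (1.0 - resultant_length), 0.0)))


def circ_mean(s) -> CircularSummary:
    """Weighted circular mean, resultant length and circular SD.

    ``C = sum w_i cos(theta_i)``, ``S = sum w_i sin(theta_i)``; the mean is
    ``atan2(S, C)`` and ``R = sqrt(C^2 + S^2) / sum w_i``.  ``R < 1e-12``
    leaves the mean undefined (flagged) with infinite circular SD.
    """
    s = _as_sample(s)
    theta = np.radians(s.angles_deg)
    w = s.weights if s.weights is not None else np.ones_like(theta)
    C = float(np.sum(w * np.cos(theta)))
    S = float(np.sum(w * np.sin(theta)))
    R = math.hypot(C, S) / float(np.sum(w))
    R = min(R, 1.0)
    if R < 1e-12:
        return CircularSummary(0.0, R, math.inf, s.n, mean_defined=False)
    mean = wrap_deg(math.degrees(math.atan2(S, C)))
    return CircularSummary(mean, R, circ_sd_from_R(R), s.n)


def rayleigh_test(s) -> tuple[float, float]:
    """Rayleigh test of uniformity: ``z = n R^2`` with the standard
    small-sample-corrected p-value
    ``p = exp(sqrt(1 + 4n + 4(n^2 - n^2 R^2)) - (1 + 2n))``.
    """
    s = _as_sample(s)
    if s.weights is not None:
        raise ValueError("rayleigh_test requires an unweighted sample")
    n = s.n
    if n < 2:
        raise ValueError("rayleigh_test requires n >= 2")
    R = circ_mean(s).resultant_length
    z = n * R * R
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - n * n * R * R))
                 - (1.0 + 2.0 * n))
    return z, float(min(max(p, 0.0), 1.0))


def watson_u2_test(s) -> tuple[float, float]:
    """Watson's U^2 test of circular uniformity (omnibus alternative to
    Rayleigh).  p-value from the asymptotic series on Stephens' modified
    statistic."""
    s = _as_sample(s)
    n = s.n
    if n < 2:
        raise ValueError("watson_u2_test requires n >= 2")
    u = np.sort((np.asarray(s.angles_deg) % 360.0) / 360.0)
    i = np.arange(1, n + 1)
    ubar = float(u.mean())
    u2 = float(np.sum((u - (2 * i - 1) / (2 * n)) ** 2) - n * (ubar - 0.5) ** 2
               + 1.0 / (12 * n))
    u2_mod = (u2 - 0.1 / n + 0.1 / n ** 2) * (1.0 + 0.8 / n)
    m = np.arange(1, 51)
    p = float(2.0 * np.sum((-1.0) ** (m - 1) * np.exp(-2.0 * m ** 2
                                                      * math.pi ** 2 * u2_mod)))
    return u2, float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# von Mises fitting
# ---------------------------------------------------------------------------

def _A1(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa)."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_R(R: float, n: int | None = None) -> float:
    """Best-Fisher piecewise inverse of A(kappa) = R, with Fisher's
    small-sample bias correction when ``n`` is given and <= 15."""
    R = float(min(max(R, 0.0), 1.0))
    if R >= 1.0 - 1e-12:
        return KAPPA_MAX
    if R < 0.53:
        kappa = 2.0 * R + R ** 3 + 5.0 * R ** 5 / 6.0
    elif R < 0.85:
        kappa = -0.4 + 1.39 * R + 0.43 / (1.0 - R)
    else:
        kappa = 1.0 / (R ** 3 - 4.0 * R ** 2 + 3.0 * R)
    if n is not None and n <= 15:
        if kappa < 2.0:
            kappa = max(kappa - 2.0 / (n * kappa), 0.0) if kappa > 0 else 0.0
        else:
            kappa = kappa * (n - 1) ** 3 / (n ** 3 + n)
    return float(min(kappa, KAPPA_MAX))


def _vm_loglik(theta: np.ndarray, mu: float, kappa: float) -> float:
    # log I0 computed via the exponentially scaled Bessel for stability
    log_i0 = math.log(float(special.i0e(kappa))) + kappa
    return float(np.sum(kappa * np.cos(theta - mu)) - theta.size
                 * (math.log(2.0 * math.pi) + log_i0))


def vonmises_fit(s) -> VonMisesFit:
    """Maximum-likelihood von Mises fit (mu = circular mean; kappa by
    Best-Fisher inversion, small-n corrected for n <= 15).

    A numerically perfectly concentrated sample saturates kappa at
    :data:`KAPPA_MAX` and sets the ``saturated`` flag.
    """
    s = _as_sample(s)
    if s.n < 2:
        raise ValueError("vonmises_fit requires n >= 2")
    summ = circ_mean(s)
    saturated = summ.resultant_length >= 1.0 - 1e-12
    kappa = kappa_from_R(summ.resultant_length, n=s.n)
    theta = np.radians(s.angles_deg)
    mu = math.radians(summ.mean_deg)
    return VonMisesFit(summ.mean_deg, kappa, _vm_loglik(theta, mu, kappa),
                       s.n, saturated=saturated)


def _vm_log_density(theta: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    log_i0 = math.log(float(special.i0e(kappa))) + kappa
    return kappa * np.cos(theta - mu) - math.log(2.0 * math.pi) - log_i0


def vonmises_mixture_fit(s, k: int = 2, seed: int = 0, restarts: int = 5,
                         max_iter: int = 500, tol: float = 1e-8) -> MixtureFit:
    """Two-component von Mises mixture by expectation-maximisation.

    Intended for bimodal pointing-error distributions (e.g. systematic
    90/180-degree flips in the mental-rotation condition).  Best of
    ``restarts`` seeded initialisations; the first restart is initialised at
    the single von Mises fit so the mixture log-likelihood can never fall
    below the k=1 fit.  The fit is collapsed to the single-component
    fallback (``collapsed`` flag set) when a component's weight drops below
    ``1/n`` or the two component means land within
    :data:`MIN_COMPONENT_SEPARATION_DEG` of each other — either way the
    sample carries no evidence of a separated second mode.
    """
    if k != 2:
        raise ValueError("only k=2 mixtures are supported")
    s = _as_sample(s)
    if s.n < 8:
        raise ValueError("mixture fit requires n >= 8")
    theta = np.radians(wrap_deg(s.angles_deg))
    n = s.n
    single = vonmises_fit(s)

    best: tuple | None = None
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        if r == 0:
            mus = np.array([math.radians(single.mu_deg)] * 2)
            kappas = np.array([min(single.kappa, 1e3)] * 2)
            weights = np.array([0.5, 0.5])
        else:
            mus = theta[rng.integers(0, n, size=2)]
            kappas = np.array([2.0, 2.0])
            weights = np.array([0.5, 0.5])
        ll_prev = -math.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            log_dens = np.stack([
                math.log(max(weights[j], 1e-300))
                + _vm_log_density(theta, mus[j], kappas[j])
                for j in range(2)
            ])
            log_norm = logsumexp(log_dens, axis=0)
            ll = float(np.sum(log_norm))
            resp = np.exp(log_dens - log_norm)
            # M step
            wsum = resp.sum(axis=1)
            weights = wsum / n
            for j in range(2):
                C = float(np.sum(resp[j] * np.cos(theta)))
                S = float(np.sum(resp[j] * np.sin(theta)))
                if wsum[j] > 1e-12:
                    mus[j] = math.atan2(S, C)
                    Rj = math.hypot(C, S) / wsum[j]
                    kappas[j] = min(kappa_from_R(Rj), 1e3)
            if ll - ll_prev < tol and n_iter > 1:
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, mus.copy(), kappas.copy(), weights.copy(), converged, n_iter)

    ll, mus, kappas, weights, converged, n_iter = best
    separation = abs(wrap_deg(math.degrees(mus[0] - mus[1])))
    # near-coincident components mean the sample is effectively unimodal
    # (the mixture exists to find well-separated 90/180-degree flip modes)
    if weights.min() < 1.0 / n or separation < MIN_COMPONENT_SEPARATION_DEG:
        return MixtureFit(
            components=(VMComponent(single.mu_deg, single.kappa, 1.0),),
            loglik=single.loglik, converged=True, n_iter=n_iter, collapsed=True)
    order = np.argsort(-weights)
    comps = tuple(
        VMComponent(wrap_deg(math.degrees(mus[j])), float(kappas[j]),
                    float(weights[j]))
        for j in order
    )
    return MixtureFit(comps, ll, converged, n_iter)


# ---------------------------------------------------------------------------
# Sensor artifacts
# ---------------------------------------------------------------------------

def detect_sensor_flips(errors_deg, elevations_deg, threshold_deg: float = -15.0,
                        window_deg: float = 20.0) -> np.ndarray:
    """Flag trials consistent with the compass 180-degree flip artifact:
    elevation below ``threshold_deg`` (strongly downward pointing) and a
    signed azimuth error within ``window_deg`` of +/-180."""
    err = np.atleast_1d(np.asarray(errors_deg, dtype=float))
    el = np.atleast_1d(np.asarray(elevations_deg, dtype=float))
    if err.shape != el.shape:
        raise ValueError("errors and elevations must have equal length")
    return (el < threshold_deg) & (np.abs(wrap_deg(err)) >= 180.0 - window_deg)
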