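"""Closed-form and quadrature quantities for feature diversity on birth-death trees.

A tree grows from one lineage for time t under a linear birth-death process
(speciation lam, extinction mu, supercritical lam > mu); features evolve on it
with gain rate r and loss rate nu; a field-of-bullets event at the present
keeps each extant species with probability s.  A feature born at time tau
behaves, in terms of the number of sampled extant species carrying it, exactly
like a linear birth-death process with birth lam and death mu + nu, sampled at
probability s after time t - tau.  Everything here follows from that reduction:

* ``bd_sampling_survival`` -- the probability R_t^s(lam, theta) that such a
  process has at least one sampled survivor;
* ``expected_fd_bd`` -- E[FD] of the pruned tree,
  r e^{(lam-mu)t} int_0^t e^{-(lam-mu)tau} R_tau^s(lam, mu+nu) dtau
  + F0 R_t^s(lam, mu+nu);
* ``phi_fd_finite_t`` and ``phi_fd_limit`` -- the surviving fraction of
  expected FD at finite t and its large-t limit s I(s)/I(1), a function of s
  and the two ratios rho1 = mu/lam, rho2 = nu/lam only;
* ``phi_pd`` -- the corresponding phylogenetic-diversity limit (the nu = 0
  case of phi_fd);
* ``fd_per_species_limit`` -- limiting expected FD per surviving species;
* ``expected_singletons`` -- expected number of features found in exactly one
  extant species, via dF_t/dt = r e^{(lam-mu)t} - (mu+nu) U_t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .trees import BDParams
from .gainloss import FeatureParams

__all__ = [
    "DerivedRatios",
    "bd_sampling_survival",
    "bd_sampling_survival_derivative",
    "phi_pd",
    "expected_fd_bd",
    "d_expected_fd_bd_dt",
    "phi_fd_finite_t",
    "phi_fd_limit",
    "fd_per_species_limit",
    "expected_singletons",
]

_QUAD_RTOL = 1e-9
#: below this nu/lam the feature-loss integral is numerically indistinguishable
#: from the pure-gain case and phi_fd delegates to phi_pd
_RHO2_SWITCHOVER = 1e-6
#: |beta| below this selects the rho = 1 branch of the limit integral
_BETA_TOL = 1e-9


@dataclass(frozen=True)
class DerivedRatios:
    """The dimensionless parameters governing the large-t FD ratio.

    rho1 = mu/lam in [0,1), rho2 = nu/lam >= 0; derived: rho = rho1 + rho2 and
    beta = 1 - (1-rho1)/rho2 (defined only for nu > 0).  rho = 1 iff beta = 0,
    rho > 1 iff beta > 0, and beta < 1 always.
    """

    rho1: float
    rho2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho1 < 1.0:
            raise ValueError(f"rho1 = mu/lam must be in [0,1), got {self.rho1}")
        if self.rho2 < 0.0:
            raise ValueError(f"rho2 = nu/lam must be >= 0, got {self.rho2}")

    @classmethod
    def from_rates(cls, lam: float, mu: float, nu: float) -> "DerivedRatios":
        if not lam > 0:
            raise ValueError("lam must be > 0")
        return cls(rho1=mu / lam, rho2=nu / lam)

    @property
    def rho(self) -> float:
        return self.rho1 + self.rho2

    @property
    def beta(self) -> float:
        if self.rho2 == 0.0:
            raise ValueError("beta is undefined for nu = 0")
        return 1.0 - (1.0 - self.rho1) / self.rho2


def bd_sampling_survival(lam: float, theta: float, s: float, t: float) -> float:
    """R_t^s(lam, theta): P(a linear birth-death process started from one
    individual has >= 1 descendant at time t that passes an independent
    sampling step with probability s).

        R_t^s = s(lam-theta) / (s lam + (lam(1-s) - theta) e^{(theta-lam)t})

    with the lam = theta branch s/(1 + lam s t) taken when |lam - theta| <=
    1e-12 * lam.  R_0^s = s; as t -> inf the value tends to 1 - theta/lam for
    lam > theta and to 0 otherwise.  s = 0 returns 0 (the limit).
    """
    if not lam > 0:
        raise ValueError("lam must be > 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0,1], got {s}")
    if t < 0:
        raise ValueError("t must be >= 0")
    if s == 0.0:
        return 0.0
    if abs(lam - theta) <= 1e-12 * lam:
        return s / (1.0 + lam * s * t)
    num = s * (lam - theta)
    den = s * lam + (lam * (1.0 - s) - theta) * math.exp((theta - lam) * t)
    return num / den


def bd_sampling_survival_derivative(
    lam: float, theta: float, s: float, t: float
) -> float:
    """d/dt of :func:`bd_sampling_survival` (analytic)."""
    if s == 0.0:
        return 0.0
    if abs(lam - theta) <= 1e-12 * lam:
        return -lam * s**2 / (1.0 + lam * s * t) ** 2
    a = s * (lam - theta)
    c = lam * (1.0 - s) - theta
    e = math.exp((theta - lam) * t)
    den = s * lam + c * e
    return -a * c * (theta - lam) * e / den**2


def phi_pd(rho: float, s: float) -> float:
    """Large-t surviving fraction of expected phylogenetic diversity.

    For a supercritical birth-death tree with extinction-to-speciation ratio
    rho = mu/lam in [0,1) and field-of-bullets survival s:

        phi_PD(s) = rho*s/(rho+s-1) * ln(s/(1-rho)) / ln(1/(1-rho))

    with removable-singularity branches -s ln(s)/(1-s) at rho = 0 and
    (1-s)/ln(1/s) at rho = 1-s.  Endpoints return s by continuity.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"phi_pd requires 0 <= rho < 1 (lam > mu), got {rho}")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0,1], got {s}")
    if s == 0.0:
        return 0.0
    if s == 1.0:
        return 1.0
    if rho <= 1e-10:
        return -s * math.log(s) / (1.0 - s)
    if abs(rho - (1.0 - s)) <= 1e-9:
        return (1.0 - s) / math.log(1.0 / s)
    return (
        rho * s / (rho + s - 1.0)
        * math.log(s / (1.0 - rho))
        / math.log(1.0 / (1.0 - rho))
    )


def expected_fd_bd(
    bd: BDParams, fp: FeatureParams, t: float, s: float
) -> float:
    """E[FD] of the pruned tree at time t (expectation over tree growth,
    feature evolution and the extinction event jointly; realisations where
    the tree dies before t contribute 0).

        E[FD] = r e^{(lam-mu)t} int_0^t e^{-(lam-mu)tau} R_tau^s(lam, mu+nu)
                dtau + F0 R_t^s(lam, mu+nu)
    """
    bd.require_supercritical()
    if t < 0:
        raise ValueError("t must be >= 0")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0,1], got {s}")
    lam, mu = bd.lam, bd.mu
    theta = mu + fp.nu
    net = lam - mu
    tail = fp.f0 * bd_sampling_survival(lam, theta, s, t)
    if fp.r == 0.0 or t == 0.0 or s == 0.0:
        return float(tail)
    integral, _ = integrate.quad(
        lambda tau: math.exp(-net * tau) * bd_sampling_survival(lam, theta, s, tau),
        0.0,
        t,
        epsrel=_QUAD_RTOL,
        epsabs=0.0,
        limit=200,
    )
    return float(fp.r * math.exp(net * t) * integral + tail)


def d_expected_fd_bd_dt(
    bd: BDParams,
    fp: FeatureParams,
    t: float,
    s: float = 1.0,
    method: str = "analytic",
) -> float:
    """Time derivative of :func:`expected_fd_bd`.

    ``analytic`` differentiates the expression directly (Leibniz + product
    rule): with J(t) the integral term,

        dF/dt = (lam-mu) r e^{(lam-mu)t} J(t) + r R_t^s + F0 dR_t^s/dt.

    ``numeric`` is a central difference with step max(1e-6, 1e-6*t), exposed
    as an independent cross-check.
    """
    bd.require_supercritical()
    if method == "numeric":
        h = max(1e-6, 1e-6 * t)
        lo = max(t - h, 0.0)
        return (expected_fd_bd(bd, fp, t + h, s) - expected_fd_bd(bd, fp, lo, s)) / (
            t + h - lo
        )
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    lam, mu = bd.lam, bd.mu
    theta = mu + fp.nu
    net = lam - mu
    r_t = bd_sampling_survival(lam, theta, s, t)
    tail = fp.f0 * bd_sampling_survival_derivative(lam, theta, s, t)
    integral_term = expected_fd_bd(bd, fp, t, s) - fp.f0 * r_t
    return float(net * integral_term + fp.r * r_t + tail)


def phi_fd_finite_t(bd: BDParams, fp: FeatureParams, t: float, s: float) -> float:
    """Surviving fraction of expected FD at finite t:
    E[FD(pruned)] / E[FD(unpruned)].  Independent of r when F0 = 0."""
    denom = expected_fd_bd(bd, fp, t, 1.0)
    if denom <= 0:
        raise ValueError("expected FD of the unpruned tree is 0")
    return expected_fd_bd(bd, fp, t, s) / denom


def _limit_integral(ratios: DerivedRatios, s: float) -> float:
    """I(s) of the large-t limit, branch-selected and numerically stable.

    rho != 1:  I(s) = int_0^1 dx / (1 - s(1-x^beta)/(1-rho)).
    For beta < 0 the substitution z = -beta ln x maps this to
    int_0^inf (1/|beta|) e^{-z/|beta|} / (1 + s(e^z - 1)/(1-rho)) dz,
    avoiding overflow of x^beta near 0 for arbitrarily large |beta|.
    rho = 1 (|beta| <= 1e-9):  I(s) = int_0^1 dx / (nu/lam - s ln x).
    """
    rho = ratios.rho
    beta = ratios.beta
    if abs(beta) <= _BETA_TOL:
        val, _ = integrate.quad(
            lambda x: 1.0 / (ratios.rho2 - s * math.log(x)),
            0.0,
            1.0,
            epsrel=_QUAD_RTOL,
            epsabs=0.0,
            limit=200,
        )
        return val
    if beta > 0:  # rho > 1: x^beta bounded on (0,1]
        val, _ = integrate.quad(
            lambda x: 1.0 / (1.0 - s * (1.0 - x**beta) / (1.0 - rho)),
            0.0,
            1.0,
            epsrel=_QUAD_RTOL,
            epsabs=0.0,
            limit=200,
        )
        return val
    ab = -beta

    def integrand(z: float) -> float:
        # log-space denominator: 1 + s(e^z - 1)/(1-rho) ~ s e^z/(1-rho) for large z
        if z > 700.0:
            log_den = math.log(s / (1.0 - rho)) + z
        else:
            log_den = math.log1p(s * math.expm1(z) / (1.0 - rho))
        return math.exp(-z / ab - log_den) / ab

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsrel=_QUAD_RTOL, epsabs=0.0, limit=200
    )
    return val


def phi_fd_limit(ratios: DerivedRatios, s: float) -> float:
    """Large-t surviving fraction of expected feature diversity.

        phi_FD(s) = s I(s) / I(1)

    a function of s, rho1 and rho2 alone; increasing and concave in s, lying
    between s and 1, decreasing in rho2 from phi_PD (rho2 -> 0) to s
    (rho2 -> inf).  Below rho2 = 1e-6 the computation delegates to
    :func:`phi_pd` (the two agree to well within quadrature tolerance there).
    Endpoints return 0 at s = 0 and 1 at s = 1 by continuity.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0,1], got {s}")
    if ratios.rho2 == 0.0:
        raise ValueError("nu = 0: feature diversity reduces to phylogenetic "
                         "diversity; use phi_pd")
    if s == 0.0:
        return 0.0
    if s == 1.0:
        return 1.0
    if ratios.rho2 < _RHO2_SWITCHOVER:
        return phi_pd(ratios.rho1, s)
    return s * _limit_integral(ratios, s) / _limit_integral(ratios, 1.0)


def fd_per_species_limit(
    ratios: DerivedRatios, r: float, nu: float, s: float
) -> float:
    """Large-t limit of E[FD(pruned)] / (s e^{(lam-mu)t}): expected feature
    diversity per surviving species.

        (r(1-rho)/nu) int_0^1 dx / (1 - s - rho + s x^beta)

    Stated only for rho != 1; rho = 1 raises.  Scales linearly in r.
    """
    if not 0.0 < s <= 1.0:
        raise ValueError(f"s must be in (0,1], got {s}")
    if nu <= 0:
        raise ValueError("requires nu > 0")
    beta = ratios.beta
    rho = ratios.rho
    if abs(beta) <= _BETA_TOL:
        raise ValueError("per-species limit undefined at rho = 1")
    # same integral as I(s) up to the factor (1-rho):
    # 1 - s - rho + s x^beta = (1-rho) (1 - s(1-x^beta)/(1-rho))
    return (r / nu) * _limit_integral(ratios, s)


def expected_singletons(bd: BDParams, fp: FeatureParams, t: float) -> float:
    """U_t: expected number of features present in exactly one extant species.

    Balancing gains against losses of uniquely held features gives
    dF_t/dt = r e^{(lam-mu)t} - (mu+nu) U_t with F_t = E[FD] of the full
    extant set, hence

        U_t = (r e^{(lam-mu)t} - dF_t/dt) / (mu + nu).

    At t = 0 this returns F0 (a single lineage holds every feature alone).
    """
    bd.require_supercritical()
    if bd.mu + fp.nu <= 0:
        raise ValueError("mu + nu must be > 0 (relation degenerate otherwise)")
    dfdt = d_expected_fd_bd_dt(bd, fp, t, s=1.0, method="analytic")
    return (fp.r * math.exp((bd.lam - bd.mu) * t) - dfdt) / (bd.mu + fp.nu)
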