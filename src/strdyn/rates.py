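"""Mutation-rate models: context substitution rates, length-dependent
instability rate curves, their parameterizations, and prior construction.

Substitutions that change a repeat tract's length are classified by
trinucleotide context in the binary A/B genome picture (A = focal motif
unit, B = anything else): BBA>BAA lengthens, AAB>ABB shortens, AAA>ABA
splits a tract (fission), ABA>AAA joins two tracts (fusion), BBB>BAB
creates a single unit and BAB>BBB destroys one.  These rates are treated
as length independent.

Expansion, contraction and non-motif-insertion rates are length dependent
("repeat length instability").  Below the instability onset they come from
trio-based empirical estimates (L = 1..8); above it they are parameterized
by one of a family of power-law / logarithmic forms anchored at L = 9,
with the non-motif insertion rate tied to 1% of the expansion rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import multivariate_normal

__all__ = [
    "SubstitutionContextRates",
    "RateCurve",
    "ParamSpec",
    "ParamGrid",
    "FAMILIES",
    "build_rate_table",
    "interpolate_rates",
    "default_substitution_rates",
    "default_empirical_curve",
    "uniform_prior",
    "fit_informative_prior",
]

# ratio of non-motif insertion to expansion rate wherever parameterized
IOTA_OVER_EPS = 0.01
# first parameterized length: empirical estimates cover L = 1..8
L_EMP = 8
L_ANCHOR = 9


@dataclass(frozen=True)
class SubstitutionContextRates:
    """Per-generation, per-target substitution and B-indel rates.

    Defaults are the mono-A point estimates from pooled de novo trio data.
    ``mu`` denotes the substitution rate that adds a motif unit to a tract
    (the BBA>BAA class) and ``nu`` the rate that removes one (AAB>ABB);
    the stationary A fraction under two-way substitution is mu/(mu+nu).
    """

    lengthening: float = 4.58e-9  # BBA>BAA / ABB>AAB
    shortening: float = 7.74e-9  # AAB>ABB / BAA>BBA
    fusion: float = 2.74e-9  # ABA>AAA
    fission: float = 4.35e-9  # AAA>ABA
    create_a1: float = 3.80e-9  # BBB>BAB
    destroy_a1: float = 6.17e-9  # BAB>BBB
    b_insert: float = 1.38e-10  # BB>BBB, per B unit
    b_delete: float = 4.37e-12  # BBB>BB, per B unit
    b1_delete: float = 2.76e-10  # ABA>AA, per length-1 B string

    @property
    def mu(self) -> float:
        return self.lengthening

    @property
    def nu(self) -> float:
        return self.shortening

    @property
    def p_a(self) -> float:
        """Stationary A fraction under two-way substitution, mu/(mu+nu)."""
        return self.mu / (self.mu + self.nu)

    @classmethod
    def two_way(cls, a_to_b: float, b_to_a: float) -> "SubstitutionContextRates":
        """Uniform two-way point-mutation process (no context dependence).

        Every A site flips at ``a_to_b`` and every B site at ``b_to_a``
        regardless of neighbors; B indels are off.  The sequence-level
        stationary state is i.i.d. with p_A = b_to_a / (a_to_b + b_to_a),
        whose tract-length law is geometric — the short-repeat limit.
        """
        return cls(
            lengthening=b_to_a,
            shortening=a_to_b,
            fusion=b_to_a,
            fission=a_to_b,
            create_a1=b_to_a,
            destroy_a1=a_to_b,
            b_insert=0.0,
            b_delete=0.0,
            b1_delete=0.0,
        )

    def scaled(self, factor: float) -> "SubstitutionContextRates":
        return SubstitutionContextRates(
            *(getattr(self, f.name) * factor for f in self.__dataclass_fields__.values())
        )


def default_substitution_rates() -> SubstitutionContextRates:
    return SubstitutionContextRates()


@dataclass
class RateCurve:
    """Per-target expansion/contraction/non-motif-insertion rates by length.

    Arrays are dense, indexed by tract length in units; index 0 is unused.
    ``provenance`` holds one of 'empirical', 'parameterized', 'interpolated'
    per length.
    """

    eps: np.ndarray
    kap: np.ndarray
    iot: np.ndarray
    provenance: list = field(default_factory=list)

    @property
    def L_bound(self) -> int:
        return len(self.eps) - 1

    def __post_init__(self):
        for arr in (self.eps, self.kap, self.iot):
            if np.any(arr[1:] < 0) or not np.all(np.isfinite(arr[1:])):
                raise ValueError("rates must be nonnegative and finite")
        if not self.provenance:
            self.provenance = ["parameterized"] * (self.L_bound + 1)

    def truncated(self, L_bound: int) -> "RateCurve":
        if L_bound >= self.L_bound:
            return self
        return RateCurve(
            self.eps[: L_bound + 1].copy(),
            self.kap[: L_bound + 1].copy(),
            self.iot[: L_bound + 1].copy(),
            self.provenance[: L_bound + 1],
        )


def default_empirical_curve(L_bound: int = L_EMP) -> RateCurve:
    """Synthetic stand-in for trio-based instability rates at L = 1..8.

    The published per-length estimates are not reproduced here; this table
    is a synthetic anchor emulating their qualitative shape — a rapid
    (roughly e-fold per unit) rise through L = 5..8 — pinned so that
    epsilon(8) ~ 1.1e-8 and kappa(8) ~ 6.8e-9.  Those anchors are implied
    by the inferred power-law constants (c_eps ~ 2.7e-8, c_kap ~ 1.7e-8
    at L = 9 with a multiplier jump m ~ 2.5), keep L = 8 expansion-biased,
    and set the relative weight of context-substitution fission against
    repeat instability that the dynamical regimes hinge on.  iota =
    epsilon/100 throughout.
    """
    L = np.arange(0, max(L_bound, L_EMP) + 1, dtype=float)
    eps = 1.1e-8 * np.exp(L - 8)
    kap = 6.8e-9 * np.exp(L - 8)
    eps[0] = kap[0] = 0.0
    iot = eps * IOTA_OVER_EPS
    prov = ["empirical"] * (len(L))
    return RateCurve(eps[: L_bound + 1], kap[: L_bound + 1], iot[: L_bound + 1],
                     prov[: L_bound + 1])


# ---------------------------------------------------------------------------
# parameterization families (functional forms anchored at L = 9)
# ---------------------------------------------------------------------------

# family -> ordered parameter names
FAMILIES = {
    "symmetric_power": ("c", "tau"),
    "decoupled_power": ("c_eps", "c_kap", "tau_eps", "tau_kap"),
    "shared_exponent_power": ("c", "tau_eps", "tau_kap"),
    "shared_constant_power": ("c_eps", "c_kap", "tau"),
    "multiplier_coupled_power": ("m", "tau_eps", "tau_kap"),
    "symmetric_log": ("c", "tau"),
    "decoupled_log": ("c_eps", "c_kap", "tau_eps", "tau_kap"),
    "multiplier_coupled_log": ("m", "tau_eps", "tau_kap"),
    "pure_power": ("lam_eps", "lam_kap", "tau_eps", "tau_kap"),
}

_LOG_FAMILIES = {"symmetric_log", "decoupled_log", "multiplier_coupled_log"}


@dataclass(frozen=True)
class ParamSpec:
    """A point in one parameterization family's parameter space."""

    family: str
    theta: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        names = FAMILIES[self.family]
        if len(self.theta) != len(names):
            raise ValueError(
                f"{self.family} takes {len(names)} parameters {names}, "
                f"got {len(self.theta)}"
            )
        if any(not np.isfinite(v) or v < 0 for v in self.theta):
            raise ValueError("parameters must be finite and nonnegative")

    def __getattr__(self, name):
        names = FAMILIES[object.__getattribute__(self, "family")]
        theta = object.__getattribute__(self, "theta")
        if name in names:
            return theta[names.index(name)]
        raise AttributeError(name)

    def anchors(self, empirical: RateCurve | None = None,
                subst: SubstitutionContextRates | None = None):
        """Resolve (c_eps, c_kap, tau_eps, tau_kap): rates at L = 9 and
        exponents, for every family except pure_power."""
        f = self.family
        if f in ("symmetric_power", "symmetric_log"):
            return self.c, self.c, self.tau, self.tau
        if f in ("decoupled_power", "decoupled_log"):
            return self.c_eps, self.c_kap, self.tau_eps, self.tau_kap
        if f == "shared_exponent_power":
            return self.c, self.c, self.tau_eps, self.tau_kap
        if f == "shared_constant_power":
            return self.c_eps, self.c_kap, self.tau, self.tau
        if f in ("multiplier_coupled_power", "multiplier_coupled_log"):
            if empirical is None:
                raise ValueError("multiplier families need empirical rates")
            return (
                self.m * empirical.eps[L_EMP],
                self.m * empirical.kap[L_EMP],
                self.tau_eps,
                self.tau_kap,
            )
        raise ValueError(f"{f} has no L=9 anchor form")

    @property
    def delta_tau(self) -> float:
        names = FAMILIES[self.family]
        if "tau_eps" in names and "tau_kap" in names:
            return self.tau_kap - self.tau_eps
        return 0.0


def _shape(family: str, L: np.ndarray) -> np.ndarray:
    """Length-dependence factor, equal to 1 at L = 9."""
    if family in _LOG_FAMILIES:
        return np.log(L - 7.0) / np.log(2.0)
    return L / 9.0


def build_rate_table(
    spec: ParamSpec,
    empirical: RateCurve | None,
    L_bound: int,
    subst: SubstitutionContextRates | None = None,
) -> RateCurve:
    """Full rate curve on L = 1..L_bound for one parameter combination.

    All families except ``pure_power`` splice empirical rates at L <= 8 to
    the parameterized form at L > 8; non-motif insertion follows the
    expansion rate at 1% wherever parameterized (and keeps its empirical
    values below L = 9).  ``pure_power`` ignores empirical rates entirely:
    eps(L) = mu (L/lam_eps)^tau_eps, kap(L) = nu (L/lam_kap)^tau_kap at
    every length, with iota = eps/100 throughout.
    """
    L = np.arange(0, L_bound + 1, dtype=float)
    eps = np.zeros(L_bound + 1)
    kap = np.zeros(L_bound + 1)
    iot = np.zeros(L_bound + 1)
    prov = ["parameterized"] * (L_bound + 1)

    if spec.family == "pure_power":
        if subst is None:
            subst = default_substitution_rates()
        with np.errstate(divide="ignore"):
            eps[1:] = subst.mu * (L[1:] / spec.lam_eps) ** spec.tau_eps
            kap[1:] = subst.nu * (L[1:] / spec.lam_kap) ** spec.tau_kap
        iot[1:] = eps[1:] * IOTA_OVER_EPS
        return RateCurve(eps, kap, iot, prov)

    if empirical is None:
        raise ValueError(f"family {spec.family!r} requires empirical rates at L <= 8")
    if empirical.L_bound < L_EMP:
        raise ValueError("empirical rates must cover L = 1..8")
    n_emp = min(L_EMP, L_bound)
    eps[1 : n_emp + 1] = empirical.eps[1 : n_emp + 1]
    kap[1 : n_emp + 1] = empirical.kap[1 : n_emp + 1]
    iot[1 : n_emp + 1] = empirical.iot[1 : n_emp + 1]
    for i in range(1, n_emp + 1):
        prov[i] = "empirical"

    if L_bound > L_EMP:
        c_eps, c_kap, tau_eps, tau_kap = spec.anchors(empirical)
        hi = L[L_EMP + 1 :]
        shape = _shape(spec.family, hi)
        eps[L_EMP + 1 :] = c_eps * shape**tau_eps
        kap[L_EMP + 1 :] = c_kap * shape**tau_kap
        iot[L_EMP + 1 :] = eps[L_EMP + 1 :] * IOTA_OVER_EPS
    return RateCurve(eps, kap, iot, prov)


def interpolate_rates(curve: RateCurve, join_window=(L_EMP, 12)) -> RateCurve:
    """Smooth the empirical/parameterized discontinuity at L = 9.

    Rates at interior lengths of ``join_window = (lo, hi)`` are replaced by
    log-linear interpolation between the rates at lo and hi (a monotone
    scheme; endpoints preserved exactly).  A window with no interior
    lengths returns the curve unchanged.
    """
    lo, hi = join_window
    if hi - lo < 2 or hi > curve.L_bound:
        return curve
    out = RateCurve(
        curve.eps.copy(), curve.kap.copy(), curve.iot.copy(), list(curve.provenance)
    )
    xs = np.arange(lo + 1, hi)
    for arr in (out.eps, out.kap, out.iot):
        if arr[lo] <= 0 or arr[hi] <= 0:
            continue
        logv = np.log(arr[lo]) + (np.log(arr[hi]) - np.log(arr[lo])) * (
            (xs - lo) / (hi - lo)
        )
        arr[xs] = np.exp(logv)
    for x in xs:
        out.provenance[x] = "interpolated"
    return out


# ---------------------------------------------------------------------------
# parameter grids and priors
# ---------------------------------------------------------------------------


@dataclass
class ParamGrid:
    """Discrete grid over one family's parameter space."""

    family: str
    axes: dict  # parameter name -> 1-D array of values

    def __post_init__(self):
        names = FAMILIES[self.family]
        if tuple(self.axes) != names:
            raise ValueError(f"axes must be {names} in order, got {tuple(self.axes)}")

    @property
    def shape(self) -> tuple:
        return tuple(len(v) for v in self.axes.values())

    @property
    def n(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> list:
        return [
            ParamSpec(self.family, tup)
            for tup in itertools.product(*self.axes.values())
        ]

    def index_of(self, theta: tuple) -> int:
        idx = 0
        for name, v in zip(self.axes, theta):
            ax = self.axes[name]
            i = int(np.argmin(np.abs(np.asarray(ax) - v)))
            if not np.isclose(ax[i], v):
                raise KeyError(f"{name}={v} not on grid")
            idx = idx * len(ax) + i
        return idx


def default_grid(family: str = "multiplier_coupled_power") -> ParamGrid:
    """Package-default grids: log-spaced rate constants over 1e-9..1e-6,
    exponents 0..4 in steps of 0.1, the canonical multiplier ladder, and
    integer onset lengths 4..20."""
    const = np.geomspace(1e-9, 1e-6, 31)
    tau = np.round(np.arange(0.0, 4.01, 0.1), 10)
    m = np.array([1.0, 1.6, 2.5, 4.0, 6.4, 10.0])
    lam = np.arange(4.0, 21.0)
    axes_by_name = {
        "c": const, "c_eps": const, "c_kap": const,
        "tau": tau, "tau_eps": tau, "tau_kap": tau,
        "m": m, "lam_eps": lam, "lam_kap": lam,
    }
    return ParamGrid(family, {p: axes_by_name[p] for p in FAMILIES[family]})


def uniform_prior(grid: ParamGrid) -> np.ndarray:
    """Every grid point equally probable (mass 1/n)."""
    return np.full(grid.n, 1.0 / grid.n)


def _fit_loglog(lengths, rates, sigmas):
    """Weighted linear fit of log(rate) on log(L/9): returns mean vector
    (log c at L=9, tau) and its 2x2 covariance."""
    x = np.log(np.asarray(lengths, dtype=float) / L_ANCHOR)
    y = np.log(np.asarray(rates, dtype=float))

    def line(x, logc, tau):
        return logc + tau * x

    popt, pcov = curve_fit(line, x, y, p0=(np.mean(y), 1.0), sigma=sigmas,
                           absolute_sigma=True)
    return popt, pcov


def fit_informative_prior(
    popstr_lengths,
    popstr_eps,
    popstr_kap,
    grid: ParamGrid,
    inflation: float = 100.0,
    empirical: RateCurve | None = None,
    trust_range=(13, 21),
    distrust_factor: float = 100.0,
    eps_sigma_log=None,
    kap_sigma_log=None,
) -> np.ndarray:
    """Empirically informed prior from population-caller rate estimates.

    Expansion-like and contraction rates at mid lengths (nominally
    L = 11..29) are fit by weighted straight lines in log-log space; the
    variance of points outside the trusted length range (13..21) is
    inflated by ``distrust_factor`` to absorb suspected systematic error at
    the range edges.  Each fit's value and spread at L = 9 define a 2x2
    covariance over (log c, tau); expansion and contraction blocks are
    assumed independent, the 4x4 block covariance is inflated by
    ``inflation`` (100 = 'restrictive', 1000 = 'permissive'), and the
    resulting multivariate normal is evaluated at every grid point and
    normalized over the grid.

    For the ``pure_power`` family the functional form is instead fit
    directly to the combined estimates (nominally L = 4..15) and the prior
    is a normal over (lam_eps, lam_kap, tau_eps, tau_kap) with 100-fold
    inflated covariance.
    """
    lengths = np.asarray(popstr_lengths, dtype=float)
    if len(lengths) < 3:
        raise ValueError("need at least 3 usable lengths for the prior fit")

    def sig(base):
        s = np.full(len(lengths), 0.2) if base is None else np.asarray(base, float)
        out = s.copy()
        out[(lengths < trust_range[0]) | (lengths > trust_range[1])] *= np.sqrt(
            distrust_factor
        )
        return out

    if grid.family == "pure_power":
        subst = default_substitution_rates()
        x = np.log(lengths)

        def form(x, lam, tau, mu0):
            return np.log(mu0) + tau * (x - np.log(lam))

        means, blocks = [], []
        for rates, mu0, s in (
            (popstr_eps, subst.mu, sig(eps_sigma_log)),
            (popstr_kap, subst.nu, sig(kap_sigma_log)),
        ):
            y = np.log(np.asarray(rates, float))
            popt, pcov = curve_fit(
                lambda x, lam, tau: form(x, lam, tau, mu0), x, y,
                p0=(9.0, 3.0), sigma=s, absolute_sigma=True,
            )
            means.append(popt)
            blocks.append(pcov)
        mean = np.array([means[0][0], means[1][0], means[0][1], means[1][1]])
        cov = np.zeros((4, 4))
        cov[0, 0], cov[0, 2] = blocks[0][0, 0], blocks[0][0, 1]
        cov[2, 0], cov[2, 2] = blocks[0][1, 0], blocks[0][1, 1]
        cov[1, 1], cov[1, 3] = blocks[1][0, 0], blocks[1][0, 1]
        cov[3, 1], cov[3, 3] = blocks[1][1, 0], blocks[1][1, 1]
        cov *= inflation
        pts = np.array([p.theta for p in grid.points()], dtype=float)
        dens = multivariate_normal(mean=mean, cov=cov, allow_singular=True).pdf(pts)
        return dens / dens.sum()

    pe, ce = _fit_loglog(lengths, popstr_eps, sig(eps_sigma_log))
    pk, ck = _fit_loglog(lengths, popstr_kap, sig(kap_sigma_log))
    mean = np.array([pe[0], pe[1], pk[0], pk[1]])  # (log c_e, tau_e, log c_k, tau_k)
    cov = np.zeros((4, 4))
    cov[:2, :2] = ce
    cov[2:, 2:] = ck
    cov *= inflation

    coords = []
    for p in grid.points():
        c_eps, c_kap, tau_eps, tau_kap = p.anchors(empirical)
        coords.append([np.log(c_eps), tau_eps, np.log(c_kap), tau_kap])
    dens = multivariate_normal(mean=mean, cov=cov, allow_singular=True).pdf(
        np.array(coords)
    )
    total = dens.sum()
    if total <= 0:
        raise ValueError("prior mass underflowed on this grid")
    return dens / total


def fitted_loglog_params(lengths, rates, sigmas=None):
    """Best-fit (c at L=9, tau) of a power law to rate estimates (log-log)."""
    s = np.full(len(lengths), 0.2) if sigmas is None else np.asarray(sigmas, float)
    popt, _ = _fit_loglog(lengths, rates, s)
    return float(np.exp(popt[0])), float(popt[1])
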