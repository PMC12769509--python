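"""Analytic and numerical characterization of the equilibrium DRL.

Short repeats are governed by two-way substitution alone: the stationary
distribution is geometric with ratio mu/(mu+nu).  Long repeats obey a
continuum (Fokker-Planck-like) steady-state equation combining
length-dependent diffusion and drift from expansion/contraction with
non-local loss and gain from fission; fusion is negligible above ~10
units.  Three nested approximations are solved as linear boundary-value
problems:

  local_only             diffusion + drift                      (2nd order)
  local_plus_fission_out adds the -(nu + iota_L) L P_L loss     (2nd order)
  full_no_fusion         adds fission influx via an overall
                         length derivative and the zero-net-flux
                         selection                              (3rd order)

Solutions are constrained by the value of a reference distribution at
L1 = round(L*) and L2 = the integer bracketing L_trunc (plus L2 - 1 for
the third-order equation), the two lengths of theoretical interest:
where expansion-contraction bias flips, and where the expected count per
genome falls below one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .rates import ParamSpec, RateCurve, SubstitutionContextRates, L_ANCHOR

__all__ = [
    "SteadyStateDiagnostics",
    "geometric_short",
    "find_Lstar",
    "find_Ltrunc",
    "classify_regime",
    "solve_steady_ode",
    "PowerLawRates",
]

APPROXIMATIONS = ("local_only", "local_plus_fission_out", "full_no_fusion")

# regime thresholds in delta_tau, calibrated for multiplier m = 4
REGIME_THRESHOLDS = {"strong": 1.5, "moderate": 0.7}


@dataclass
class SteadyStateDiagnostics:
    L_star: float | None
    L_trunc: float | None
    delta_tau: float
    regime: str  # strong_contraction | moderate_contraction | weak_contraction
    #             | non_equilibrating


def geometric_short(
    subst: SubstitutionContextRates, anchor: tuple, L_max: int
) -> np.ndarray:
    """Short-repeat geometric law P(L) = C rho^L with rho = mu/(mu+nu).

    ``anchor = (L0, value)`` fixes the constant so the returned array
    equals ``value`` at L0 (normalization is relative to the long tail
    and cannot be fixed from the ratio alone).
    """
    mu, nu = subst.mu, subst.nu
    if mu + nu <= 0:
        raise ValueError("mu + nu must be positive")
    rho = mu / (mu + nu)
    L0, v0 = anchor
    L = np.arange(L_max + 1, dtype=float)
    out = v0 * rho ** (L - L0)
    out[0] = 0.0
    return out


class PowerLawRates:
    """Continuum per-target rates eps, kap, iota for power-law families.

    eps(L) = c_eps (L/9)^tau_eps etc.; accepts real or complex L so that
    derivatives can be taken by complex step.
    """

    def __init__(self, c_eps, c_kap, tau_eps, tau_kap, nu, iota_ratio=0.01):
        self.c_eps, self.c_kap = c_eps, c_kap
        self.tau_eps, self.tau_kap = tau_eps, tau_kap
        self.nu = nu
        self.iota_ratio = iota_ratio

    @classmethod
    def from_spec(cls, spec: ParamSpec, empirical, subst: SubstitutionContextRates):
        if spec.family == "pure_power":
            # re-anchor eps(L) = mu (L/lam)^tau at L = 9
            return cls(
                subst.mu * (L_ANCHOR / spec.lam_eps) ** spec.tau_eps,
                subst.nu * (L_ANCHOR / spec.lam_kap) ** spec.tau_kap,
                spec.tau_eps,
                spec.tau_kap,
                subst.nu,
            )
        c_eps, c_kap, tau_eps, tau_kap = spec.anchors(empirical)
        return cls(c_eps, c_kap, tau_eps, tau_kap, subst.nu)

    def eps(self, L):
        return self.c_eps * (L / L_ANCHOR) ** self.tau_eps

    def kap(self, L):
        return self.c_kap * (L / L_ANCHOR) ** self.tau_kap

    def iot(self, L):
        return self.iota_ratio * self.eps(L)


def find_Lstar(curve_or_rates, L_lo: int = 8) -> float | None:
    """Length where contraction overtakes expansion (kappa = epsilon).

    For :class:`PowerLawRates` the closed form 9 (c_eps/c_kap)^(1/dtau)
    is used; for a tabulated curve the crossing at L >= ``L_lo`` is
    interpolated log-linearly in log L (exact for power laws).  Returns
    None when the curves do not cross.
    """
    if isinstance(curve_or_rates, PowerLawRates):
        r = curve_or_rates
        dtau = r.tau_kap - r.tau_eps
        if dtau == 0 or r.c_eps <= 0 or r.c_kap <= 0:
            return None
        Ls = L_ANCHOR * (r.c_eps / r.c_kap) ** (1.0 / dtau)
        return float(Ls) if Ls >= L_lo else None
    curve: RateCurve = curve_or_rates
    eps, kap = curve.eps, curve.kap
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.log(eps) - np.log(kap)
    for L in range(max(L_lo, 1), curve.L_bound):
        if not (np.isfinite(f[L]) and np.isfinite(f[L + 1])):
            continue
        if f[L] == 0:
            return float(L)
        if f[L] > 0 >= f[L + 1]:
            x0, x1 = np.log(L), np.log(L + 1)
            t = f[L] / (f[L] - f[L + 1])
            return float(np.exp(x0 + t * (x1 - x0)))
    return None


def find_Ltrunc(counts, start: int | None = None) -> float | None:
    """Length where the expected genome-wide count first drops below one.

    Scans from the mode of the distribution; the crossing is interpolated
    in log-count between the bracketing integers.  Returns None if counts
    never fall below one within the modeled range (boundary marker).
    """
    arr = counts.to_array() if hasattr(counts, "to_array") else np.asarray(
        counts, dtype=float
    )
    if start is None:
        start = int(np.argmax(arr))
    for L in range(max(start, 1), len(arr) - 1):
        c0, c1 = arr[L], arr[L + 1]
        if c0 >= 1 > c1:
            if c1 <= 0:
                return float(L + 1)
            t = np.log(c0) / (np.log(c0) - np.log(c1))
            return float(L + t)
        if c0 < 1 and L == max(start, 1):
            return float(L)
    return None


def classify_regime(
    spec_or_rates,
    reference_counts=None,
    empirical=None,
    subst: SubstitutionContextRates | None = None,
    thresholds: dict | None = None,
) -> SteadyStateDiagnostics:
    """Dynamical regime from the exponent gap delta_tau = tau_kap - tau_eps.

    delta_tau <= 0 never equilibrates (asymptotically expansion-biased —
    including the symmetric edge case, which inherits expansion bias from
    the rates at L = 8); large positive gaps truncate the tail early
    (strong contraction), intermediate gaps are moderate, small positive
    gaps weak.  Default thresholds are calibrated at multiplier m = 4.
    """
    th = {**REGIME_THRESHOLDS, **(thresholds or {})}
    if isinstance(spec_or_rates, PowerLawRates):
        rates = spec_or_rates
        dtau = rates.tau_kap - rates.tau_eps
    else:
        spec = spec_or_rates
        dtau = spec.delta_tau
        if subst is None:
            from .rates import default_substitution_rates

            subst = default_substitution_rates()
        rates = PowerLawRates.from_spec(spec, empirical, subst)
    if dtau <= 0:
        regime = "non_equilibrating"
    elif dtau >= th["strong"]:
        regime = "strong_contraction"
    elif dtau >= th["moderate"]:
        regime = "moderate_contraction"
    else:
        regime = "weak_contraction"
    L_star = find_Lstar(rates) if dtau > 0 else None
    L_trunc = find_Ltrunc(reference_counts) if reference_counts is not None else None
    return SteadyStateDiagnostics(L_star, L_trunc, float(dtau), regime)


# ---------------------------------------------------------------------------
# numerical steady-state solutions
# ---------------------------------------------------------------------------


def _cstep(f, L, h=1e-30):
    """Derivative by complex step (exact to machine precision)."""
    return f(L + 1j * h).imag / h


class SolverError(RuntimeError):
    pass


def solve_steady_ode(
    rates: PowerLawRates,
    approximation: str,
    constraints: dict,
    L_eval=None,
    rtol: float = 1e-10,
):
    """Solve one steady-state approximation as a linear BVP by shooting.

    ``constraints`` maps length -> reference P value: two entries for the
    second-order equations, three for ``full_no_fusion`` (by convention
    L1 = round(L*), L2 ~ L_trunc, L3 = L2 - 1).  The equations are linear
    in P, so the boundary problem is solved exactly by superposing
    fundamental solutions integrated from the left constraint.

    Returns (L_eval, P) with P evaluated at ``L_eval`` (default: integer
    lengths spanning the constraint interval; points outside it are
    reached by integrating the same fundamental system outward, within
    ``L_lo``..``L_hi``).
    """
    if approximation not in APPROXIMATIONS:
        raise ValueError(f"approximation must be one of {APPROXIMATIONS}")
    order = 3 if approximation == "full_no_fusion" else 2
    pts = sorted(constraints.items())
    if len(pts) != order:
        raise SolverError(
            f"{approximation} needs {order} constraints, got {len(pts)}"
        )
    Ls = [p[0] for p in pts]
    Ps = [p[1] for p in pts]
    La, Lb = Ls[0], Ls[-1]

    def a_of(L):
        return 0.5 * (rates.eps(L) + rates.kap(L)) * L

    def f1(L):  # drift / diffusion coefficient ratio
        return (rates.eps(L) - rates.kap(L)) * L / a_of(L)

    def f2(L):  # fission-out / diffusion
        return (rates.nu + rates.iot(L)) * L / a_of(L)

    def f3(L):  # fission-in source / diffusion
        return 2.0 * (rates.nu + rates.iot(L)) / a_of(L)

    use_g = approximation != "local_only"

    if order == 2:

        def rhs(L, y):
            u, up = y
            upp = _cstep(f1, L) * u + f1(L) * up
            if use_g:
                upp += f2(L) * u
            return [up, upp]

    else:
        # f1, f2 are smooth combinations of power laws; the second
        # derivative differences two complex-step first derivatives,
        # which keeps the right-hand side smooth enough for tight
        # integrator tolerances
        def d2(f, L, h=1e-5):
            return (_cstep(f, L + h) - _cstep(f, L - h)) / (2 * h)

        def rhs(L, y):
            u, up, upp = y
            uppp = (
                d2(f1, L) * u
                + 2 * _cstep(f1, L) * up
                + f1(L) * upp
                + _cstep(f2, L) * u
                + f2(L) * up
                + f3(L) * u
            )
            return [up, upp, uppp]

    # work in units of the left-constraint value so u is O(1)
    scale = a_of(La) * Ps[0]
    if scale <= 0:
        raise SolverError("left constraint must be positive")
    if order == 2:
        ics = [[1.0, 0.0], [0.0, 1.0]]
    else:
        ics = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    if L_eval is None:
        L_eval = np.arange(int(np.ceil(La)), int(np.floor(Lb)) + 1, dtype=float)
    L_eval = np.asarray(L_eval, dtype=float)
    L_lo = min(float(L_eval.min()), La)
    L_hi = max(float(L_eval.max()), Lb)

    def integrate(ic):
        sols_dir = []
        for target in (L_lo, L_hi):
            if target == La:
                sols_dir.append(None)
                continue
            sol = solve_ivp(
                rhs,
                (La, target),
                ic,
                method="DOP853",
                rtol=rtol,
                atol=1e-14,
                dense_output=True,
            )
            if not sol.success:
                raise SolverError(f"integration failed: {sol.message}")
            sols_dir.append(sol)
        back, fwd = sols_dir

        def u_of(L):
            L = np.asarray(L, dtype=float)
            out = np.empty_like(L)
            below = L < La
            if below.any():
                out[below] = back.sol(L[below])[0]
            if (~below).any():
                out[~below] = fwd.sol(L[~below])[0]
            return out

        return u_of

    sols = [integrate(ic) for ic in ics]

    # superpose to satisfy the remaining constraints
    targets = []
    rows = []
    for Lc, Pc in zip(Ls[1:], Ps[1:]):
        Lc_arr = np.array([float(Lc)])
        targets.append(a_of(Lc) * Pc / scale - sols[0](Lc_arr)[0])
        rows.append([s(Lc_arr)[0] for s in sols[1:]])
    coef = np.linalg.solve(np.array(rows), np.array(targets))

    u = sols[0](L_eval) + sum(c * s(L_eval) for c, s in zip(coef, sols[1:]))
    P = u * scale / a_of(L_eval)
    # constraint reproduction check
    for Lc, Pc in zip(Ls, Ps):
        Lc_arr = np.array([float(Lc)])
        uc = sols[0](Lc_arr)[0] + sum(
            c * s(Lc_arr)[0] for c, s in zip(coef, sols[1:])
        )
        if Pc != 0 and abs(uc * scale / a_of(Lc) - Pc) > 1e-6 * abs(Pc):
            raise SolverError("constraints not reproduced; ill-conditioned shoot")
    return L_eval, P
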