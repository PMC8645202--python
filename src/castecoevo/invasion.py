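"""Rare-mutant invasion analysis for the caste-determination / hybridization model.

A rare mutant allele (additive, expressed as the mean of the two allelic
values in diploid carriers) segregates in two carrier classes: heterozygous
queens and hemizygous males.  Its growth is governed by a 2x2 transmission
matrix over (queen, male) classes, normalized by the resident's class-
specific success so the resident allele is exactly neutral (spectral radius
1).  Males have no sons under arrhenotoky, so the male->male entry is zero
and the leading eigenvalue has the closed form

    lambda = (a_QQ + sqrt(a_QQ**2 + 4 * a_QM * a_MQ)) / 2.

Entry construction follows the life cycle: a carrier queen's mate
composition is binomial in her own eta phenotype; she transmits the allele
to half her fertilized daughters, all her parthenogenetic daughters and
half her sons; a carrier male sires heterozygous daughters when drawn as a
conspecific mate.  The omega-locus is expressed in each larva's own
genotype (carrier larvae use the heterozygote phenotype; colony workforce
uses the within-brood mixture), the eta-locus in the mating queen.  All
outputs are weighted by the natal colony's survival weight (workforce**gamma).

Selection gradients and Hessians are central finite differences of
log(lambda) with respect to mutant *allelic* values; the trait-substitution
dynamics follow the gradient field with equal mutational variance on both
traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .colony import INFINITE, ModelParams, TraitPair

__all__ = [
    "ResidentInviableError",
    "MutantSpec",
    "TransmissionMatrix",
    "SelectionGradient",
    "SingularPoint",
    "Trajectory",
    "RegionMap",
    "WorkerLossState",
    "transmission_matrix",
    "invasion_fitness",
    "log_invasion_fitness",
    "selection_gradient",
    "mutant_hessian",
    "gradient_jacobian",
    "integrate_trajectory",
    "omega_root_at_eta",
    "find_singular_points",
    "worker_loss_stable",
    "eta_zero_unstable",
    "classify_region",
]

#: finite-difference step on allelic values (gradient)
GRAD_STEP = 1e-4
#: finite-difference step on allelic values (Hessian)
HESS_STEP = 1e-3
#: numerical floor below which the resident is declared inviable
_VIABILITY_FLOOR = 1e-300


class ResidentInviableError(ValueError):
    """The resident population has zero reproductive output through queens or males."""


@dataclass(frozen=True)
class MutantSpec:
    """A mutant allele: which locus it affects and its allelic deviation(s).

    ``delta`` is the deviation of the mutant allelic value from the resident
    allelic value; carrier phenotypes deviate by ``delta / 2`` (additive
    expression, heterozygote midway).  For ``locus="both"`` pass a pair
    ``(d_omega, d_eta)``.
    """

    locus: Literal["omega", "eta", "both"]
    delta: float | tuple[float, float]

    def deviations(self) -> tuple[float, float]:
        if self.locus == "omega":
            return float(self.delta), 0.0
        if self.locus == "eta":
            return 0.0, float(self.delta)
        d_o, d_e = self.delta  # type: ignore[misc]
        return float(d_o), float(d_e)


@dataclass(frozen=True)
class TransmissionMatrix:
    """Normalized mutant-copy flow between (queen, male) carrier classes."""

    queen_from_queen: float
    queen_from_male: float
    male_from_queen: float
    male_from_male: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.queen_from_queen, self.queen_from_male],
                [self.male_from_queen, self.male_from_male],
            ]
        )

    def spectral_radius(self) -> float:
        a, b, cc = self.queen_from_queen, self.queen_from_male, self.male_from_queen
        return 0.5 * (a + math.sqrt(a * a + 4 * b * cc))


class _Machine:
    """Precomputed resident-side quantities for fast entry evaluation."""

    def __init__(self, resident: TraitPair, params: ModelParams):
        self.res = resident
        self.p = params
        om, et = resident.omega, resident.eta
        p = params
        if p.infinite_m:
            W = p.f * (p.e * (1 - p.c) * et + (1 - p.c) * (1 - et) * om + p.c * om)
            S = W**p.gamma
            self.Qbar = p.f * ((1 - p.c) * (1 - et) + p.c) * (1 - om) * S
            self.Sres = S
        else:
            m = int(p.m)
            k = np.arange(m + 1)
            self._k = k
            self._binom_m = np.array([math.comb(m, int(i)) for i in k], dtype=float)
            self._binom_m1 = np.array([math.comb(m - 1, int(i)) for i in range(m)], dtype=float)
            w_res = self._binom_m * (1 - et) ** k * et ** (m - k)
            W = p.f * (p.e * (1 - p.c) * (m - k) / m + (1 - p.c) * (k / m) * om + p.c * om)
            S = W**p.gamma
            q_res = p.f * ((1 - p.c) * (k / m) + p.c) * (1 - om)
            self.Qbar = float(w_res @ (q_res * S))
            self.Mbar = float(w_res @ S)
        if not np.isfinite(self.Qbar) or self.Qbar <= _VIABILITY_FLOOR:
            raise ResidentInviableError(
                f"resident (omega={om}, eta={et}) produces no successful queens "
                f"under {params}"
            )
        if not p.infinite_m and (not np.isfinite(self.Mbar) or self.Mbar <= _VIABILITY_FLOOR):
            raise ResidentInviableError(
                f"resident (omega={om}, eta={et}) produces no successful males "
                f"under {params}"
            )

    def entries(
        self,
        d_omega_caste: float = 0.0,
        d_omega_work: float = 0.0,
        d_eta: float = 0.0,
    ) -> TransmissionMatrix:
        """Transmission-matrix entries for a mutant with given allelic deviations.

        The omega deviation is split into two expression slots so the kin
        decomposition can perturb them independently: ``d_omega_caste``
        enters the carrier larva's own caste decision, ``d_omega_work`` its
        contribution to colony workforce.  Ordinary invasion analysis sets
        them equal.
        """
        om, et = self.res.omega, self.res.eta
        p = self.p
        oc = om + d_omega_caste / 2  # carrier larva caste phenotype
        ow = om + d_omega_work / 2  # carrier larva work phenotype
        ex = et + d_eta / 2  # carrier queen mating phenotype
        if p.infinite_m:
            W_mut = p.f * (
                p.e * (1 - p.c) * ex + (1 - p.c) * (1 - ex) * (ow + om) / 2 + p.c * ow
            )
            S_mut = W_mut**p.gamma
            a_qq = p.f * ((1 - p.c) * (1 - ex) * 0.5 + p.c) * (1 - oc) * S_mut / self.Qbar
            a_mq = 0.5 * S_mut / self.Sres
            a_qm = (1 - et) * p.f * (1 - p.c) * (1 - oc) * self.Sres / self.Qbar
            return TransmissionMatrix(a_qq, a_qm, a_mq)
        m = int(p.m)
        k = self._k
        w_mut = self._binom_m * (1 - ex) ** k * ex ** (m - k)
        W_mut = p.f * (
            p.e * (1 - p.c) * (m - k) / m
            + (1 - p.c) * (k / m) * (ow + om) / 2
            + p.c * ow
        )
        S_mut = W_mut**p.gamma
        d_q = p.f * ((1 - p.c) * (k / m) * 0.5 + p.c) * (1 - oc)
        a_qq = float(w_mut @ (d_q * S_mut)) / self.Qbar
        a_mq = 0.5 * float(w_mut @ S_mut) / self.Mbar
        # carrier father: one conspecific slot is his, the other m-1 slots of a
        # resident queen are conspecific with probability 1 - eta
        j = np.arange(m)
        w_f = self._binom_m1 * (1 - et) ** j * et ** (m - 1 - j)
        kf = 1 + j
        W_f = p.f * (
            p.e * (1 - p.c) * (m - kf) / m
            + (1 - p.c) * ((kf - 1) * om + ow) / m
            + p.c * om
        )
        a_qm = (
            (1 - et)
            * float(w_f @ (p.f * (1 - p.c) * (1 - oc) * W_f**p.gamma))
            / self.Qbar
        )
        return TransmissionMatrix(a_qq, a_qm, a_mq)

    def log_lambda(self, d_omega: float = 0.0, d_eta: float = 0.0) -> float:
        tm = self.entries(d_omega, d_omega, d_eta)
        return math.log(tm.spectral_radius())


def transmission_matrix(
    resident: TraitPair, mutant: MutantSpec, params: ModelParams
) -> TransmissionMatrix:
    """The normalized carrier-class transmission matrix of a rare mutant."""
    d_o, d_e = mutant.deviations()
    return _Machine(resident, params).entries(d_o, d_o, d_e)


def invasion_fitness(resident: TraitPair, mutant: MutantSpec, params: ModelParams) -> float:
    """Asymptotic growth rate (spectral radius) of a rare mutant allele."""
    return transmission_matrix(resident, mutant, params).spectral_radius()


def log_invasion_fitness(
    resident: TraitPair, params: ModelParams, d_omega: float = 0.0, d_eta: float = 0.0
) -> float:
    return _Machine(resident, params).log_lambda(d_omega, d_eta)


@dataclass(frozen=True)
class SelectionGradient:
    """First (and optionally second) derivatives of log invasion fitness.

    Derivatives are taken with respect to the mutant allelic values at the
    resident.  At a boundary of the feasible trait space the one-sided
    (feasible-direction) derivative is reported.
    """

    g_omega: float
    g_eta: float
    hessian: np.ndarray | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.g_omega, self.g_eta])


def _fd_derivative(L, x: float, h: float) -> float:
    """Finite difference of L at deviation 0, one-sided at bounds.

    ``x`` is the resident trait value; the stencil on *allelic* deviations
    keeps carrier phenotypes (x +- h/2) inside [0, 1] by switching to
    one-sided differences near the boundary (L(0) = 0 by neutrality).
    Interior stencils are Richardson-extrapolated central differences
    (fourth order), so truncation is negligible against the 1e-4 step.
    """
    if x >= h and x <= 1 - h:
        d1 = (L(h) - L(-h)) / (2 * h)
        d2 = (L(h / 2) - L(-h / 2)) / h
        return (4 * d2 - d1) / 3
    if x < h:  # forward, feasible direction +
        return (4 * L(h) - L(2 * h)) / (2 * h)
    return -(4 * L(-h) - L(-2 * h)) / (2 * h)  # backward


def selection_gradient(
    resident: TraitPair,
    params: ModelParams,
    with_hessian: bool = False,
    step: float = GRAD_STEP,
) -> SelectionGradient:
    """Selection gradient (and optionally mutant Hessian) at a resident."""
    mach = _Machine(resident, params)
    g_o = _fd_derivative(lambda d: mach.log_lambda(d, 0.0), resident.omega, step)
    g_e = _fd_derivative(lambda d: mach.log_lambda(0.0, d), resident.eta, step)
    hess = mutant_hessian(resident, params, machine=mach) if with_hessian else None
    return SelectionGradient(g_o, g_e, hess)


def mutant_hessian(
    resident: TraitPair,
    params: ModelParams,
    step: float = HESS_STEP,
    machine: "_Machine | None" = None,
) -> np.ndarray:
    """Second derivatives of log invasion fitness in mutant allelic directions.

    Includes the mixed (correlational-selection) term.  Uses central second
    differences; at a singular point log(lambda)(0) = 0 so the diagonal
    terms reduce to (L(h) + L(-h)) / h**2.
    """
    mach = machine or _Machine(resident, params)
    h = step
    L = mach.log_lambda
    h_oo = (L(h, 0.0) + L(-h, 0.0)) / h**2
    h_ee = (L(0.0, h) + L(0.0, -h)) / h**2
    h_oe = (L(h, h) + L(-h, -h) - L(h, -h) - L(-h, h)) / (4 * h**2)
    return np.array([[h_oo, h_oe], [h_oe, h_ee]])


def gradient_jacobian(
    resident: TraitPair, params: ModelParams, step: float = 1e-4
) -> np.ndarray:
    """Jacobian of the gradient field with respect to the resident position."""
    x = resident.as_array()
    J = np.zeros((2, 2))
    for j in range(2):
        h = step
        lo = max(x[j] - h, 0.0)
        hi = min(x[j] + h, 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j], xm[j] = hi, lo
        gp = selection_gradient(TraitPair(*xp), params).as_array()
        gm = selection_gradient(TraitPair(*xm), params).as_array()
        J[:, j] = (gp - gm) / (hi - lo)
    return J


@dataclass(frozen=True)
class SingularPoint:
    """A zero of the selection-gradient field with its stability classification."""

    location: TraitPair
    convergence_stable: bool
    ess: bool
    label: Literal["repellor", "attractor-ESS", "attractor-branching", "boundary-state"]
    jacobian_eigenvalues: tuple[complex, complex] | None = None
    hessian_eigenvalues: tuple[float, float] | None = None


@dataclass
class Trajectory:
    """An Euler path of the trait-substitution dynamics in the unit square."""

    states: np.ndarray  # (n, 2) of (omega, eta)
    termination: Literal["converged", "boundary", "step-limit", "inviable"]
    step: float

    @property
    def endpoint(self) -> TraitPair:
        return TraitPair(*self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": np.arange(len(self.states)), "omega": self.states[:, 0], "eta": self.states[:, 1]}
        )


def _projected_gradient(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    gp = g.copy()
    for j in range(2):
        if (x[j] <= 0.0 and g[j] < 0) or (x[j] >= 1.0 and g[j] > 0):
            gp[j] = 0.0
    return gp


def integrate_trajectory(
    init: TraitPair,
    params: ModelParams,
    step: float = 1e-2,
    max_steps: int = 100_000,
    tol: float = 1e-6,
) -> Trajectory:
    """Euler integration of the coupled trait dynamics along the gradient field.

    Mutational input is assumed unbiased with equal variance on both traits,
    so the substitution dynamics follow the raw gradient direction up to a
    positive constant absorbed into the step size.  Traits are clipped to
    [0, 1]; convergence is declared when the gradient, projected on feasible
    directions at the boundary, falls below ``tol`` in norm.
    """
    x = init.as_array().astype(float)
    states = [x.copy()]
    termination = "step-limit"
    for _ in range(max_steps):
        try:
            g = selection_gradient(TraitPair(*x), params).as_array()
        except ResidentInviableError:
            termination = "inviable"
            break
        gp = _projected_gradient(x, g)
        if np.linalg.norm(gp) < tol:
            termination = "boundary" if (x <= 0).any() or (x >= 1).any() else "converged"
            break
        x = np.clip(x + step * g, 0.0, 1.0)
        states.append(x.copy())
    return Trajectory(np.array(states), termination, step)


def omega_root_at_eta(
    params: ModelParams, eta: float, bracket: tuple[float, float] = (1e-6, 1 - 1e-6)
) -> float | None:
    """Root of the omega-gradient at fixed eta, or None if omega is driven to 0.

    This is the selected caste-determination value for a fixed level of
    hybridization; for infinite m, c = 0, gamma = 1 it coincides with the
    closed-form equilibrium.
    """

    def g(o: float) -> float:
        return selection_gradient(TraitPair(o, eta), params).g_omega

    lo, hi = bracket
    try:
        g_lo, g_hi = g(lo), g(hi)
    except ResidentInviableError:
        return None
    if g_lo <= 0:
        return None  # selection pushes omega to the lower boundary
    if g_hi >= 0:
        return 1.0
    return float(optimize.brentq(g, lo, hi, xtol=1e-12))


def _dedupe(points: list[np.ndarray], tol: float = 1e-4) -> list[np.ndarray]:
    kept: list[np.ndarray] = []
    for x in points:
        if not any(np.max(np.abs(x - y)) < tol for y in kept):
            kept.append(x)
    return kept


def find_singular_points(
    params: ModelParams,
    n_starts: int = 5,
    include_boundary: bool = True,
    interior_margin: float = 5e-3,
    grad_tol: float = 1e-8,
) -> list[SingularPoint]:
    """Locate and classify zeros of the selection-gradient field.

    Interior singular points are found by multistart root-finding from an
    ``n_starts x n_starts`` grid; each is classified for convergence
    stability (Jacobian eigenvalues) and evolutionary stability (mutant
    Hessian, including the correlational term).  Boundary states -- the
    selected omega at eta = 0 and the worker-loss state (omega = 0, selected
    eta) -- are appended with label ``boundary-state``.
    """

    def fun(x: np.ndarray) -> np.ndarray:
        o = float(np.clip(x[0], 1e-6, 1 - 1e-6))
        t = float(np.clip(x[1], 1e-6, 1 - 1e-6))
        try:
            return selection_gradient(TraitPair(o, t), params).as_array()
        except ResidentInviableError:
            return np.array([1e6, 1e6])

    starts = np.linspace(0.1, 0.9, n_starts)
    roots: list[np.ndarray] = []
    for o0 in starts:
        for e0 in starts:
            sol = optimize.root(fun, np.array([o0, e0]), method="hybr", tol=1e-12)
            if not sol.success:
                continue
            x = np.clip(sol.x, 0.0, 1.0)
            if np.max(np.abs(fun(x))) > grad_tol:
                continue
            if not (
                interior_margin < x[0] < 1 - interior_margin
                and interior_margin < x[1] < 1 - interior_margin
            ):
                continue
            roots.append(x)
    out: list[SingularPoint] = []
    for x in _dedupe(roots):
        loc = TraitPair(*x)
        J = gradient_jacobian(loc, params)
        jeig = np.linalg.eigvals(J)
        cs = bool(np.all(jeig.real < 0))
        H = mutant_hessian(loc, params)
        heig = np.linalg.eigvalsh(H)
        ess = bool(heig.max() <= 1e-6)
        if not cs:
            label = "repellor"
        elif ess:
            label = "attractor-ESS"
        else:
            label = "attractor-branching"
        out.append(
            SingularPoint(
                loc, cs, ess, label,
                tuple(jeig), tuple(heig),
            )
        )
    if include_boundary:
        out.extend(_boundary_states(params))
    return out


def _boundary_states(params: ModelParams) -> list[SingularPoint]:
    states: list[SingularPoint] = []
    # hybridization-avoidance state: eta = 0, omega at its selected value
    try:
        o0 = omega_root_at_eta(params, 0.0)
    except ResidentInviableError:
        o0 = None
    if o0 is not None and 0 < o0 < 1:
        loc = TraitPair(o0, 0.0)
        g_eta = selection_gradient(loc, params).g_eta
        cs = g_eta < 0  # feasible direction is eta > 0
        states.append(SingularPoint(loc, cs, cs, "boundary-state"))
    # worker-loss state: omega = 0, eta at its selected value
    wl = worker_loss_stable(params)
    if wl.viable and wl.eta_hat is not None:
        loc = TraitPair(0.0, wl.eta_hat)
        states.append(SingularPoint(loc, wl.stable, wl.stable, "boundary-state"))
    return states


@dataclass(frozen=True)
class WorkerLossState:
    """The hybridization level selected at complete worker loss, and its stability."""

    eta_hat: float | None
    stable: bool
    viable: bool


def worker_loss_stable(params: ModelParams, eta_lo: float = 2e-3) -> WorkerLossState:
    """Solve for the eta selected when the population is fixed at omega = 0.

    Returns the zero of the eta-gradient restricted to omega = 0 (or the
    boundary eta = 1 when selection pushes hybridization all the way up),
    and whether that worker-loss state resists invasion by omega-mutants
    (one-sided gradient in the feasible direction omega > 0).
    """

    def g_eta(x: float) -> float:
        return selection_gradient(TraitPair(0.0, x), params).g_eta

    hi = 1.0
    try:
        g_hi = g_eta(hi)
    except ResidentInviableError:
        hi = 1 - 1e-6
        try:
            g_hi = g_eta(hi)
        except ResidentInviableError:
            return WorkerLossState(None, False, False)
    if g_hi >= 0:
        eta_hat = 1.0
    else:
        try:
            g_lo = g_eta(eta_lo)
        except ResidentInviableError:
            return WorkerLossState(None, False, False)
        if g_lo <= 0:
            # no hybridization is selected at worker loss: the state collapses
            return WorkerLossState(None, False, True)
        eta_hat = float(optimize.brentq(g_eta, eta_lo, hi, xtol=1e-10))
    try:
        g_om = selection_gradient(TraitPair(0.0, eta_hat), params).g_omega
    except ResidentInviableError:
        return WorkerLossState(eta_hat, False, False)
    return WorkerLossState(eta_hat, bool(g_om <= 1e-9), True)


def eta_zero_unstable(params: ModelParams) -> bool:
    """Can hybridization invade a population that does not hybridize?

    Evaluates the one-sided eta-gradient at (omega = selected value given
    eta = 0, eta = 0).  With worthless hybrids (e = 0) hybridization only
    destroys queen production and can never invade.
    """
    if params.e == 0:
        return False
    try:
        o0 = omega_root_at_eta(params, 0.0)
    except ResidentInviableError:
        return False
    if o0 is None or not 0 < o0 <= 1:
        return False
    o0 = min(o0, 1 - 1e-9)
    return selection_gradient(TraitPair(o0, 0.0), params).g_eta > 0


@dataclass
class RegionMap:
    """Per-cell outcome labels over a two-parameter grid."""

    axis_names: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    labels: np.ndarray  # (len(axis1), len(axis2)) of str

    LABELS = (
        "plasticity-maintained",
        "worker-loss-always",
        "bistable",
        "internal-attractor",
    )

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = self.axis_names
        v1, v2 = self.axis_values
        rows = [
            {a1: x1, a2: x2, "outcome": self.labels[i, j]}
            for i, x1 in enumerate(v1)
            for j, x2 in enumerate(v2)
        ]
        return pd.DataFrame(rows)


def _confirm_bistable(params: ModelParams, n: int = 5) -> bool:
    """Check that both endpoints are reached from an n x n grid of initial states."""
    seen: set[str] = set()
    for o0 in np.linspace(0.05, 0.95, n):
        for e0 in np.linspace(0.05, 0.95, n):
            try:
                tr = integrate_trajectory(
                    TraitPair(o0, e0), params, step=5e-2, max_steps=4000, tol=1e-4
                )
            except ResidentInviableError:
                continue
            end = tr.endpoint
            if end.omega < 0.05:
                seen.add("worker-loss")
            elif end.eta < 0.05:
                seen.add("avoidance")
            if len(seen) == 2:
                return True
    return len(seen) == 2


def classify_cell(params: ModelParams, confirm_bistable: bool = False) -> str:
    """Outcome label for one parameter combination.

    Priority: an interior convergence-stable point wins (partial
    hybridization with retained plasticity); otherwise worker-loss-always
    when the worker-loss state is uninvadable *and* eta = 0 is unstable;
    bistable when worker-loss is uninvadable but eta = 0 is stable;
    plasticity-maintained otherwise.
    """
    try:
        interior = [
            s
            for s in find_singular_points(params, n_starts=4, include_boundary=False)
            if s.convergence_stable
        ]
    except ResidentInviableError:
        interior = []
    if interior:
        return "internal-attractor"
    wl = worker_loss_stable(params)
    unstable0 = eta_zero_unstable(params)
    if wl.viable and wl.stable:
        if unstable0:
            return "worker-loss-always"
        if confirm_bistable and not _confirm_bistable(params):
            return "plasticity-maintained"
        return "bistable"
    return "plasticity-maintained"


def classify_region(
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    base: ModelParams,
    confirm_bistable: bool = False,
) -> RegionMap:
    """Classify selection outcomes over a grid of two scenario axes.

    ``axis1`` / ``axis2`` are ``(field_name, values)`` pairs naming
    :class:`ModelParams` fields (e.g. ``("m", [1, 2, 4]), ("e", grid)``).
    """
    from dataclasses import replace

    name1, vals1 = axis1
    name2, vals2 = axis2
    v1 = np.asarray(list(vals1), dtype=float)
    v2 = np.asarray(list(vals2), dtype=float)
    labels = np.empty((len(v1), len(v2)), dtype=object)
    for i, x1 in enumerate(v1):
        for j, x2 in enumerate(v2):
            kw = {name1: x1, name2: x2}
            if "m" in kw and not math.isinf(kw["m"]):
                kw["m"] = int(round(kw["m"]))
            params = replace(base, **kw)
            labels[i, j] = classify_cell(params, confirm_bistable=confirm_bistable)
    return RegionMap((name1, name2), (v1, v2), labels)
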