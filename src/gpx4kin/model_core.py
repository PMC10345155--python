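"""Core kinetic model of GPX4 acting on liposomal membranes.

The model couples reversible docking of the reduced enzyme onto the
membrane (association constant ``k_A``, dissociation constant ``k_B``)
with the two redox half-reactions of the peroxidase cycle taking place on
the membrane surface: oxidation of the bound enzyme by a phospholipid
hydroperoxide (``k_1s``) and its two-electron re-reduction by GSH
(``k_2s``, lumping the two consecutive GSH reactions into a single
termolecular step, hence the [GSH]² dependence).  Five pools are
propagated in bulk-equivalent molarity:

    E_red   reduced enzyme free in solution
    EM      membrane-bound reduced enzyme
    EoxM    membrane-bound oxidised enzyme
    SLPCOOH phospholipid hydroperoxide substrate
    GSSG    glutathione disulfide produced

The membrane phospholipid ``M`` is a binding platform, not a consumed
substrate, so it enters as a constant.  GSH is held constant by default
because the assay regenerates it enzymatically (glutathione reductase +
NADPH); the NADPH consumed by that regeneration is what the
spectrophotometer sees at 340 nm, one NADPH per GSSG, which is how a
trajectory maps to an absorbance trace.

The module also carries the micellar-phase ping-pong (Dalziel) rate law
used for mixed-micelle substrates, and the algebraic bridge between a
two-step SPR binding scheme and the one-step (k_A, k_B) docking reaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError

__all__ = [
    "KineticParameters",
    "ReactionConditions",
    "StateVector",
    "StateDerivatives",
    "Trajectory",
    "AbsorbanceTrace",
    "DalzielCoefficients",
    "SPRTwoStepConstants",
    "rhs",
    "simulate",
    "absorbance_from_trajectory",
    "micellar_rate",
    "simulate_micellar_progress",
    "spr_to_onestep",
    "k2s_from_dalziel",
    "classify_rate_shape",
]

#: Molar extinction coefficient of NADPH at 340 nm, M^-1 cm^-1.
EPSILON_340_NADPH = 6220.0

_PARAM_NAMES = ("k_A", "k_B", "k_1s", "k_2s")


@dataclass(frozen=True)
class KineticParameters:
    """The four constants of the interfacial model.

    Parameters
    ----------
    k_A : float
        Enzyme–membrane association rate constant, M⁻¹s⁻¹.
    k_B : float
        Enzyme–membrane dissociation rate constant, s⁻¹.
    k_1s : float
        Surface oxidative rate constant, M⁻¹s⁻¹.
    k_2s : float
        Surface reductive rate constant (lumped two-GSH step), M⁻²s⁻¹.
    """

    k_A: float
    k_B: float
    k_1s: float
    k_2s: float

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        """Return (k_A, k_B, k_1s, k_2s) as a float array."""
        return np.array([self.k_A, self.k_B, self.k_1s, self.k_2s], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "KineticParameters":
        k_a, k_b, k_1s, k_2s = (float(v) for v in values)
        return cls(k_a, k_b, k_1s, k_2s)


@dataclass(frozen=True)
class ReactionConditions:
    """Assay composition and optical constants for one reaction.

    Concentrations are bulk molar.  ``M_total`` is the concentration of
    *all* phospholipids in liposomal form, irrespective of cardiolipin
    content; ``tocl_fraction`` is carried as metadata only — the model
    expresses cardiolipin effects entirely through the fitted rate
    constants.
    """

    E_total: float
    M_total: float
    ROOH_0: float
    GSH: float = 2.5e-3
    NADPH_0: float = 1.6e-4
    tocl_fraction: float = 0.0
    epsilon_340: float = EPSILON_340_NADPH
    path_length: float = 1.0
    gsh_constant: bool = True

    def __post_init__(self) -> None:
        for name in ("E_total", "M_total", "ROOH_0", "GSH", "NADPH_0"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0):
                raise DomainError(f"{name} must be non-negative, got {value!r}")
        if not 0.0 <= self.tocl_fraction <= 1.0:
            raise DomainError(
                f"tocl_fraction must lie in [0, 1], got {self.tocl_fraction!r}"
            )
        if self.epsilon_340 <= 0 or self.path_length <= 0:
            raise DomainError("epsilon_340 and path_length must be positive")
        if self.ROOH_0 > self.NADPH_0:
            warnings.warn(
                "ROOH_0 exceeds NADPH_0: the coupled NADPH readout will be "
                "truncated before the hydroperoxide is exhausted",
                stacklevel=2,
            )


class StateDerivatives(NamedTuple):
    """Time derivatives of the five pools, M/s."""

    dE_red: float
    dEM: float
    dEoxM: float
    dSLPCOOH: float
    dGSSG: float


@dataclass(frozen=True)
class StateVector:
    """Instantaneous state of the five pools, bulk molar."""

    E_red: float
    EM: float
    EoxM: float
    SLPCOOH: float
    GSSG: float

    _NEG_TOL = 1e-12

    def __post_init__(self) -> None:
        for name in ("E_red", "EM", "EoxM", "SLPCOOH", "GSSG"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < -self._NEG_TOL:
                raise DomainError(
                    f"state component {name} = {value!r} is negative beyond tolerance"
                )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.E_red, self.EM, self.EoxM, self.SLPCOOH, self.GSSG], dtype=float
        )


def _rhs_array(y: np.ndarray, p: KineticParameters, m_total: float, gsh: float) -> np.ndarray:
    e_red, em, eox, rooh, _ = y
    bind = p.k_A * e_red * m_total
    unbind = p.k_B * em
    oxidise = p.k_1s * em * rooh
    reduce_ = p.k_2s * eox * gsh * gsh
    return np.array(
        [
            -bind + unbind,
            bind - unbind - oxidise + reduce_,
            oxidise - reduce_,
            -oxidise,
            reduce_,
        ]
    )


def rhs(
    state: StateVector, params: KineticParameters, cond: ReactionConditions
) -> StateDerivatives:
    """Right-hand side of the interfacial kinetic model.

    Mass-action rates of the three reactions — docking/undocking
    (k_A, k_B), surface oxidation (k_1s) and lumped two-GSH reduction
    (k_2s·[GSH]²) — assembled into per-pool derivatives.  Enzyme pools
    sum to a constant by construction, and every oxidising equivalent
    removed from SLPCOOH appears either as EoxM or as GSSG.
    """
    dy = _rhs_array(state.as_array(), params, cond.M_total, cond.GSH)
    return StateDerivatives(*dy)


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of the five pools under fixed conditions."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 5), columns E_red, EM, EoxM, SLPCOOH, GSSG
    conditions: ReactionConditions
    params: KineticParameters
    gsh: np.ndarray | None = None  # populated only in depleting-GSH mode

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)
        if states.shape != (times.size, 5):
            raise DomainError("states must have shape (len(times), 5)")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")

    @property
    def E_red(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def EM(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def EoxM(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def SLPCOOH(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def GSSG(self) -> np.ndarray:
        return self.states[:, 4]

    def gssg_rate(self) -> np.ndarray:
        """Instantaneous GSSG production rate d[GSSG]/dt, M/s."""
        gsh = self.gsh if self.gsh is not None else self.conditions.GSH
        return self.params.k_2s * self.EoxM * np.asarray(gsh) ** 2


@dataclass(frozen=True)
class AbsorbanceTrace:
    """A (time, A340) series with the conditions it was recorded under."""

    times: np.ndarray
    a340: np.ndarray
    conditions: ReactionConditions
    label: str = ""
    is_blank: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        a340 = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "a340", a340)
        if times.shape != a340.shape:
            raise DomainError("times and a340 must have the same length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DalzielCoefficients:
    """Dalziel coefficients of the ping-pong rate law E/v = φ₀ + φ₁/[ROOH] + φ₂/[GSH].

    φ₁ and φ₂ are the reciprocals of the apparent second-order rate
    constants of the oxidative (k₁) and cumulative reductive (k'₂) steps;
    φ₀ is the reciprocal turnover number, typically 0 for selenoperoxidases.
    """

    phi0: float
    phi1: float
    phi2: float
    rms_residual: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (self.phi1 > 0 and self.phi2 > 0):
            raise DomainError("phi1 and phi2 must be strictly positive")
        if not math.isfinite(self.phi0):
            raise DomainError("phi0 must be finite")

    @property
    def k1(self) -> float:
        """Apparent oxidative rate constant 1/φ₁, M⁻¹s⁻¹."""
        return 1.0 / self.phi1

    @property
    def k2_prime(self) -> float:
        """Apparent cumulative reductive rate constant 1/φ₂, M⁻¹s⁻¹."""
        return 1.0 / self.phi2

    @classmethod
    def from_rate_constants(
        cls, k1: float, k2_prime: float, phi0: float = 0.0
    ) -> "DalzielCoefficients":
        if k1 <= 0 or k2_prime <= 0:
            raise DomainError("k1 and k2_prime must be strictly positive")
        return cls(phi0=phi0, phi1=1.0 / k1, phi2=1.0 / k2_prime)


@dataclass(frozen=True)
class SPRTwoStepConstants:
    """Rate constants of the two-step SPR binding scheme.

    The enzyme first binds the phospholipid polar head with low affinity
    (k_a1, k_d1) and then relaxes to a stable bound conformation
    (k_a2, k_d2).
    """

    k_a1: float
    k_d1: float
    k_a2: float
    k_d2: float

    def __post_init__(self) -> None:
        for name in ("k_a1", "k_d1", "k_a2", "k_d2"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be strictly positive, got {value!r}")


def simulate(
    params: KineticParameters,
    cond: ReactionConditions,
    t_grid: Sequence[float] | np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-14,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from the standard initial condition.

    At t = 0 all enzyme is reduced and in solution (the enzyme is added
    last to start the reaction), SLPCOOH equals ROOH_0 and no GSSG has
    been produced.  An adaptive stiff-capable solver (LSODA by default,
    BDF available for the stiffest parameter regions) is used with
    tight tolerances; ``t_grid`` is an arbitrary strictly increasing
    sampling grid starting at ≥ 0.

    Raises
    ------
    IntegrationError
        If the solver fails (e.g. step-size collapse).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise DomainError("t_grid must be a 1-D array with at least two points")
    if not np.all(np.diff(t_grid) > 0) or t_grid[0] < 0:
        raise DomainError("t_grid must be strictly increasing and non-negative")

    y0 = [cond.E_total, 0.0, 0.0, cond.ROOH_0, 0.0]
    if cond.gsh_constant:
        fun = lambda t, y: _rhs_array(y, params, cond.M_total, cond.GSH)
    else:
        y0 = y0 + [cond.GSH]

        def fun(t, y):
            dy5 = _rhs_array(y[:5], params, cond.M_total, y[5])
            return np.append(dy5, -2.0 * dy5[4])

    sol = solve_ivp(
        fun,
        t_span=(0.0, float(t_grid[-1])),
        y0=y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    states = sol.y[:5].T
    gsh = sol.y[5] if not cond.gsh_constant else None
    return Trajectory(times=t_grid, states=states, conditions=cond, params=params, gsh=gsh)


def absorbance_from_trajectory(
    traj: Trajectory, baseline: float = 0.0, label: str = ""
) -> AbsorbanceTrace:
    """Convert a trajectory to the NADPH-coupled 340 nm readout.

    Glutathione reductase re-reduces each GSSG at the cost of one NADPH,
    so A340(t) = ε·ℓ·(NADPH_0 − GSSG(t)) (+ an optional constant
    baseline).  If GSSG overruns the NADPH supply the trace is truncated
    at depletion with a warning.
    """
    cond = traj.conditions
    gssg = traj.GSSG
    times = traj.times
    if times.size == 0:
        return AbsorbanceTrace(
            times=times, a340=np.empty(0), conditions=cond, label=label
        )
    over = gssg > cond.NADPH_0
    if np.any(over):
        cut = int(np.argmax(over))
        warnings.warn(
            "GSSG production exceeds the NADPH supply; trace truncated at "
            f"t = {times[cut]:.3g} s",
            stacklevel=2,
        )
        times, gssg = times[:cut], gssg[:cut]
    a340 = cond.epsilon_340 * cond.path_length * (cond.NADPH_0 - gssg) + baseline
    return AbsorbanceTrace(times=times, a340=a340, conditions=cond, label=label)


def micellar_rate(
    E: float, ROOH: float, GSH: float, dalziel: DalzielCoefficients
) -> float:
    """Ping-pong rate v = E / (φ₀ + φ₁/[ROOH] + φ₂/[GSH]) for micellar substrate."""
    if ROOH <= 0 or GSH <= 0:
        raise DomainError("micellar rate is undefined for non-positive ROOH or GSH")
    if E < 0:
        raise DomainError("enzyme concentration must be non-negative")
    return E / (dalziel.phi0 + dalziel.phi1 / ROOH + dalziel.phi2 / GSH)


def simulate_micellar_progress(
    E: float,
    ROOH_0: float,
    GSH: float,
    dalziel: DalzielCoefficients,
    t_grid: Sequence[float] | np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-16,
) -> tuple[np.ndarray, np.ndarray]:
    """Progression curve of a micellar assay under the Dalziel rate law.

    Integrates d[ROOH]/dt = −v(E, ROOH(t), GSH) and returns
    ``(ROOH(t), NADPH consumed)`` on ``t_grid``; one NADPH is consumed
    per hydroperoxide reduced.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if ROOH_0 <= 0 or GSH <= 0:
        raise DomainError("ROOH_0 and GSH must be strictly positive")
    if E < 0:
        raise DomainError("enzyme concentration must be non-negative")

    def fun(t, y):
        rooh = max(y[0], 0.0)
        if rooh == 0.0:
            return [0.0]
        return [-E / (dalziel.phi0 + dalziel.phi1 / rooh + dalziel.phi2 / GSH)]

    sol = solve_ivp(
        fun,
        t_span=(0.0, float(t_grid[-1])),
        y0=[ROOH_0],
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"micellar integration failed: {sol.message}")
    rooh = np.clip(sol.y[0], 0.0, None)
    return rooh, ROOH_0 - rooh


def spr_to_onestep(spr: SPRTwoStepConstants, M_total: float) -> tuple[float, float]:
    """Collapse the two-step SPR binding scheme to one-step (k_A, k_B).

    Under a stationary intermediate, k_A = k_a2 / (k_d1/k_a1 + [M]) and
    k_B = k_d2, where [M] is the total liposomal phospholipid
    concentration of the kinetic assay.
    """
    if M_total <= 0:
        raise DomainError("M_total must be strictly positive")
    k_a = spr.k_a2 / (spr.k_d1 / spr.k_a1 + M_total)
    return k_a, spr.k_d2


def k2s_from_dalziel(k2_prime: float, GSH: float) -> float:
    """Map the micellar reductive constant k'₂ to the surface constant k_2s.

    Under the steady-state approximation k_2s = k'₂ / [GSH]; the two
    constants describe inherently different mechanisms, so this is a
    rough order-of-magnitude bridge, not an identity.
    """
    if GSH <= 0:
        raise DomainError("GSH must be strictly positive")
    if k2_prime < 0:
        raise DomainError("k2_prime must be non-negative")
    return k2_prime / GSH


def classify_rate_shape(
    traj: Trajectory, min_peak_time: float = 10.0, rise_fraction: float = 0.95
) -> str:
    """Classify a trajectory's rate curve d[GSSG]/dt by how late it peaks.

    Slow membrane binding relative to the surface cycle delays the
    build-up of bound enzyme, so the rate starts low and climbs to an
    interior maximum well after t = 0 (the hallmark of the wild-type
    enzyme on cardiolipin membranes).  Fast binding brings the rate to
    its maximum within the first instants, after which substrate
    consumption makes it decay monotonically.

    The statistic is the rise time: the first time the rate reaches
    ``rise_fraction`` of its maximum (more robust than the exact argmax,
    which drifts along flat-topped curves).  Returns
    ``"interior_maximum"`` if the rise time is at or after
    ``min_peak_time`` seconds, else ``"monotone_decay"``.
    """
    rate = traj.gssg_rate()
    if rate.size < 3:
        raise DomainError("trajectory too short to classify")
    t_rise = traj.times[np.argmax(rate >= rise_fraction * rate.max())]
    return "interior_maximum" if t_rise >= min_peak_time else "monotone_decay"
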