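"""Velocity extraction and Dalziel analysis of progression curves.

For a ping-pong peroxidase with no ternary complex the steady-state
rate obeys  E/v = φ₀ + φ₁/[ROOH] + φ₂/[GSH].  A single progression
curve visits a whole range of hydroperoxide concentrations, so pairing
instantaneous velocities v(t) = −(dA/dt)/(ε·ℓ) with the simultaneous
ROOH(t) = ROOH₀ − ΔA(t)/(ε·ℓ) turns one trace into many (1/ROOH, E/v)
points; curves at two or more GSH levels make φ₂ identifiable and a
single multilinear least-squares fit returns all three coefficients at
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DataInconsistencyError, DomainError, IdentifiabilityError
from .model_core import AbsorbanceTrace, DalzielCoefficients

__all__ = [
    "VelocityCurve",
    "InitialRate",
    "background_correct",
    "estimate_initial_rate",
    "extract_velocity_curve",
    "fit_dalziel",
]


@dataclass(frozen=True)
class VelocityCurve:
    """Instantaneous velocities paired with substrate concentrations."""

    times: np.ndarray
    v: np.ndarray  # M/s, clipped at 0 after smoothing
    ROOH: np.ndarray  # M
    GSH: float
    E: float

    def __post_init__(self) -> None:
        for name in ("times", "v", "ROOH"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.times.shape == self.v.shape == self.ROOH.shape):
            raise DomainError("times, v and ROOH must have identical shapes")
        if self.E <= 0 or self.GSH <= 0:
            raise DomainError("E and GSH must be strictly positive")


@dataclass(frozen=True)
class InitialRate:
    """Initial velocity of a trace, in SI units and as the bench-top ΔAbs/min."""

    v0: float  # M/s
    slope: float  # AU/s (signed; negative for a consuming assay)
    window: tuple

    @property
    def delta_abs_per_min(self) -> float:
        return -self.slope * 60.0


def background_correct(
    trace: AbsorbanceTrace, blank: AbsorbanceTrace
) -> AbsorbanceTrace:
    """Remove the enzyme-free background drift from a trace.

    A straight line is fitted to the blank and its slope component is
    subtracted pointwise from the trace (the blank's own offset is the
    NADPH plateau and is not removed).  A flat blank therefore leaves
    the trace untouched.
    """
    if not blank.is_blank:
        raise DomainError("second argument must be a blank (is_blank=True) trace")
    if len(blank) < 2:
        raise DomainError("blank trace too short to fit a drift line")
    drift_slope = np.polyfit(blank.times, blank.a340, 1)[0]
    corrected = trace.a340 - drift_slope * (trace.times - trace.times[0])
    return AbsorbanceTrace(
        times=trace.times,
        a340=corrected,
        conditions=trace.conditions,
        label=trace.label,
        is_blank=trace.is_blank,
    )


def estimate_initial_rate(
    trace: AbsorbanceTrace, window: tuple = (0.0, 60.0)
) -> InitialRate:
    """Initial rate from a linear fit of A340 over the opening window.

    The default 0–60 s window matches the bench convention of reading
    ΔAbs/min over the first 30–60 s; the slope is converted to a molar
    velocity through v₀ = −slope/(ε·ℓ).
    """
    t0, t1 = window
    mask = (trace.times >= t0) & (trace.times <= t1)
    if int(mask.sum()) < 5:
        raise DomainError(
            f"initial-rate window ({t0}, {t1}) s contains fewer than 5 points"
        )
    slope = np.polyfit(trace.times[mask], trace.a340[mask], 1)[0]
    cond = trace.conditions
    v0 = -slope / (cond.epsilon_340 * cond.path_length)
    return InitialRate(v0=v0, slope=slope, window=(t0, t1))


def extract_velocity_curve(
    trace: AbsorbanceTrace,
    smoothing_window: int = 5,
    rooh_floor_fraction: float = 0.05,
) -> VelocityCurve:
    """Instantaneous velocities and substrate concentrations from one trace.

    The absorbance is smoothed with a centred moving average of
    ``smoothing_window`` points and differentiated with centred finite
    differences; small negative velocities left by the noise are clipped
    to zero.  ROOH(t) is reconstructed from the raw absorbance drop so
    no smoothing bias enters the concentration axis.  Points with ROOH
    below ``rooh_floor_fraction``·ROOH₀ are dropped to keep the 1/ROOH
    leverage bounded near substrate exhaustion.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise DomainError("smoothing_window must be a positive odd integer")
    n = len(trace)
    if n < smoothing_window + 2:
        raise DomainError("trace too short for the requested smoothing window")
    cond = trace.conditions
    eps_l = cond.epsilon_340 * cond.path_length

    half = smoothing_window // 2
    kernel = np.full(smoothing_window, 1.0 / smoothing_window)
    a_smooth = np.convolve(trace.a340, kernel, mode="valid")
    t_mid = trace.times[half : n - half]
    a_raw_mid = trace.a340[half : n - half]

    v = -np.gradient(a_smooth, t_mid) / eps_l
    rooh = cond.ROOH_0 - (trace.a340[0] - a_raw_mid) / eps_l

    if np.any(rooh < -1e-3 * cond.ROOH_0):
        raise DataInconsistencyError(
            "trace implies negative hydroperoxide concentration; check ROOH_0 "
            "metadata and background correction"
        )
    keep = rooh >= rooh_floor_fraction * cond.ROOH_0
    if not np.any(keep):
        raise DataInconsistencyError(
            "no points remain above the ROOH floor; the trace is exhausted"
        )
    return VelocityCurve(
        times=t_mid[keep],
        v=np.clip(v[keep], 0.0, None),
        ROOH=rooh[keep],
        GSH=cond.GSH,
        E=cond.E_total,
    )


def fit_dalziel(
    curves: list[VelocityCurve],
    fix_phi0_zero: bool = False,
) -> DalzielCoefficients:
    """Fit E/v = φ₀ + φ₁/[ROOH] + φ₂/[GSH] across velocity curves.

    A single ordinary least-squares regression of E/v on
    [1, 1/ROOH, 1/GSH] pools every point of every curve; it is exactly
    equivalent to the classical primary/secondary reciprocal plots on
    noiseless data and better conditioned on noisy data.  With
    ``fix_phi0_zero`` the intercept is constrained to 0 (the selenium
    enzyme shows no turnover saturation), which also makes a
    single-GSH-level design identifiable.

    Raises
    ------
    IdentifiabilityError
        If fewer than two distinct GSH levels are supplied without the
        φ₀ = 0 constraint, or the pooled design is rank deficient.
    """
    if not curves:
        raise IdentifiabilityError("no velocity curves supplied")
    gsh_levels = {c.GSH for c in curves}
    if len(gsh_levels) < 2 and not fix_phi0_zero:
        raise IdentifiabilityError(
            "at least two distinct GSH levels are required to separate phi0 "
            "from phi2; pass fix_phi0_zero=True for a single-level design"
        )

    inv_rooh, inv_gsh, y, w = [], [], [], []
    for c in curves:
        ok = c.v > 0
        inv_rooh.append(1.0 / c.ROOH[ok])
        inv_gsh.append(np.full(int(ok.sum()), 1.0 / c.GSH))
        y.append(c.E / c.v[ok])
        # Var(E/v) ∝ (E/v²)²·Var(v): weight by v⁴/E² so the noisy,
        # near-exhaustion reciprocals do not dominate the fit.  On
        # noiseless data the weights are irrelevant (exact fit).
        w.append(c.v[ok] ** 4 / c.E**2)
    inv_rooh = np.concatenate(inv_rooh)
    inv_gsh = np.concatenate(inv_gsh)
    y = np.concatenate(y)
    w = np.concatenate(w)
    if y.size < 3:
        raise IdentifiabilityError("too few positive-velocity points to fit")

    if fix_phi0_zero:
        X = np.column_stack([inv_rooh, inv_gsh])
    else:
        X = np.column_stack([np.ones_like(inv_rooh), inv_rooh, inv_gsh])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError(
            "rank-deficient design: vary ROOH (use a progression curve) and GSH"
        )
    fit = sm.WLS(y, X, weights=w).fit()
    if fix_phi0_zero:
        phi0, (phi1, phi2) = 0.0, fit.params
    else:
        phi0, phi1, phi2 = fit.params
    rms = float(np.sqrt(np.mean(fit.resid**2)))
    r2 = float(fit.rsquared)
    return DalzielCoefficients(
        phi0=float(phi0), phi1=float(phi1), phi2=float(phi2),
        rms_residual=rms, r_squared=r2,
    )
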