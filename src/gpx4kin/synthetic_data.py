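"""Synthetic spectrophotometric traces with the structure of the real assays.

The generators reproduce the coupled-assay geometry: 0.4 mM total
liposomal phospholipid, 0.05 mM SLPCOOH in-test, 2.5 mM GSH held by the
regenerating system, 0.16 mM NADPH read at 340 nm, enzyme in the low
nanomolar range added last to start the reaction.  Noise is additive
Gaussian on the absorbance with an optional constant offset and linear
drift, which is what a thermostatted diode-array spectrophotometer
contributes on this timescale.

Per-level parameter schedules are explicit inputs: cooperative
behaviour (association constant rising with enzyme level, or with
cardiolipin fraction) is *emulated* by supplying one
:class:`~gpx4kin.model_core.KineticParameters` per condition, never
inferred — mirroring how the kinetic model itself encodes cardiolipin
effects only through the fitted constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DomainError
from .model_core import (
    AbsorbanceTrace,
    DalzielCoefficients,
    KineticParameters,
    ReactionConditions,
    absorbance_from_trajectory,
    simulate,
    simulate_micellar_progress,
)

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "generate_trace",
    "generate_enzyme_titration",
    "generate_tocl_series",
    "generate_dalziel_dataset",
    "generate_blank",
    "WT_PC",
    "WT_TOCL",
    "R152H_PC",
    "R152H_TOCL",
]

# Representative parameter sets for the four canonical assay conditions:
# wild-type / R152H enzyme on plain phosphatidylcholine liposomes and on
# liposomes with 20% cardiolipin.  Association is weak without
# cardiolipin (k_A ~ 1 M^-1 s^-1) and strong with it; cardiolipin lowers
# the dissociation and surface-cycle constants of the wild type far more
# than of the mutant.
WT_PC = KineticParameters(k_A=1.0, k_B=5e-2, k_1s=1e5, k_2s=1e6)
WT_TOCL = KineticParameters(k_A=40.0, k_B=3e-3, k_1s=1e4, k_2s=1e5)
R152H_PC = KineticParameters(k_A=0.8, k_B=5e-2, k_1s=5e4, k_2s=5e5)
R152H_TOCL = KineticParameters(k_A=10.0, k_B=3e-2, k_1s=1e4, k_2s=1e5)


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise on the absorbance readout."""

    sd_absorbance: float = 5e-4
    baseline_offset: float = 0.0
    baseline_drift: float = 0.0  # AU/s, subtracted (drift makes A fall faster)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_absorbance < 0:
            raise DomainError("sd_absorbance must be non-negative")

    def apply(self, times: np.ndarray, a340: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        noisy = a340 + self.baseline_offset - self.baseline_drift * times
        if self.sd_absorbance > 0:
            noisy = noisy + rng.normal(0.0, self.sd_absorbance, size=a340.shape)
        return noisy


@dataclass(frozen=True)
class ExperimentDesign:
    """Levels and geometry of a synthetic assay series."""

    enzyme_levels: tuple = (3.2e-9, 6.4e-9, 1.6e-8, 3.2e-8, 6.4e-8)
    tocl_fractions: tuple = (0.0, 0.03, 0.11, 0.20)
    gsh_levels: tuple = (2e-3, 3e-3, 4e-3)
    ROOH_0: float = 5e-5
    M_total: float = 4e-4
    GSH: float = 2.5e-3
    NADPH_0: float = 1.6e-4
    duration: float = 900.0
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        if not self.enzyme_levels or not self.tocl_fractions or not self.gsh_levels:
            raise ConfigError("level lists must be non-empty")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ConfigError("duration and sampling_interval must be positive")

    def time_grid(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


def generate_trace(
    params: KineticParameters,
    cond: ReactionConditions,
    noise: NoiseModel | None = None,
    duration: float = 900.0,
    interval: float = 1.0,
    label: str = "",
) -> AbsorbanceTrace:
    """Simulate one liposome progression curve and add instrument noise.

    With ``noise=None`` (or zero sd, offset and drift) the trace is the
    deterministic model output; with a fixed seed the trace is
    bit-reproducible.
    """
    t_grid = np.arange(int(np.floor(duration / interval)) + 1) * interval
    traj = simulate(params, cond, t_grid)
    trace = absorbance_from_trajectory(traj, label=label)
    if noise is None:
        return trace
    return AbsorbanceTrace(
        times=trace.times,
        a340=noise.apply(trace.times, trace.a340),
        conditions=cond,
        label=label,
    )


def _spread_noise(noise: NoiseModel | None, i: int) -> NoiseModel | None:
    """Derive an independent per-trace noise stream from a base model."""
    if noise is None:
        return None
    return NoiseModel(
        sd_absorbance=noise.sd_absorbance,
        baseline_offset=noise.baseline_offset,
        baseline_drift=noise.baseline_drift,
        seed=noise.seed + i,
    )


def generate_enzyme_titration(
    design: ExperimentDesign,
    params_per_level: Sequence[KineticParameters],
    tocl_fraction: float = 0.0,
    noise: NoiseModel | None = None,
) -> list[AbsorbanceTrace]:
    """One trace per enzyme level, with an explicit parameter schedule.

    Supplying the same :class:`KineticParameters` at every level yields
    initial rates linear in total enzyme; a schedule whose k_A rises
    with the level emulates the cooperative (surface-sensing) wild-type
    behaviour on cardiolipin membranes.
    """
    if len(params_per_level) != len(design.enzyme_levels):
        raise ConfigError(
            f"need one KineticParameters per enzyme level: "
            f"{len(params_per_level)} != {len(design.enzyme_levels)}"
        )
    traces = []
    for i, (e_tot, params) in enumerate(zip(design.enzyme_levels, params_per_level)):
        cond = ReactionConditions(
            E_total=e_tot,
            M_total=design.M_total,
            ROOH_0=design.ROOH_0,
            GSH=design.GSH,
            NADPH_0=design.NADPH_0,
            tocl_fraction=tocl_fraction,
        )
        traces.append(
            generate_trace(
                params,
                cond,
                noise=_spread_noise(noise, i),
                duration=design.duration,
                interval=design.sampling_interval,
                label=f"E={e_tot:.3g}M",
            )
        )
    return traces


def generate_tocl_series(
    design: ExperimentDesign,
    params_per_fraction: Sequence[KineticParameters],
    E_total: float,
    noise: NoiseModel | None = None,
) -> list[AbsorbanceTrace]:
    """One trace per cardiolipin fraction at a fixed enzyme level.

    The cardiolipin fraction is metadata: identical parameters across
    fractions give identical noiseless traces.  A wild-type-like
    schedule (k_A up; k_B, k_1s, k_2s down with the fraction) reproduces
    the paradoxical slow-down at low enzyme, a mutant-like schedule
    (k_A up, the rest roughly constant) a plain acceleration.
    """
    if len(params_per_fraction) != len(design.tocl_fractions):
        raise ConfigError(
            f"need one KineticParameters per TOCL fraction: "
            f"{len(params_per_fraction)} != {len(design.tocl_fractions)}"
        )
    traces = []
    for i, (frac, params) in enumerate(zip(design.tocl_fractions, params_per_fraction)):
        cond = ReactionConditions(
            E_total=E_total,
            M_total=design.M_total,
            ROOH_0=design.ROOH_0,
            GSH=design.GSH,
            NADPH_0=design.NADPH_0,
            tocl_fraction=frac,
        )
        traces.append(
            generate_trace(
                params,
                cond,
                noise=_spread_noise(noise, i),
                duration=design.duration,
                interval=design.sampling_interval,
                label=f"TOCL={frac:.0%}",
            )
        )
    return traces


def generate_dalziel_dataset(
    dalziel_truth: DalzielCoefficients,
    E: float = 1e-8,
    ROOH_0: float = 3e-5,
    gsh_levels: Sequence[float] = (2e-3, 3e-3, 4e-3),
    NADPH_0: float = 1.6e-4,
    duration: float = 600.0,
    interval: float = 0.5,
    noise: NoiseModel | None = None,
) -> list[AbsorbanceTrace]:
    """Micellar progression traces for a Dalziel experiment, one per GSH level.

    Each curve integrates the ping-pong rate law from ``ROOH_0`` and is
    converted to A340 through the NADPH-coupled readout (one NADPH per
    hydroperoxide reduced).  Defaults follow the micellar assay design:
    GSH at 2, 3 and 4 mM and 30 µM hydroperoxide.
    """
    t_grid = np.arange(int(np.floor(duration / interval)) + 1) * interval
    traces = []
    for i, gsh in enumerate(gsh_levels):
        _, consumed = simulate_micellar_progress(E, ROOH_0, gsh, dalziel_truth, t_grid)
        cond = ReactionConditions(
            E_total=E, M_total=0.0, ROOH_0=ROOH_0, GSH=gsh, NADPH_0=NADPH_0
        )
        a340 = cond.epsilon_340 * cond.path_length * (NADPH_0 - consumed)
        per_trace = _spread_noise(noise, i)
        if per_trace is not None:
            a340 = per_trace.apply(t_grid, a340)
        traces.append(
            AbsorbanceTrace(
                times=t_grid, a340=a340, conditions=cond, label=f"GSH={gsh:.3g}M"
            )
        )
    return traces


def generate_blank(
    cond: ReactionConditions,
    noise: NoiseModel | None = None,
    duration: float = 900.0,
    interval: float = 1.0,
    slope: float = 0.0,
) -> AbsorbanceTrace:
    """Enzyme-free background trace: A(t) = ε·ℓ·NADPH_0 − slope·t (+ noise)."""
    t_grid = np.arange(int(np.floor(duration / interval)) + 1) * interval
    a0 = cond.epsilon_340 * cond.path_length * cond.NADPH_0
    a340 = a0 - slope * t_grid
    if noise is not None:
        a340 = noise.apply(t_grid, a340)
    return AbsorbanceTrace(
        times=t_grid, a340=a340, conditions=cond, label="blank", is_blank=True
    )
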