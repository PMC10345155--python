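"""Independent brute-force integrators used as oracles in tests.

These deliberately re-state the kinetic scheme from scratch (mass-action
terms written out inline) and integrate with a classical fixed-step RK4
loop, so they share no code path with the package's adaptive solver.
"""

from __future__ import annotations

import numpy as np


def rk4_liposome(
    k_a: float,
    k_b: float,
    k_1s: float,
    k_2s: float,
    e_total: float,
    m_total: float,
    rooh_0: float,
    gsh: float,
    t_end: float,
    dt: float = 1e-3,
    n_save: int = 61,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 on the five-pool scheme; returns (times, states)."""

    def f(y):
        e_red, em, eox, rooh, gssg = y
        v_bind = k_a * e_red * m_total
        v_unbind = k_b * em
        v_ox = k_1s * em * rooh
        v_red = k_2s * eox * gsh * gsh
        return np.array([
            v_unbind - v_bind,
            v_bind - v_unbind - v_ox + v_red,
            v_ox - v_red,
            -v_ox,
            v_red,
        ])

    save_times = np.linspace(0.0, t_end, n_save)
    y = np.array([e_total, 0.0, 0.0, rooh_0, 0.0])
    out = np.empty((n_save, 5))
    out[0] = y
    n_steps = int(round(t_end / dt))
    save_every = n_steps // (n_save - 1)
    assert save_every * (n_save - 1) == n_steps, "dt must tile the save grid"
    j = 1
    for i in range(1, n_steps + 1):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i % save_every == 0:
            out[j] = y
            j += 1
    return save_times, out


def rk4_micellar(
    e: float,
    rooh_0: float,
    gsh: float,
    phi0: float,
    phi1: float,
    phi2: float,
    t_end: float,
    dt: float = 1e-3,
    n_save: int = 61,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step RK4 on d[ROOH]/dt = -E/(phi0 + phi1/ROOH + phi2/GSH)."""

    def f(rooh):
        if rooh <= 0:
            return 0.0
        return -e / (phi0 + phi1 / rooh + phi2 / gsh)

    save_times = np.linspace(0.0, t_end, n_save)
    rooh = rooh_0
    out = np.empty(n_save)
    out[0] = rooh
    n_steps = int(round(t_end / dt))
    save_every = n_steps // (n_save - 1)
    assert save_every * (n_save - 1) == n_steps
    j = 1
    for i in range(1, n_steps + 1):
        k1 = f(rooh)
        k2 = f(rooh + 0.5 * dt * k1)
        k3 = f(rooh + 0.5 * dt * k2)
        k4 = f(rooh + dt * k3)
        rooh = rooh + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i % save_every == 0:
            out[j] = rooh
            j += 1
    return save_times, out
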