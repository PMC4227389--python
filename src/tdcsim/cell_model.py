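"""FitzHugh-Nagumo neuron membrane model and its explicit ODE integrator.

The transmembrane voltage v (volts) and a single recovery variable w evolve
as

    dv/dt = c1 / v_amp^2 * (v - v_rest) (v - v_th) (v_peak - v) - c2 w + I_app
    dw/dt = b (v - v_rest - c3 w)

with v_amp = v_peak - v_rest and threshold v_th = v_rest + a * v_amp.  The
cubic is kept literally in this form (explicit 1/v_amp^2 prefactor) so the
coefficient values read off directly.  Coefficients are scaled for time in
seconds and voltages in volts; (v_rest, 0) is an exact fixed point.

The reaction substep of the operator-splitting scheme integrates this
system nodewise with Heun's method (explicit trapezoidal predictor-
corrector, second order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["FHNParams", "CellState", "fhn_rhs", "threshold_voltage",
           "heun_step", "ode_substep_loop"]


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo coefficients (time in seconds, voltage in volts).

    Defaults are the classical coefficient set rescaled for seconds, with
    the resting and peak membrane voltages pinned at -70 mV and +40 mV.
    """

    a: float = 0.13          # dimensionless threshold position
    b: float = 13.0          # 1/s, recovery rate
    c1: float = 260.0        # 1/s (cubic prefactor; divided by v_amp^2 in use)
    c2: float = 100.0        # 1/s, recovery feedback strength
    c3: float = 1.0          # dimensionless
    v_rest: float = -0.070   # V
    v_peak: float = 0.040    # V

    def __post_init__(self) -> None:
        if not self.v_peak > self.v_rest:
            raise ValueError("v_peak must exceed v_rest")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must lie in [0, 1]")

    @property
    def v_amp(self) -> float:
        """Action-potential amplitude v_peak - v_rest (V)."""
        return self.v_peak - self.v_rest

    @property
    def v_th(self) -> float:
        """Threshold voltage v_rest + a * v_amp (V)."""
        return self.v_rest + self.a * self.v_amp


@dataclass
class CellState:
    """Nodal membrane state on the brain node set."""

    v: np.ndarray  # V
    w: np.ndarray  # recovery variable (V-scaled)
    t: float = 0.0  # s

    def copy(self) -> "CellState":
        return CellState(v=self.v.copy(), w=self.w.copy(), t=self.t)


def threshold_voltage(params: FHNParams) -> float:
    """Firing threshold v_th = v_rest + a (v_peak - v_rest), in volts."""
    return params.v_th


def fhn_rhs(v, w, params: FHNParams, i_app=0.0):
    """Right-hand sides (dv/dt, dw/dt) of the membrane model.

    Vectorized over nodal arrays; ``i_app`` (V/s) may be scalar or per-node.
    """
    p = params
    dv = (
        p.c1 / p.v_amp**2 * (v - p.v_rest) * (v - p.v_th) * (p.v_peak - v)
        - p.c2 * w
        + i_app
    )
    dw = p.b * (v - p.v_rest - p.c3 * w)
    return dv, dw


def heun_step(state: CellState, params: FHNParams, i_app, dt: float) -> CellState:
    """One Heun (explicit trapezoidal) step of size ``dt`` for all nodes."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    v, w = state.v, state.w
    dv1, dw1 = fhn_rhs(v, w, params, i_app)
    vp = v + dt * dv1
    wp = w + dt * dw1
    dv2, dw2 = fhn_rhs(vp, wp, params, i_app)
    return CellState(
        v=v + 0.5 * dt * (dv1 + dv2),
        w=w + 0.5 * dt * (dw1 + dw2),
        t=state.t + dt,
    )


def ode_substep_loop(
    state: CellState,
    params: FHNParams,
    i_app,
    dt_global: float,
    dt_ode: float,
) -> CellState:
    """Advance the membrane ODEs over one global step using Heun substeps.

    The global step ``dt_global`` is covered by ``ceil(dt_global/dt_ode)``
    equal Heun substeps, so a finer reaction step than the diffusion step
    can be used without touching the PDE solve.  ``i_app`` may be a scalar,
    a per-node array, or a callable ``t -> scalar/array`` evaluated at each
    substep start time.
    """
    if dt_ode > dt_global:
        raise ValueError("dt_ode must not exceed dt_global")
    n_sub = int(np.ceil(dt_global / dt_ode - 1e-12))
    h = dt_global / n_sub
    out = state
    for _ in range(n_sub):
        cur = i_app(out.t) if callable(i_app) else i_app
        out = heun_step(out, params, cur, h)
    return out
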