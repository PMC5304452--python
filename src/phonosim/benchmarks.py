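"""Built-in verification benchmarks.

These drive single solvers on closed-form cases: the open-closed tube
resonance of the acoustic solver (against the quarter-wave formula), the
pressure-driven channel of the flow solver (against plane Poiseuille),
and a decaying-vortex accuracy check.  They are used by the test suite,
the CLI and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .acoustics import AcousticProperties, AcousticState, LpceSolver
from .analysis import dominant_frequency, spectrum
from .flow import FlowSolver, FluidProperties
from .grid import GridSpec

__all__ = ["tube_resonance", "poiseuille_channel", "decaying_vortex_error"]


def tube_resonance(
    length: float = 0.174,
    c: float = 352.0,
    n_cells: int = 128,
    duration: float = 0.15,
    rho0: float = 1.1455,
    filter_strength: float = 0.1,
    pulse_center_frac: float = 0.12,
    pulse_width_frac: float = 0.05,
    cfl: float = 0.5,
) -> dict:
    """Broadband-excited open-closed tube; returns the lowest pressure peak.

    A 1D duct of the given length is closed (rigid) at x = 0 and open
    (p' = 0, complete reflection) at x = L.  A Gaussian pressure pulse
    near the closed end rings the tube's modes; the spectrum of p' at the
    closed end is returned along with its lowest peak, to be compared with
    the quarter-wave resonance (2n - 1) c / 4L.
    """
    grid = GridSpec([np.linspace(0.0, length, n_cells + 1)])
    solver = LpceSolver(
        grid,
        AcousticProperties(c=c),
        rho0,
        edge_bc={(0, 0): "wall", (0, 1): "open"},
        filter_strength=filter_strength,
    )
    state = AcousticState.zeros(grid)
    x = grid.centers(0)
    state.p[:] = 100.0 * np.exp(
        -(((x - pulse_center_frac * length) / (pulse_width_frac * length)) ** 2)
    )
    state.rho[:] = state.p / c**2
    dt = cfl * grid.min_width(0) / c
    n_steps = int(round(duration / dt))
    trace = np.empty(n_steps)
    # standing-wave envelope |p'| along the tube, accumulated after the
    # initial transient has rung down into the modes
    envelope = np.zeros(n_cells)
    for k in range(n_steps):
        state = solver.step(state, dt, check_cfl=(k == 0))
        trace[k] = state.p[0]
        if k > n_steps // 2:
            envelope = np.maximum(envelope, np.abs(state.p))
    freq, amp = spectrum(trace - trace.mean(), 1.0 / dt)
    f_low = dominant_frequency(trace, 1.0 / dt, f_min=0.3 * c / (4 * length))
    return {
        "frequency": float(f_low),
        "freq_axis": freq,
        "amplitude": amp,
        "trace": trace,
        "dt": dt,
        "envelope": envelope,
        "x": x,
        "n": n_cells,
    }


def poiseuille_channel(
    height: float = 0.01,
    length: float = 0.05,
    n_across: int = 64,
    n_along: int = 24,
    dp: float = 1.0,
    props: FluidProperties | None = None,
    t_end: float = 1.1,
    upwind: float = 0.0,
) -> dict:
    """Pressure-driven steady channel flow between edge walls.

    Returns the computed mid-channel velocity profile, the peak velocity
    and the flow rate, together with the analytic plane-Poiseuille values
    u_max = dP h^2 / (8 rho nu L), Q = (2/3) u_max h.
    """
    props = props or FluidProperties(dp_drive=dp)
    grid = GridSpec(
        [
            np.linspace(-height / 2, height / 2, n_across + 1),
            np.linspace(0.0, length, n_along + 1),
        ]
    )
    solver = FlowSolver(grid, props, upwind=upwind)
    state = solver.initial_state()
    dt = min(0.8 * solver.stable_dt(state), 0.2 * height**2 / (4 * props.nu0))
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        state = solver.step(state, dt)
    xc = grid.centers(0)
    profile = state.v[:, n_along // 2]
    u_max = dp * height**2 / (8 * props.rho0 * props.nu0 * length)
    exact = dp / (2 * props.rho0 * props.nu0 * length) * ((height / 2) ** 2 - xc**2)
    return {
        "x": xc,
        "profile": profile,
        "exact_profile": exact,
        "u_max": float(profile.max()),
        "u_max_exact": float(u_max),
        "flow_rate": solver.outlet_flowrate(state),
        "flow_rate_exact": float(2.0 / 3.0 * u_max * height),
        "div_residual": state.div_residual,
        "state": state,
        "solver": solver,
    }


def decaying_vortex_error(n: int = 16, t_end: float = 2.0e-3, box: float = 0.01) -> float:
    """L2 velocity error of the decaying-vortex exact solution at t_end.

    Velocity Dirichlet boundaries from the exact solution; used for the
    grid-convergence (design order) check of the flow solver.
    """
    a = np.pi / box
    nu = 6.6e-5
    props = FluidProperties(rho0=1.1455, nu0=nu, dp_drive=0.0)

    def F(t):
        return np.exp(-2 * nu * a * a * t)

    def uex(x, y, t):
        return -np.cos(a * x) * np.sin(a * y) * F(t)

    def vex(x, y, t):
        return np.sin(a * x) * np.cos(a * y) * F(t)

    def bc(x, y, t):
        return (uex(x, y, t), vex(x, y, t))

    grid = GridSpec([np.linspace(0, box, n + 1), np.linspace(0, box, n + 1)])
    edge = {k: ("velocity", bc) for k in ((0, 0), (0, 1), (1, 0), (1, 1))}
    solver = FlowSolver(grid, props, edge_bc=edge, upwind=0.0)
    state = solver.initial_state()
    Xu, Yu = np.meshgrid(grid.axes[0], grid.centers(1), indexing="ij")
    Xv, Yv = np.meshgrid(grid.centers(0), grid.axes[1], indexing="ij")
    state.u[:] = uex(Xu, Yu, 0.0)
    state.v[:] = vex(Xv, Yv, 0.0)
    dt = t_end / (8 * (n // 16) ** 2)  # dt ~ h^2 so spatial order dominates
    for _ in range(int(round(t_end / dt))):
        state = solver.step(state, dt)
    return float(np.sqrt(np.mean((state.u - uex(Xu, Yu, state.t)) ** 2)))
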