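"""Incoherent type-1 feedforward loop (I1-FFL) model of the GAT1–DAL80–MEP2
regulatory motif.

GAT1 activates both the high-affinity ammonium transporter gene MEP2 and the
repressor DAL80, which in turn represses MEP2.  With linear production and
first-order decay the dynamics are::

    dGAT1/dt  = 0
    dDAL80/dt = A·X·GAT1 − c·DAL80
    dMEP2/dt  = A·GAT1 − R·DAL80 − c·MEP2

where ``A`` is the strength of MEP2 promoter activation by GAT1, ``X`` scales
the DAL80 promoter's activation relative to MEP2's (DAL80 activation = A·X),
``R`` is the strength of MEP2 repression by DAL80 and ``c`` is a common
first-order degradation rate.  The fixed point is available in closed form::

    DAL80* = A·X·GAT1 / c
    MEP2*  = A·GAT1·(1 − R·X/c) / c

The model is deliberately linear: MEP2* may go negative for X > c/R, which is
reported as computed (and flagged in sweeps) rather than clamped.  The
interesting regime for adaptive tuning is the one in which *both* promoter
activations decrease (A and A·X both drop) yet MEP2* rises — possible
whenever the proportional drop in DAL80 activation exceeds the drop in direct
MEP2 activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DivisionUndefinedError, IntegrationError, InvalidParameterError

__all__ = [
    "FFLParameters",
    "FFLState",
    "SteadyStateResult",
    "Trajectory",
    "SweepGrid",
    "analytic_steady_state",
    "integrate_ffl",
    "sweep_parameter_grid",
    "relative_mep2",
    "gat1_dose_response",
]


@dataclass(frozen=True)
class FFLParameters:
    """Rate parameters of the I1-FFL.

    Parameters
    ----------
    a : float
        Strength of MEP2 promoter activation by GAT1 (rate units; A ≥ 0).
    x : float
        Dimensionless multiplier: the DAL80 promoter is activated at rate
        ``a * x`` (X ≥ 0).
    r : float
        Strength of MEP2 promoter repression by DAL80 (rate units; R ≥ 0).
    c : float
        First-order degradation rate constant (1/time; c > 0).
    gat1 : float
        Constant GAT1 level (arbitrary concentration units; ≥ 0).
    """

    a: float
    x: float
    r: float
    c: float
    gat1: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a >= 0 and self.x >= 0 and self.r >= 0 and self.gat1 >= 0):
            raise InvalidParameterError(
                "a, x, r and gat1 must all be non-negative; got "
                f"a={self.a}, x={self.x}, r={self.r}, gat1={self.gat1}"
            )
        if not self.c > 0:
            raise InvalidParameterError(f"degradation rate c must be positive, got c={self.c}")

    def with_gat1(self, gat1: float) -> "FFLParameters":
        return replace(self, gat1=gat1)


@dataclass(frozen=True)
class FFLState:
    """Instantaneous state of the loop (arbitrary concentration units)."""

    time: float
    gat1: float
    dal80: float
    mep2: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError(f"time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class SteadyStateResult:
    """Fixed point of the loop, with provenance of how it was obtained."""

    dal80_ss: float
    mep2_ss: float
    method: str  # "analytic" or "numeric"
    residual: float  # max |d/dt| at the reported state
    converged: bool


@dataclass(frozen=True)
class Trajectory:
    """Time course of the three species as parallel arrays."""

    time: np.ndarray
    gat1: np.ndarray
    dal80: np.ndarray
    mep2: np.ndarray

    def __len__(self) -> int:
        return self.time.size

    def state_at(self, i: int) -> FFLState:
        return FFLState(
            time=float(self.time[i]),
            gat1=float(self.gat1[i]),
            dal80=float(self.dal80[i]),
            mep2=float(self.mep2[i]),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.time, "gat1": self.gat1, "dal80": self.dal80, "mep2": self.mep2}
        )


@dataclass(frozen=True)
class SweepGrid:
    """Steady-state MEP2 over an (A, X) grid, relative to a reference state.

    ``mep2_matrix[i, j]`` holds MEP2* at ``(a_values[i], x_values[j])``.
    ``relative_matrix`` divides by MEP2* at ``reference`` and
    ``increased_mask`` thresholds it at 1; both are ``None`` when the
    reference steady state is exactly zero (``reference_degenerate``).
    """

    a_values: np.ndarray
    x_values: np.ndarray
    mep2_matrix: np.ndarray
    reference: tuple[float, float]
    reference_mep2: float
    relative_matrix: np.ndarray | None = None
    increased_mask: np.ndarray | None = None
    reference_degenerate: bool = False
    has_negative: bool = field(default=False)


def _derivatives(params: FFLParameters, gat1: float, dal80: float, mep2: float):
    d_dal80 = params.a * params.x * gat1 - params.c * dal80
    d_mep2 = params.a * gat1 - params.r * dal80 - params.c * mep2
    return d_dal80, d_mep2


def analytic_steady_state(params: FFLParameters) -> SteadyStateResult:
    """Closed-form fixed point of the loop.

    Setting both time derivatives to zero gives ``DAL80* = A·X·GAT1/c`` and
    ``MEP2* = (A·GAT1 − R·DAL80*)/c``.  No clamping: MEP2* is negative
    whenever X > c/R.
    """
    dal80_ss = params.a * params.x * params.gat1 / params.c
    mep2_ss = (params.a * params.gat1 - params.r * dal80_ss) / params.c
    return SteadyStateResult(
        dal80_ss=dal80_ss, mep2_ss=mep2_ss, method="analytic", residual=0.0, converged=True
    )


def integrate_ffl(
    params: FFLParameters,
    initial: FFLState | None = None,
    t_end: float | None = None,
    tol: float = 1e-8,
    n_points: int = 201,
    rtol: float = 1e-9,
    atol: float = 1e-9,
    t_eval=None,
) -> tuple[Trajectory, SteadyStateResult]:
    """Integrate the loop from ``initial`` and report the numeric steady state.

    Defaults: ``initial = (GAT1 = params.gat1, DAL80 = 0, MEP2 = 0)`` and
    ``t_end = 100 / c`` (many decay half-lives, so the linear system has
    relaxed far below the solver tolerance).  The final state is reported as a
    converged steady state when the maximum absolute time derivative there is
    at most ``tol``.
    """
    if initial is None:
        initial = FFLState(time=0.0, gat1=params.gat1, dal80=0.0, mep2=0.0)
    if t_end is None:
        t_end = 100.0 / params.c
    if t_end < 0:
        raise InvalidParameterError(f"t_end must be non-negative, got {t_end}")
    if tol <= 0:
        raise InvalidParameterError(f"tol must be positive, got {tol}")

    if t_end == 0:
        traj = Trajectory(
            time=np.array([initial.time]),
            gat1=np.array([initial.gat1]),
            dal80=np.array([initial.dal80]),
            mep2=np.array([initial.mep2]),
        )
        res = max(abs(d) for d in _derivatives(params, initial.gat1, initial.dal80, initial.mep2))
        return traj, SteadyStateResult(
            dal80_ss=initial.dal80,
            mep2_ss=initial.mep2,
            method="numeric",
            residual=res,
            converged=res <= tol,
        )

    def rhs(_t, y):
        d_dal80, d_mep2 = _derivatives(params, y[0], y[1], y[2])
        return [0.0, d_dal80, d_mep2]

    if t_eval is None:
        t_eval = initial.time + np.linspace(0.0, t_end, n_points)
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if np.any(np.diff(t_eval) < 0):
            raise InvalidParameterError("t_eval must be sorted non-decreasingly")
    sol = solve_ivp(
        rhs,
        (initial.time, initial.time + t_end),
        [initial.gat1, initial.dal80, initial.mep2],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"ODE integration failed: {sol.message}")

    traj = Trajectory(time=sol.t, gat1=sol.y[0], dal80=sol.y[1], mep2=sol.y[2])
    final = traj.state_at(-1)
    residual = max(abs(d) for d in _derivatives(params, final.gat1, final.dal80, final.mep2))
    return traj, SteadyStateResult(
        dal80_ss=final.dal80,
        mep2_ss=final.mep2,
        method="numeric",
        residual=residual,
        converged=residual <= tol,
    )


def sweep_parameter_grid(
    a_values=None,
    x_values=None,
    r: float = 2.0,
    c: float = 1.0,
    gat1: float = 1.0,
    reference: tuple[float, float] = (1.0, 0.4),
) -> SweepGrid:
    """Evaluate MEP2* over an (A, X) grid, relative to an ancestral reference.

    The reference pair is evaluated exactly via the closed form whether or
    not it lies on the grid.  A reference with MEP2* = 0 makes the relative
    surface undefined; the absolute matrix is still returned, with
    ``reference_degenerate=True`` and no relative matrix or mask.

    Default grid: 101×101 over A ∈ [0, 2], X ∈ [0, 1].
    """
    a_values = np.linspace(0.0, 2.0, 101) if a_values is None else np.asarray(a_values, float)
    x_values = np.linspace(0.0, 1.0, 101) if x_values is None else np.asarray(x_values, float)
    if a_values.size == 0 or x_values.size == 0:
        raise InvalidParameterError("a_values and x_values must be non-empty")

    a_col = a_values[:, None]
    x_row = x_values[None, :]
    # closed form vectorized over the grid
    mep2 = a_col * gat1 * (1.0 - r * x_row / c) / c

    ref_a, ref_x = reference
    ref = analytic_steady_state(FFLParameters(a=ref_a, x=ref_x, r=r, c=c, gat1=gat1))
    if ref.mep2_ss == 0:
        return SweepGrid(
            a_values=a_values,
            x_values=x_values,
            mep2_matrix=mep2,
            reference=(ref_a, ref_x),
            reference_mep2=0.0,
            reference_degenerate=True,
            has_negative=bool(np.any(mep2 < 0)),
        )
    rel = mep2 / ref.mep2_ss
    return SweepGrid(
        a_values=a_values,
        x_values=x_values,
        mep2_matrix=mep2,
        reference=(ref_a, ref_x),
        reference_mep2=ref.mep2_ss,
        relative_matrix=rel,
        increased_mask=rel > 1.0,
        has_negative=bool(np.any(mep2 < 0)),
    )


def relative_mep2(mutant: FFLParameters, ancestor: FFLParameters) -> float:
    """MEP2* of ``mutant`` divided by MEP2* of ``ancestor``.

    Raises :class:`DivisionUndefinedError` when the ancestral steady state
    is exactly zero.
    """
    anc = analytic_steady_state(ancestor)
    if anc.mep2_ss == 0:
        raise DivisionUndefinedError("ancestral MEP2 steady state is zero; ratio undefined")
    return analytic_steady_state(mutant).mep2_ss / anc.mep2_ss


def gat1_dose_response(params: FFLParameters, gat1_levels) -> np.ndarray:
    """MEP2* at each GAT1 level, holding all rate parameters fixed.

    The closed form is linear in GAT1, so the response is exactly
    proportional: doubling GAT1 doubles MEP2* (and whenever
    ``A·(1 − R·X/c) > 0`` the response is strictly increasing).
    """
    levels = np.asarray(gat1_levels, dtype=float)
    if np.any(levels < 0):
        raise InvalidParameterError("gat1 levels must be non-negative")
    return np.array(
        [analytic_steady_state(params.with_gat1(g)).mep2_ss for g in levels]
    )
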