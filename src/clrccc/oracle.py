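"""Independent numerical oracle: the equilibrium-cell cascade integrated
exactly, against which every closed-form profile is validated.

The column is ``N`` well-mixed equilibrium cells in series; with the x-phase
mobile the normalised cell concentrations obey

    dx_k/dt = a N (x_{k-1} - x_k),          k = 1..N,

with ``x_0`` the inlet (rectangular feed of height 1/ts while loading, then
the recycling-loop outlet).  The loop is ``Nec`` mixed cells of total
relative volume ``b``:  dz_j/dt = (Nec/b)(z_{j-1} - z_j) with z_0 = x_N.
Stage 2 reverses the flow on the y-phase basis:

    dy_k/dt = K_D a N (y_{k+1} - y_k),      y_{N+1} = 0,  y_k(0) = K_D x_k.

The systems are linear with piecewise-constant coefficients, so they are
integrated by matrix-exponential stepping (``scipy.sparse.linalg
.expm_multiply`` on a uniform grid; the affine loading phase is handled by
augmenting the state with a constant), which is exact up to the Krylov
tolerance — no time-discretisation error.  The oracle therefore realises the
cascade model itself; the closed forms are Gaussian approximations of its
Erlang responses, with error shrinking as 1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply

__all__ = ["OracleResult", "simulate_stage1", "simulate_stage2", "compare"]


@dataclass
class OracleResult:
    """Time grid, outlet series and final state of a cascade integration."""

    t: np.ndarray
    outlet: np.ndarray
    x_final: np.ndarray        # column cells at t[-1]
    z_final: np.ndarray | None  # loop cells at t[-1] (None without a loop)
    mass: np.ndarray           # total dimensionless mass (column + loop)


def _column_block(N: int, rate: float) -> sparse.lil_matrix:
    A = sparse.lil_matrix((N, N))
    for k in range(N):
        A[k, k] = -rate
        if k > 0:
            A[k, k - 1] = rate
    return A


def _system_matrix(N: int, a: float, Nec: int, b: float,
                   closed: bool) -> sparse.csr_matrix:
    """Column + loop matrix; `closed` routes the outlet back to the inlet."""
    aN = a * N
    if b > 0.0:
        M = N + Nec
        A = sparse.lil_matrix((M, M))
        A[:N, :N] = _column_block(N, aN)
        rl = Nec / b
        for j in range(Nec):
            A[N + j, N + j] = -rl
            A[N + j, N + j - 1 if j > 0 else N - 1] = rl
        if closed:
            A[0, N + Nec - 1] = aN  # loop outlet feeds the column inlet
    else:
        A = _column_block(N, aN)
        if closed:
            A[0, N - 1] = aN  # direct (ideal, volume-free) recycle
    return A.tocsr()


def _augment_feed(A: sparse.csr_matrix, feed: float,
                  aN: float) -> sparse.csr_matrix:
    """Append a frozen unit state carrying the constant feed term aN*feed."""
    M = A.shape[0]
    Aug = sparse.lil_matrix((M + 1, M + 1))
    Aug[:M, :M] = A
    Aug[0, M] = aN * feed
    return Aug.tocsr()


def _mass(x: np.ndarray, z: np.ndarray | None, a: float, N: int,
          Nec: int, b: float) -> np.ndarray:
    m = x.sum(axis=-1) / (a * N)
    if z is not None:
        m = m + z.sum(axis=-1) * b / Nec
    return m


def simulate_stage1(*, N: int, a: float, ts: float = 0.0, Nec: int = 0,
                    b: float = 0.0, t_end: float, num: int = 2001,
                    closed: bool = True) -> OracleResult:
    """Integrate the stage-1 cascade and record the outlet chromatogram.

    ``closed=False`` gives a single open-loop passage (the pure tanks-in-
    series / Erlang response).  Feed is a rectangle of height ``1/ts`` on
    ``[0, ts]``; ``ts = 0`` injects a unit-area impulse into cell 1
    (``x_1(0+) = a N``).
    """
    if t_end <= ts:
        raise ValueError("t_end must exceed the loading time ts")
    M = N + (Nec if b > 0.0 else 0)
    dt = t_end / (num - 1)
    A_run = _system_matrix(N, a, Nec, b, closed)

    if ts > 0.0:
        # loading phase: column inlet held at 1/ts, loop open at the inlet
        A_load = _system_matrix(N, a, Nec, b, closed=False)
        A_aug = _augment_feed(A_load, 1.0 / ts, a * N)
        n1 = max(2, int(np.ceil(ts / dt)) + 1)
        v0 = np.zeros(M + 1)
        v0[-1] = 1.0
        traj1 = expm_multiply(A_aug, v0, start=0.0, stop=ts, num=n1)
        t1 = np.linspace(0.0, ts, n1)
        state = traj1[-1, :M].copy()
        traj1 = traj1[:, :M]
    else:
        state = np.zeros(M)
        state[0] = a * N  # unit-area delta into the first cell
        t1 = np.array([0.0])
        traj1 = state[None, :].copy()

    n2 = max(2, int(np.ceil((t_end - ts) / dt)) + 1)
    traj2 = expm_multiply(A_run, state, start=0.0, stop=t_end - ts, num=n2)
    t2 = ts + np.linspace(0.0, t_end - ts, n2)

    t = np.concatenate([t1, t2[1:]])
    traj = np.concatenate([traj1, traj2[1:]], axis=0)
    x = traj[:, :N]
    z = traj[:, N:] if M > N else None
    return OracleResult(
        t=t,
        outlet=x[:, N - 1].copy(),
        x_final=x[-1].copy(),
        z_final=None if z is None else z[-1].copy(),
        mass=_mass(x, z, a, N, Nec if Nec else 1, b),
    )


def simulate_stage2(s: np.ndarray, *, K_D: float, a: float, N: int,
                    t_end: float, num: int = 2001) -> OracleResult:
    """Integrate the reversed (y-phase) cascade from column state ``s``.

    ``s`` holds the x-phase concentrations at the switch; the equilibrated
    y-phase starts at ``y_k(0) = K_D s_k`` and the outlet is cell 1.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (N,):
        raise ValueError(f"state vector must have length N={N}")
    rate = K_D * a * N
    A = sparse.lil_matrix((N, N))
    for k in range(N):
        A[k, k] = -rate
        if k < N - 1:
            A[k, k + 1] = rate
    traj = expm_multiply(A.tocsr(), K_D * s, start=0.0, stop=t_end, num=num)
    t = np.linspace(0.0, t_end, num)
    return OracleResult(
        t=t,
        outlet=traj[:, 0].copy(),
        x_final=traj[-1].copy(),
        z_final=None,
        mass=traj.sum(axis=-1) / (K_D * a * N),
    )


def _refined_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak position/height by quadratic interpolation around the maximum."""
    i = int(np.argmax(y))
    if 0 < i < len(t) - 1:
        c = np.polyfit(t[i - 1:i + 2], y[i - 1:i + 2], 2)
        if c[0] < 0.0:
            tp = -c[1] / (2.0 * c[0])
            return float(tp), float(np.polyval(c, tp))
    return float(t[i]), float(y[i])


def compare(t: np.ndarray, closed_form: np.ndarray,
            oracle_series: np.ndarray) -> dict[str, float]:
    """Error report between a closed-form series and the oracle's.

    Returns relative peak-time and area discrepancies and the sup-norm
    difference as a fraction of the oracle's peak height.
    """
    tp_c, _ = _refined_peak(t, closed_form)
    tp_o, yp_o = _refined_peak(t, oracle_series)
    area_c = float(np.trapezoid(closed_form, t))
    area_o = float(np.trapezoid(oracle_series, t))
    return {
        "peak_time_rel": abs(tp_c - tp_o) / abs(tp_o) if tp_o else 0.0,
        "area_rel": abs(area_c - area_o) / abs(area_o) if area_o else 0.0,
        "supnorm_over_peak": float(np.max(np.abs(closed_form - oracle_series))
                                   / yp_o) if yp_o else 0.0,
    }
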