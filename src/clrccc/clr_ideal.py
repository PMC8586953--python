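"""Stage-1 elution/column profiles under the ideal recycling model.

The column is a cascade of ``N`` equilibrium cells.  A band that has entered
cycle ``n`` and reached cell ``k`` after being loaded as a rectangular inlet
pulse of duration ``ts`` has, to the plate-model (Gaussian) approximation, a
unit-area profile in dimensionless time ``t`` with

    mean      m(n, k) = [ (n-1) + k/N + a*ts/2 ] / a
    variance  v(n, k) = [ (N(n-1)+k)/N^2 + (a*ts)^2/12 ] / a^2

where ``a`` is the velocity factor of the compound.  The variance is the sum
of the cascade dispersion accumulated over ``N(n-1)+k`` cells and the exact
``ts^2/12`` second moment of the rectangular loading pulse.

Every public profile function evaluates this Gaussian; each has a
``literal_*`` twin that evaluates the same closed form written as a single
algebraic expression (prefactor ``a N sqrt(6/(pi D))``, exponent
``-3[...]^2/(2D)`` with ``D = 12[N(n-1)+k] + (N a ts)^2``).  The two agree to
machine precision; tests assert it.

In the ideal model the recycling line is volume-free: consecutive cycles
differ only by the extra column passage.  Functions are vectorised over ``t``
(and ``k`` where noted).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = [
    "moments",
    "cell_profile",
    "outlet_profile",
    "summed_cell_profile",
    "summed_outlet_profile",
    "last_two_outlet",
    "impulse_cell_profile",
    "impulse_outlet_profile",
    "impulse_summed_cell_profile",
    "impulse_summed_outlet_profile",
    "impulse_last_two_outlet",
    "literal_cell_profile",
    "literal_outlet_profile",
]


def moments(n, k, *, a: float, N: int, ts: float = 0.0):
    """Analytic mean and variance of the single-cycle profile at cell k.

    Vectorised over ``n`` and ``k``.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    m = ((n - 1.0) + k / N + a * ts / 2.0) / a
    v = ((N * (n - 1.0) + k) / N**2 + (a * ts) ** 2 / 12.0) / a**2
    return m, v


def _gaussian(t, m, v):
    t = np.asarray(t, dtype=float)
    return np.exp(-((t - m) ** 2) / (2.0 * v)) / np.sqrt(2.0 * np.pi * v)


def cell_profile(t, n: int, k: int, *, a: float, N: int, ts: float = 0.0):
    """K_D-normalised concentration in cell k during cycle n (single cycle)."""
    _check_query(n, k, N)
    m, v = moments(n, k, a=a, N=N, ts=ts)
    return _gaussian(t, m, v)


def outlet_profile(t, n: int, *, a: float, N: int, ts: float = 0.0):
    """Column-outlet profile of cycle n; equals ``cell_profile`` at k = N."""
    return cell_profile(t, n, N, a=a, N=N, ts=ts)


def literal_cell_profile(t, n: int, k: int, *, a: float, N: int,
                         ts: float = 0.0):
    """Single-expression form: a N sqrt(6/(pi D)) exp(-3[...]^2 / (2D))."""
    _check_query(n, k, N)
    t = np.asarray(t, dtype=float)
    D = 12.0 * (N * (n - 1) + k) + (N * a * ts) ** 2
    arg = 2.0 * N * (n - 1) + 2.0 * k + N * a * ts - 2.0 * a * N * t
    return a * N * np.sqrt(6.0 / (np.pi * D)) * np.exp(-3.0 * arg**2 / (2.0 * D))


def literal_outlet_profile(t, n: int, *, a: float, N: int, ts: float = 0.0):
    return literal_cell_profile(t, n, N, a=a, N=N, ts=ts)


def _cycle_mass_in_window(m, v, t_lo, t_hi):
    s = np.sqrt(v)
    return norm.cdf(t_hi, m, s) - norm.cdf(t_lo, m, s)


def summed_cell_profile(t, n_max: int, k: int, *, a: float, N: int,
                        ts: float = 0.0, tail_tol: float = 1e-12):
    """Recycling profile at cell k: sum of cycles 1..n_max.

    Cycles whose Gaussian mass inside the span of ``t`` is below ``tail_tol``
    are skipped (set ``tail_tol=0`` for exact summation).
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    t_lo, t_hi = t.min(), t.max()
    for n in range(1, n_max + 1):
        m, v = moments(n, k, a=a, N=N, ts=ts)
        if tail_tol > 0.0 and t.size > 1:
            if _cycle_mass_in_window(m, v, t_lo, t_hi) < tail_tol:
                continue
        out += _gaussian(t, m, v)
    return out


def summed_outlet_profile(t, n_max: int, *, a: float, N: int,
                          ts: float = 0.0, tail_tol: float = 1e-12):
    """Outlet chromatogram over the whole recycling run (cycles 1..n_max)."""
    return summed_cell_profile(t, n_max, N, a=a, N=N, ts=ts,
                               tail_tol=tail_tol)


def last_two_outlet(t, n: int, *, a: float, N: int, ts: float = 0.0):
    """Outlet profile of the last two cycles, X(n-1,N,t) + X(n,N,t).

    A cheap stand-in for the full sum once earlier cycles have left the
    observation window; exact for n = 2.
    """
    if n < 2:
        raise ValueError(f"last_two_outlet requires n >= 2, got {n}")
    return (outlet_profile(t, n - 1, a=a, N=N, ts=ts)
            + outlet_profile(t, n, a=a, N=N, ts=ts))


# -- impulse-injection (ts = 0) family ------------------------------------
#
# Dedicated closed forms for the delta-injection limit; identical to the
# finite-loading forms evaluated at ts = 0.

def impulse_cell_profile(t, n: int, k: int, *, a: float, N: int):
    """aN exp(-[N(n-1)+k-aNt]^2 / (2[N(n-1)+k])) / sqrt(2 pi [N(n-1)+k])."""
    _check_query(n, k, N)
    t = np.asarray(t, dtype=float)
    p = N * (n - 1) + k  # cells traversed
    return a * N * np.exp(-((p - a * N * t) ** 2) / (2.0 * p)) / np.sqrt(
        2.0 * np.pi * p)


def impulse_outlet_profile(t, n: int, *, a: float, N: int):
    """a sqrt(N/(2 pi n)) exp(-N[n - a t]^2 / (2n))."""
    t = np.asarray(t, dtype=float)
    return a * np.sqrt(N / (2.0 * np.pi * n)) * np.exp(
        -N * (n - a * t) ** 2 / (2.0 * n))


def impulse_summed_cell_profile(t, n_max: int, k: int, *, a: float, N: int):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for n in range(1, n_max + 1):
        out += impulse_cell_profile(t, n, k, a=a, N=N)
    return out


def impulse_summed_outlet_profile(t, n_max: int, *, a: float, N: int):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    for n in range(1, n_max + 1):
        out += impulse_outlet_profile(t, n, a=a, N=N)
    return out


def impulse_last_two_outlet(t, n: int, *, a: float, N: int):
    if n < 2:
        raise ValueError(f"last-two form requires n >= 2, got {n}")
    return (impulse_outlet_profile(t, n - 1, a=a, N=N)
            + impulse_outlet_profile(t, n, a=a, N=N))


def _check_query(n: int, k: int, N: int) -> None:
    if n < 1:
        raise ValueError(f"cycle index n must be >= 1, got {n}")
    if not 1 <= k <= N:
        raise ValueError(f"cell index k must lie in 1..{N}, got {k}")
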