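"""Stage-1 profiles under the non-ideal recycling model (long line).

A recycling line of relative volume ``b = V_ec/V_c`` modelled as ``Nec``
perfectly mixed cells delays a band by ``b`` dimensionless time units per
completed loop passage and disperses it.  Material in cycle ``n`` has crossed
the line ``n - 1`` times, so the single-cycle Gaussian becomes

    mean      m'(n, k) = [ (n-1) + k/N + a*b*(n-1) + a*ts/2 ] / a
    variance  v'(n, k) = [ (N(n-1)+k)/N^2 + (a*ts)^2/12
                           + (n-1)*a^2*b^2/Nec ] / a^2

i.e. the line contributes a plug-flow delay ``b`` and an extra variance
``a^2 b^2 / Nec`` (in ``a*t`` units) per passage; ``Nec -> inf`` leaves the
delay but removes the extra dispersion, and ``b = 0`` recovers the ideal
model exactly.  ``literal_*`` twins carry the single-expression algebraic
form with ``D' = [12(N(n-1)+k) + (N a ts)^2] Nec + 12 N^2 a^2 (n-1) b^2``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .clr_ideal import _check_query, _gaussian

__all__ = [
    "moments",
    "cell_profile",
    "outlet_profile",
    "summed_cell_profile",
    "summed_outlet_profile",
    "last_two_outlet",
    "literal_cell_profile",
    "literal_outlet_profile",
]


def moments(n, k, *, a: float, N: int, ts: float = 0.0,
            Nec: int = 1, b: float = 0.0):
    """Analytic mean/variance of the cycle-n profile at cell k (long line)."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    loops = n - 1.0  # completed passages through the recycling line
    m = (loops + k / N + a * b * loops + a * ts / 2.0) / a
    v = ((N * loops + k) / N**2 + (a * ts) ** 2 / 12.0
         + loops * a**2 * b**2 / Nec) / a**2
    return m, v


def cell_profile(t, n: int, k: int, *, a: float, N: int, ts: float = 0.0,
                 Nec: int = 1, b: float = 0.0):
    """Single-cycle K_D-normalised concentration in cell k, long-line model."""
    _check_query(n, k, N)
    m, v = moments(n, k, a=a, N=N, ts=ts, Nec=Nec, b=b)
    return _gaussian(t, m, v)


def outlet_profile(t, n: int, *, a: float, N: int, ts: float = 0.0,
                   Nec: int = 1, b: float = 0.0):
    return cell_profile(t, n, N, a=a, N=N, ts=ts, Nec=Nec, b=b)


def literal_cell_profile(t, n: int, k: int, *, a: float, N: int,
                         ts: float = 0.0, Nec: int = 1, b: float = 0.0):
    """a N sqrt(6 Nec/(pi D')) exp(-3 Nec [...]^2 / (2 D'))."""
    _check_query(n, k, N)
    t = np.asarray(t, dtype=float)
    D = (12.0 * (N * (n - 1) + k) + (N * a * ts) ** 2) * Nec \
        + 12.0 * N**2 * a**2 * (n - 1) * b**2
    arg = (2.0 * N * (n - 1) + 2.0 * k + 2.0 * a * N * b * (n - 1)
           + a * N * ts - 2.0 * a * N * t)
    return a * N * np.sqrt(6.0 * Nec / (np.pi * D)) * np.exp(
        -3.0 * Nec * arg**2 / (2.0 * D))


def literal_outlet_profile(t, n: int, *, a: float, N: int, ts: float = 0.0,
                           Nec: int = 1, b: float = 0.0):
    return literal_cell_profile(t, n, N, a=a, N=N, ts=ts, Nec=Nec, b=b)


def summed_cell_profile(t, n_max: int, k: int, *, a: float, N: int,
                        ts: float = 0.0, Nec: int = 1, b: float = 0.0,
                        tail_tol: float = 1e-12):
    """Recycling profile at cell k: sum of cycles 1..n_max (long line)."""
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    t_lo, t_hi = t.min(), t.max()
    for n in range(1, n_max + 1):
        m, v = moments(n, k, a=a, N=N, ts=ts, Nec=Nec, b=b)
        if tail_tol > 0.0 and t.size > 1:
            s = np.sqrt(v)
            if norm.cdf(t_hi, m, s) - norm.cdf(t_lo, m, s) < tail_tol:
                continue
        out += _gaussian(t, m, v)
    return out


def summed_outlet_profile(t, n_max: int, *, a: float, N: int,
                          ts: float = 0.0, Nec: int = 1, b: float = 0.0,
                          tail_tol: float = 1e-12):
    return summed_cell_profile(t, n_max, N, a=a, N=N, ts=ts, Nec=Nec, b=b,
                               tail_tol=tail_tol)


def last_two_outlet(t, n: int, *, a: float, N: int, ts: float = 0.0,
                    Nec: int = 1, b: float = 0.0):
    """X(n-1,N,t) + X(n,N,t); the (n-1) term carries n-2 loop passages."""
    if n < 2:
        raise ValueError(f"last_two_outlet requires n >= 2, got {n}")
    return (outlet_profile(t, n - 1, a=a, N=N, ts=ts, Nec=Nec, b=b)
            + outlet_profile(t, n, a=a, N=N, ts=ts, Nec=Nec, b=b))
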