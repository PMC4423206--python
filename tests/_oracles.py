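"""Independent numerical oracles used by the tests.

These deliberately re-derive results through different algorithms than
the package (fixed-step integrators instead of adaptive ones) so that
agreement is evidence of correctness rather than tautology.
"""

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(f):
        return f


@njit(cache=False)
def _rk4_cr(e, a, b, d_T, r0, K_N, T0, N0, t_grid, dt):
    out_T = np.empty(t_grid.size)
    out_N = np.empty(t_grid.size)
    T, N = T0, N0
    t = t_grid[0]
    out_T[0], out_N[0] = T, N
    for k in range(1, t_grid.size):
        target = t_grid[k]
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1T, k1N = _cr_rhs(T, N, e, a, b, d_T, r0, K_N)
            k2T, k2N = _cr_rhs(T + 0.5 * h * k1T, N + 0.5 * h * k1N, e, a, b, d_T, r0, K_N)
            k3T, k3N = _cr_rhs(T + 0.5 * h * k2T, N + 0.5 * h * k2N, e, a, b, d_T, r0, K_N)
            k4T, k4N = _cr_rhs(T + h * k3T, N + h * k3N, e, a, b, d_T, r0, K_N)
            T += h / 6.0 * (k1T + 2 * k2T + 2 * k3T + k4T)
            N += h / 6.0 * (k1N + 2 * k2N + 2 * k3N + k4N)
            if T < 0.0:
                T = 0.0
            if N < 0.0:
                N = 0.0
            t += h
        out_T[k], out_N[k] = T, N
    return out_T, out_N


@njit(cache=False)
def _cr_rhs(T, N, e, a, b, d_T, r0, K_N):
    intake = a * N / (N + b)
    return e * intake * T - d_T * T, r0 * N * (1.0 - N / K_N) - intake * T


def rk4_consumer_resource(p, t_grid, dt=1e-3):
    """Fixed-step RK4 solution of the consumer--resource system."""
    t_grid = np.asarray(t_grid, dtype=float)
    return _rk4_cr(p.e, p.a, p.b, p.d_T, p.r0, p.K_N, p.T0, p.N0, t_grid, dt)


@njit(cache=False)
def euler_logistic(r, K, T0, t_end, dt=1e-6):
    """Forward-Euler integration of dT/dt = r T (1 - T/K); returns T(t_end).

    Euler's O(dt) global error needs dt=1e-6 to resolve 1e-6 relative
    agreement (at dt=1e-4 the discretisation error is already ~2e-5).
    """
    n = int(round(t_end / dt))
    T = T0
    for _ in range(n):
        T += dt * r * T * (1.0 - T / K)
    return T
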