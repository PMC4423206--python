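"""Deterministic population-growth models.

Two descriptions of consumer growth in a closed microcosm:

* a phenomenological logistic r--K model, and
* a mechanistic Rosenzweig--MacArthur consumer--resource model with a
  type II functional response, in which the consumer (e.g. the ciliate
  *Tetrahymena*) harvests a logistically growing resource (bacteria).

The consumer--resource system is

    dT/dt = e * a * N / (N + b) * T - d_T * T
    dN/dt = r0 * N * (1 - N / K_N) - a * N / (N + b) * T

with ``T`` the consumer density, ``N`` the resource density, ``e`` the
assimilation coefficient, ``a`` the maximum intake rate, ``b`` the
half-saturation constant (``1/b`` is the foraging efficiency) and ``d_T``
the consumer death rate.  Time is in hours, consumer densities in
individuals per ml, resources in bacterial-count units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "LogisticParams",
    "CRParams",
    "GrowthSeries",
    "IntegrationError",
    "logistic_density",
    "functional_response",
    "cr_derivatives",
    "simulate_cr",
    "growth_rate_vs_resources",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value):
            raise ValueError(f"parameter {name!r} must be finite, got {value!r}")


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of logistic r--K growth.

    r : intrinsic growth rate (per hour)
    K : carrying capacity (individuals per ml)
    T0 : initial density (individuals per ml)
    """

    r: float
    K: float
    T0: float

    def __post_init__(self) -> None:
        _require_finite(r=self.r, K=self.K, T0=self.T0)
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.T0 <= 0:
            raise ValueError(f"T0 must be > 0, got {self.T0}")


@dataclass(frozen=True)
class CRParams:
    """Parameters and initial state of the consumer--resource system.

    e : assimilation coefficient (offspring per resource unit)
    a : maximum intake rate (resource units per consumer per hour)
    b : half-saturation constant of the type II functional response
    d_T : consumer death rate (per hour)
    r0 : resource growth rate (per hour)
    K_N : resource carrying capacity (resource units)
    T0, N0 : initial consumer and resource densities
    """

    e: float
    a: float
    b: float
    d_T: float
    r0: float
    K_N: float
    T0: float
    N0: float

    def __post_init__(self) -> None:
        _require_finite(e=self.e, a=self.a, b=self.b, d_T=self.d_T,
                        r0=self.r0, K_N=self.K_N, T0=self.T0, N0=self.N0)
        for name in ("e", "a", "b", "K_N"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.d_T < 0 or self.r0 < 0 or self.T0 < 0:
            raise ValueError("d_T, r0 and T0 must be >= 0")
        if not (0 < self.N0 <= self.K_N * (1 + 1e-12)):
            raise ValueError(f"N0 must lie in (0, K_N], got {self.N0}")


@dataclass
class GrowthSeries:
    """A (time, density) growth curve of a consumer population."""

    times: np.ndarray
    densities: np.ndarray
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.shape != self.densities.shape or self.times.ndim != 1:
            raise ValueError("times and densities must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.densities)) or np.any(self.densities < 0):
            raise ValueError("densities must be finite and non-negative")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_h": self.times, "density_per_ml": self.densities}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "GrowthSeries":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("time_h", "density_per_ml"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in {path}")
            if df[col].isna().any():
                raise ValueError(f"missing values in column {col!r} of {path}")
        return cls(df["time_h"].to_numpy(), df["density_per_ml"].to_numpy())


def logistic_density(p: LogisticParams, t) -> np.ndarray | float:
    """Closed-form logistic solution T(t) = K / (1 + (K/T0 - 1) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.K / (1.0 + (p.K / p.T0 - 1.0) * np.exp(-p.r * t))
    return out if out.ndim else float(out)


def functional_response(a: float, b: float, N) -> np.ndarray | float:
    """Type II per-capita intake rate a*N/(N+b)."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be > 0")
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("resource density N must be >= 0")
    out = a * N / (N + b)
    return out if out.ndim else float(out)


def cr_derivatives(T: float, N: float, p: CRParams) -> tuple[float, float]:
    """Right-hand side (dT/dt, dN/dt) of the consumer--resource system."""
    if T < 0 or N < 0:
        raise ValueError("state must be non-negative")
    intake = p.a * N / (N + p.b)
    dT = p.e * intake * T - p.d_T * T
    dN = p.r0 * N * (1.0 - N / p.K_N) - intake * T
    return dT, dN


def simulate_cr(
    p: CRParams,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the consumer--resource system at the requested times.

    The initial state ``(T0, N0)`` applies at ``times[0]``.  Tiny negative
    solver excursions are clipped to zero.  Returns ``(consumer, resource)``
    arrays aligned with ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D sequence")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with times[0] >= 0")

    def rhs(t, y):
        T, N = y
        # the solver may step slightly negative; evaluate on the clipped state
        T = max(T, 0.0)
        N = max(N, 0.0)
        intake = p.a * N / (N + p.b)
        return (p.e * intake * T - p.d_T * T,
                p.r0 * N * (1.0 - N / p.K_N) - intake * T)

    if times.size == 1:
        return np.array([p.T0]), np.array([p.N0])

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        (p.T0, p.N0),
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else float(times[0])
        raise IntegrationError(f"ODE integration failed: {sol.message}", last)
    consumer = np.clip(sol.y[0], 0.0, None)
    resource = np.clip(sol.y[1], 0.0, None)
    return consumer, resource


def growth_rate_vs_resources(p: CRParams, N) -> np.ndarray | float:
    """Per-capita consumer growth rate (birth minus death) at resource level N.

    This is the resource-dependent fitness e*a*N/(N+b) - d_T.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("resource density N must be >= 0")
    out = p.e * p.a * N / (N + p.b) - p.d_T
    return out if out.ndim else float(out)
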