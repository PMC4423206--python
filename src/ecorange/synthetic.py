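"""Synthetic data generators.

These emulate the statistical structure of microcosm observations so the
fitting and trajectory pipelines can be exercised end to end:

* growth curves sampled at the experiment's cadence (daily over ten days,
  denser at the start) with small-aliquot counting noise — observed
  density is a Poisson count in the sampled volume divided by that
  volume, which matches microscopy counting of a 150 ul aliquot and
  approaches Gaussian noise at high counts;
* correlated random walks at 25 frames/s over 20 s (500 frames) with a
  fixed step speed and wrapped-normal turning angles;
* a two-treatment "core vs margin" scenario in which the range-margin
  population has a lower foraging efficiency (larger half-saturation
  constant ``b``) but the same assimilation coefficient, and swims
  faster — the qualitative contrast the downstream pipeline should
  recover.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cr_models import CRParams, GrowthSeries, LogisticParams, logistic_density, simulate_cr
from .trajectory import DEFAULT_FPS, MovementPath

__all__ = [
    "SamplingDesign",
    "ScenarioData",
    "CORE_TRUTH",
    "MARGIN_TRUTH",
    "generate_growth_curves",
    "generate_crw_paths",
    "generate_core_margin_scenario",
]

# daily sampling over 10 days with two extra early points (hours)
DEFAULT_TIMES_H = np.array(
    [0.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0, 216.0, 240.0]
)

# Reference truths for the two-treatment scenario.  The consumer starts
# from a stock at equilibrium density (~1e4 per ml, diluted tenfold into
# fresh medium by the sampling design) and harvests bacteria whose
# growth rate and carrying capacity match the fixed fitting constants.
# "Margin" differs from "core" only in a lower foraging efficiency 1/b.
# Both sit in the damped (stable-focus) regime of the consumer-resource
# system -- the core equilibrium resource level exceeds (K_N - b)/2 -- so
# curves rise to a plateau with at most a mild overshoot rather than
# cycling, as observed microcosm growth curves do.
CORE_TRUTH = CRParams(
    e=2.0e-4, a=1200.0, b=2.0e7, d_T=0.10,
    r0=0.24, K_N=3.6e7, T0=1.0e4, N0=3.6e7,
)
MARGIN_TRUTH = replace(CORE_TRUTH, b=3.2e7)

CORE_SPEED = 300.0  # um/s
MARGIN_SPEED = 390.0  # +30% at the margin
DEFAULT_CIRC_SD = 0.6  # radians; turning spread does not differ by treatment


@dataclass(frozen=True)
class SamplingDesign:
    """When and how densely the growth curves are sampled.

    ``aliquot_ml`` is the counted sample volume (Poisson counting noise
    scales with it); ``dilution`` is the dilution factor applied to the
    stock when the common garden is started.
    """

    times_h: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES_H.copy())
    aliquot_ml: float = 0.15
    dilution: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.aliquot_ml <= 0 or self.dilution < 1:
            raise ValueError("aliquot_ml must be > 0 and dilution >= 1")


def _true_curve(truth, design: SamplingDesign):
    """Effective (diluted) parameters and the noiseless model curve."""
    if isinstance(truth, CRParams):
        eff = replace(truth, T0=truth.T0 / design.dilution)
        consumer, _ = simulate_cr(eff, design.times_h)
        return eff, consumer
    if isinstance(truth, LogisticParams):
        eff = replace(truth, T0=truth.T0 / design.dilution)
        return eff, np.asarray(logistic_density(eff, design.times_h))
    raise TypeError(f"unsupported truth type {type(truth).__name__}")


def generate_growth_curves(
    truth,
    design: SamplingDesign | None = None,
    n_replicates: int = 6,
    seed: int = 0,
):
    """Simulate replicate growth curves with aliquot counting noise.

    The observed density at each time is Poisson(true density x aliquot)
    divided by the aliquot volume (exactly the true density when the
    aliquot is infinite).  Returns ``(replicates, true_series, eff)``
    where ``eff`` is the truth with the dilution applied to T0.
    """
    design = design or SamplingDesign()
    eff, true_dens = _true_curve(truth, design)
    true_series = GrowthSeries(design.times_h, true_dens, label="true")
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    reps = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        if np.isinf(design.aliquot_ml):
            obs = true_dens.copy()
        else:
            obs = rng.poisson(true_dens * design.aliquot_ml) / design.aliquot_ml
        reps.append(GrowthSeries(design.times_h, obs, label=f"rep{i}"))
    return reps, true_series, eff


def generate_crw_paths(
    speed: float,
    circ_sd: float,
    n_paths: int = 100,
    n_frames: int = 500,
    fps: float = DEFAULT_FPS,
    seed: int = 0,
) -> list[MovementPath]:
    """Correlated random walks with constant step length ``speed/fps``.

    Headings start uniform and accumulate wrapped-normal increments of
    s.d. ``circ_sd``; ``circ_sd=0`` gives perfectly straight paths.
    """
    if speed < 0 or circ_sd < 0:
        raise ValueError("speed and circ_sd must be >= 0")
    rng = np.random.default_rng(seed)
    step = speed / fps
    paths = []
    for i in range(n_paths):
        turns = rng.normal(0.0, circ_sd, size=n_frames - 2) if n_frames > 2 else np.empty(0)
        headings = np.concatenate([[rng.uniform(-np.pi, np.pi)], turns]).cumsum()
        x = np.concatenate([[0.0], step * np.cos(headings)]).cumsum()
        y = np.concatenate([[0.0], step * np.sin(headings)]).cumsum()
        paths.append(MovementPath(x, y, frame_interval=1.0 / fps, path_id=i))
    return paths


@dataclass
class ScenarioData:
    """End-to-end fixture contrasting range-core and range-margin samples."""

    growth: dict[str, list[GrowthSeries]]
    true_growth: dict[str, GrowthSeries]
    truths: dict[str, CRParams]
    paths: dict[str, list[MovementPath]]
    speeds: dict[str, float]
    design: SamplingDesign


def generate_core_margin_scenario(
    seed: int = 0,
    n_replicates: int = 6,
    n_paths: int = 40,
    design: SamplingDesign | None = None,
    equal_truth: bool = False,
) -> ScenarioData:
    """Two labelled treatments from consumer--resource truths.

    By default "margin" has a lower foraging efficiency (same ``e``,
    larger ``b``) and a 30% higher swimming speed than "core".  With
    ``equal_truth=True`` both labels share the core truth and speed — a
    null fixture in which any recovered ordering is spurious.
    """
    design = design or SamplingDesign()
    truths = {
        "core": CORE_TRUTH,
        "margin": CORE_TRUTH if equal_truth else MARGIN_TRUTH,
    }
    speeds = {
        "core": CORE_SPEED,
        "margin": CORE_SPEED if equal_truth else MARGIN_SPEED,
    }
    ss = np.random.SeedSequence(seed).spawn(4)
    growth, true_growth = {}, {}
    for (label, truth), child in zip(truths.items(), ss[:2]):
        reps, true_series, _ = generate_growth_curves(
            truth, design, n_replicates=n_replicates,
            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
        )
        growth[label] = reps
        true_growth[label] = true_series
    paths = {
        label: generate_crw_paths(
            speeds[label], DEFAULT_CIRC_SD, n_paths=n_paths,
            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
        )
        for (label, child) in zip(("core", "margin"), ss[2:])
    }
    return ScenarioData(
        growth=growth, true_growth=true_growth, truths=truths,
        paths=paths, speeds=speeds, design=design,
    )
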