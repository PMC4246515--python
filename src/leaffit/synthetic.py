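"""Synthetic beta-sigmoid growth series and cell-length profiles.

Emulates the measurement regimes of real grass phenotyping experiments:
leaf length read daily with a ruler (additive Gaussian error, a few mm on
a half-metre leaf), and cell lengths read along the leaf axis under a
microscope, where scatter is large and scales with cell size
(multiplicative noise).  Every draw is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .errors import ParameterDomainError
from .fitting import CellProfile, LeafSeries
from .models import CellProfileParams, GrowthParams

__all__ = [
    "SimulationSpec",
    "simulate_leaf_series",
    "simulate_cell_profile",
    "simulate_cohort",
    "CONTROL_LIKE",
    "TRANSGENIC_LIKE",
    "CONTROL_PROFILE_LIKE",
    "TRANSGENIC_PROFILE_LIKE",
]

# Reference cohorts for end-to-end tests: a wild-type-like maize leaf and a
# longer, later GA-overexpressor-like one; basal cell profiles to match.
CONTROL_LIKE = GrowthParams(Lm=535.0, t0=0.0, tm=167.0, te=231.0)
TRANSGENIC_LIKE = GrowthParams(Lm=743.0, t0=0.0, tm=180.0, te=246.0)
CONTROL_PROFILE_LIKE = CellProfileParams(Lb=10.9, Lm=118.5, Pm=21.3, Pe=43.4)
TRANSGENIC_PROFILE_LIKE = CellProfileParams(Lb=13.2, Lm=118.1, Pm=29.5, Pe=56.6)


@dataclass(frozen=True)
class SimulationSpec:
    """Sampling schedule and noise model for one simulated series.

    ``start + step * [0..count)`` defines the abscissa (°Cd for growth,
    mm for profiles).  ``sd`` adds Gaussian noise in measurement units;
    ``cv`` adds multiplicative Gaussian noise (fractional).  Both default
    to zero; either or both may be used.
    """

    params: object
    start: float = 0.0
    step: float = 14.0
    count: int = 18
    sd: float = 0.0
    cv: float = 0.0
    seed: int | None = None
    leaf_id: str = "sim"
    group: str = "sim"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ParameterDomainError("step must be > 0")
        if self.count < 2:
            raise ParameterDomainError("count must be >= 2")
        if self.sd < 0 or self.cv < 0:
            raise ParameterDomainError("noise levels must be >= 0")

    def schedule(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)


def simulate_leaf_series(spec: SimulationSpec) -> LeafSeries:
    """Draw one leaf-length series: model curve plus noise, floored at 0."""
    if not isinstance(spec.params, GrowthParams):
        raise ParameterDomainError("spec.params must be GrowthParams")
    t = spec.schedule()
    y = np.asarray(models.length_at(spec.params, t), dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.cv > 0:
        y = y * (1.0 + spec.cv * rng.standard_normal(t.size))
    if spec.sd > 0:
        y = y + spec.sd * rng.standard_normal(t.size)
    y = np.clip(y, 0.0, None)
    return LeafSeries(leaf_id=spec.leaf_id, group=spec.group, t=t, length=y)


def simulate_cell_profile(spec: SimulationSpec) -> CellProfile:
    """Draw one cell-length profile; noisy values floored at 0.1 μm."""
    if not isinstance(spec.params, CellProfileParams):
        raise ParameterDomainError("spec.params must be CellProfileParams")
    p = spec.schedule()
    y = np.asarray(models.cell_length_at(spec.params, p), dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.cv > 0:
        y = y * (1.0 + spec.cv * rng.standard_normal(p.size))
    if spec.sd > 0:
        y = y + spec.sd * rng.standard_normal(p.size)
    y = np.clip(y, 0.1, None)
    return CellProfile(leaf_id=spec.leaf_id, group=spec.group,
                       position=p, cell_length=y)


def simulate_cohort(
    params: GrowthParams,
    n: int,
    seed: int,
    group: str = "control",
    sd: float = 5.0,
    param_cv: float = 0.03,
    step: float = 14.0,
    count: int = 18,
) -> list[LeafSeries]:
    """Simulate a cohort of replicate leaves around shared mean parameters.

    Each plant gets its own parameters, jittered multiplicatively with
    coefficient of variation ``param_cv`` (between-plant biological
    variation), then a measurement series with additive noise ``sd`` mm.
    Defaults emulate daily measurements of a maize leaf at a constant
    14 °Cd/day.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        jit = 1.0 + param_cv * rng.standard_normal(3)
        lm = params.Lm * jit[0]
        tm = params.tm * jit[1]
        te = params.te * jit[2]
        if te <= tm:  # keep the ordering under extreme draws
            te = tm + 0.05 * params.te
        plant = GrowthParams(Lm=lm, t0=params.t0, tm=tm, te=te)
        spec = SimulationSpec(
            params=plant,
            step=step,
            count=count,
            sd=sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            leaf_id=f"{group}_{i + 1}",
            group=group,
        )
        cohort.append(simulate_leaf_series(spec))
    return cohort
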