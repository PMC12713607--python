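"""Hands-free composition: base scheduler -> uniform prefix -> TM filter -> polisher.

The two decoherence stages are applied in a fixed order — the local
Thue-Morse filter first, the global PSF polisher second — because the TM
filter can itself introduce weak global biases that the polisher then
treats.  The composed procedure is referred to as TMPF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import ScheduleReport, build_report
from .polisher import DEFAULT_SWAP_COST, DEFAULT_TAU, polish
from .schedule import SamplingSchedule
from .schedulers import (
    WeightingDensity,
    apply_uniform_prefix,
    averaged_schedule,
    density_exponential,
    density_sine_chord,
    poisson_gap_schedule,
    quantile_schedule,
    random_unweighted_schedule,
)
from .tm_filter import tm_filter

__all__ = ["RunConfig", "run_tmpf", "base_schedule", "METHODS"]

METHODS = ("quantile", "pg", "exponential", "ru")

#: replicates used for schedule-averaged exponential schedules
EXPONENTIAL_REPLICATES = 512


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one schedule generation run."""

    grid_size: int
    sample_count: int
    method: str = "quantile"
    seed: int = 0
    tm_offset: int = 0
    tm_start_symbol: int = 1
    tau: float = DEFAULT_TAU
    swap_cost: float = DEFAULT_SWAP_COST
    uniform_prefix: int | None = None  # None -> method default (2 weighted, 0 ru)
    backfill: int = 0
    one_based: bool = False
    tmpf: bool = True
    protect_endpoints: bool = True
    exponential_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 1 <= self.sample_count <= self.grid_size:
            raise ValueError("require 1 <= sample_count <= grid_size")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must lie in (0, 1]")
        if self.swap_cost < 0 or self.backfill < 0 or self.tm_offset < 0:
            raise ValueError("costs, backfill and tm_offset must be non-negative")

    @property
    def effective_prefix(self) -> int:
        if self.uniform_prefix is not None:
            return self.uniform_prefix
        return 0 if self.method == "ru" else 2

    def describe(self) -> list[str]:
        """Key=value lines for schedule-file provenance comments."""
        return [
            f"{k}={v}"
            for k, v in sorted(vars(self).items())
        ]


def _weighting(config: RunConfig) -> WeightingDensity | None:
    if config.method == "quantile":
        return density_sine_chord(config.grid_size)
    if config.method == "exponential":
        return density_exponential(config.grid_size, config.exponential_decay)
    return None


def base_schedule(config: RunConfig) -> SamplingSchedule:
    """Generate the unfiltered base schedule for a config."""
    N, n = config.grid_size, config.sample_count
    if config.method == "quantile":
        return quantile_schedule(N, n, _weighting(config))
    if config.method == "pg":
        return poisson_gap_schedule(N, n, config.seed)
    if config.method == "exponential":
        return averaged_schedule(
            N, n, _weighting(config), EXPONENTIAL_REPLICATES, config.seed
        )
    return random_unweighted_schedule(N, n - config.backfill, config.seed,
                                      backfill=config.backfill)


def run_tmpf(config: RunConfig) -> tuple[SamplingSchedule, ScheduleReport]:
    """Run the full hands-free pipeline and report metrics for the result."""
    schedule = base_schedule(config)
    prefix = min(config.effective_prefix, config.sample_count)
    if prefix:
        schedule = apply_uniform_prefix(schedule, prefix, _weighting(config))
    if not config.tmpf:
        return schedule, build_report(schedule)
    tm_result = tm_filter(
        schedule,
        start_symbol=config.tm_start_symbol,
        offset=config.tm_offset,
        protect_endpoints=config.protect_endpoints,
    )
    polished, trace = polish(
        tm_result.schedule,
        tau=config.tau,
        swap_cost=config.swap_cost,
        protect_endpoints=config.protect_endpoints,
    )
    return polished, build_report(polished, tm_result, trace)
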