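"""Feedback controller for tolerance adaptive laboratory evolution (TALE).

The controller closes the loop around serial batch passaging: cultures are
passed once they reach a plate-reader OD600 threshold, the stressor
concentration is raised by a fixed step once fitted growth rates have met a
threshold for a window of consecutive flasks, and an over-stressed crash
(culture never reaching the passage OD within a timeout) reverts the
concentration to the previous level and halves the step, so the controller
re-approaches the tolerance boundary more cautiously.

The "culture" the controller drives is anything implementing the small
:class:`Culture` protocol -- the stochastic simulator
(:class:`SimulatedCulture`) or a deterministic stand-in for recorded OD
streams (:class:`ConstantRateCulture`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .growth import InsufficientDataError, ODSeries, fit_rate
from .simulate import (
    FlaskResult,
    Lineage,
    SimConfig,
    bottleneck,
    child_rng,
    simulate_flask,
)

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "FlaskLogEntry",
    "TaleResult",
    "TaleRunError",
    "Culture",
    "ConstantRateCulture",
    "SimulatedCulture",
    "should_pass",
    "next_concentration",
    "run_tale",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable parameters of the TALE control loop.

    Defaults follow common automated-ALE practice: passage at plate OD600
    0.3, a 1:100 transfer, escalation once the growth rate is >= 0.15 h^-1
    for 3 consecutive flasks, a 0.75 % (w/v) concentration step halved after
    each crash, and a 72 h crash timeout.
    """

    passage_od: float = 0.3
    dilution: float = 0.01
    rate_threshold: float = 0.15
    window_flasks: int = 3
    step_pct: float = 0.75
    step_reduction: float = 0.5
    crash_timeout_h: float = 72.0
    max_flasks: int = 70
    od_fit_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.dilution < 1):
            raise ValueError("dilution must be in (0, 1)")
        if self.passage_od <= 0:
            raise ValueError("passage_od must be positive")
        if self.step_pct <= 0:
            raise ValueError("step_pct must be positive")
        if not (0 < self.step_reduction < 1):
            raise ValueError("step_reduction must be in (0, 1)")
        if self.window_flasks < 1:
            raise ValueError("window_flasks must be >= 1")


@dataclass(frozen=True)
class FlaskLogEntry:
    flask_index: int
    concentration: float
    rate: float
    crashed: bool


@dataclass
class ControllerState:
    """Mutable record of a TALE run's control variables."""

    current_conc: float
    previous_conc: float
    current_step: float
    flask_log: list[FlaskLogEntry] = field(default_factory=list)
    n_increases: int = 0
    n_crashes: int = 0


@dataclass(frozen=True)
class TaleResult:
    state: ControllerState
    flasks: tuple[FlaskResult, ...]


class TaleRunError(RuntimeError):
    """A culture stream failed mid-flask; the partial log is preserved."""

    def __init__(self, message: str, result: TaleResult) -> None:
        super().__init__(message)
        self.result = result


def should_pass(series: ODSeries, config: ControllerConfig) -> bool:
    """True iff the latest plate-reader OD has reached the passage threshold."""
    if len(series) == 0:
        raise ValueError("empty OD series")
    return bool(series.ods[-1] >= config.passage_od)


def next_concentration(
    state: ControllerState,
    latest_rates: Sequence[float],
    crashed: bool,
    config: ControllerConfig,
) -> ControllerState:
    """Apply the TALE escalation / crash-recovery rule.

    ``latest_rates`` are the fitted growth rates of the flasks run at the
    current concentration (i.e. since the last concentration change).  On a
    crash the concentration reverts to the previous level and the step is
    multiplied by ``step_reduction``; otherwise, if the last
    ``window_flasks`` rates all meet ``rate_threshold`` the concentration is
    raised by the current step (applied to the next flask's medium).
    """
    if crashed:
        return replace(
            state,
            current_conc=state.previous_conc,
            current_step=state.current_step * config.step_reduction,
            n_crashes=state.n_crashes + 1,
        )
    w = config.window_flasks
    if len(latest_rates) >= w:
        window = list(latest_rates)[-w:]
        if all(not math.isnan(r) and r >= config.rate_threshold for r in window):
            return replace(
                state,
                previous_conc=state.current_conc,
                current_conc=state.current_conc + state.current_step,
                n_increases=state.n_increases + 1,
            )
    return state


class Culture(Protocol):
    """What the controller needs from a culture: grow one flask, then passage."""

    def grow(self, concentration: float, flask_index: int) -> FlaskResult: ...

    def passage(self, flask_index: int) -> None: ...


class ConstantRateCulture:
    """Deterministic culture growing at a fixed rate, for closed-form checks
    and for replaying idealized recorded OD streams.

    With ``rate = 0`` the culture never reaches the passage OD and every
    flask crashes.
    """

    def __init__(
        self,
        rate: float,
        start_od: float = 0.003,
        passage_od: float = 0.3,
        timeout_h: float = 72.0,
        sample_dt: float = 0.5,
    ) -> None:
        self.rate = rate
        self.start_od = start_od
        self.passage_od = passage_od
        self.timeout_h = timeout_h
        self.sample_dt = sample_dt

    def grow(self, concentration: float, flask_index: int) -> FlaskResult:
        if self.rate > 0:
            t_pass = math.log(self.passage_od / self.start_od) / self.rate
        else:
            t_pass = math.inf
        crashed = t_pass > self.timeout_h
        duration = self.timeout_h if crashed else t_pass
        grid = np.arange(0.0, duration, self.sample_dt)
        if grid.size == 0 or grid[-1] < duration:
            grid = np.append(grid, duration)
        ods = self.start_od * np.exp(self.rate * grid)
        return FlaskResult(
            flask_index=flask_index,
            concentration=concentration,
            od_series=ODSeries(times=grid, ods=ods),
            lineage_snapshot=(),
            crashed=crashed,
            duration_h=duration,
        )

    def passage(self, flask_index: int) -> None:
        pass


class SimulatedCulture:
    """Adapter driving :mod:`talekit.simulate` as a TALE culture.

    Starts from a single wild-type lineage at the inoculum density implied
    by the passage OD and dilution.  On a crash the inoculum is reused (the
    wet-lab analogue: re-inoculating from the last healthy flask), so the
    lineage state is unchanged until the next successful passage.
    """

    def __init__(
        self,
        sim_config: SimConfig,
        controller_config: ControllerConfig | None = None,
        *,
        seed: int | None = None,
        population_index: int = 0,
        label: str = "pop1",
    ) -> None:
        self.sim_config = sim_config
        self.cc = controller_config or ControllerConfig()
        self.seed = sim_config.seed if seed is None else seed
        self.population_index = population_index
        self.label = label
        inoculum = (
            self.cc.passage_od
            * sim_config.plate_ratio
            * sim_config.cells_per_od
            * sim_config.volume_ml
            * self.cc.dilution
        )
        self.lineages: list[Lineage] = [
            Lineage(id="wt", mutations=(), tolerance=sim_config.ic50_wt, size=inoculum)
        ]
        self._grown: FlaskResult | None = None
        self._last_good: FlaskResult | None = None

    def grow(self, concentration: float, flask_index: int) -> FlaskResult:
        rng = child_rng(self.seed, self.population_index, flask_index, 0)
        fr = simulate_flask(
            self.lineages,
            concentration,
            self.sim_config,
            passage_od=self.cc.passage_od,
            timeout_h=self.cc.crash_timeout_h,
            rng=rng,
            flask_index=flask_index,
            allele_prefix=f"{self.label}:",
        )
        self._grown = fr
        if not fr.crashed:
            self._last_good = fr
        return fr

    def passage(self, flask_index: int) -> None:
        if self._grown is None:
            raise RuntimeError("passage() called before grow()")
        rng = child_rng(self.seed, self.population_index, flask_index, 1)
        transferred = bottleneck(
            self._grown.lineage_snapshot, self.cc.dilution, self.sim_config, rng=rng
        )
        if transferred:
            self.lineages = transferred

    @property
    def final_lineages(self) -> tuple[Lineage, ...]:
        """Lineage state of the last flask that reached the passage OD."""
        src = self._last_good or self._grown
        if src is None:
            return tuple(self.lineages)
        return src.lineage_snapshot


def run_tale(
    culture: Culture,
    config: ControllerConfig,
    start_conc: float,
) -> TaleResult:
    """Run the closed TALE loop for up to ``max_flasks`` flasks.

    Each iteration grows one flask, fits the growth rate on the semi-log
    window, logs the flask, and applies the escalation / crash rule.  The
    rate window resets whenever the concentration changes, so escalation
    requires ``window_flasks`` qualifying flasks at the *current*
    concentration.
    """
    if start_conc < 0:
        raise ValueError("start_conc must be non-negative")
    state = ControllerState(
        current_conc=start_conc, previous_conc=start_conc, current_step=config.step_pct
    )
    rates_at_conc: list[float] = []
    flasks: list[FlaskResult] = []
    for i in range(config.max_flasks):
        try:
            fr = culture.grow(state.current_conc, i)
        except Exception as exc:
            raise TaleRunError(
                f"culture stream ended during flask {i}: {exc}",
                TaleResult(state=state, flasks=tuple(flasks)),
            ) from exc
        try:
            rate = fit_rate(fr.od_series, config.od_fit_min, config.passage_od).rate
        except InsufficientDataError:
            rate = float("nan")
        state.flask_log.append(
            FlaskLogEntry(
                flask_index=i,
                concentration=fr.concentration,
                rate=rate,
                crashed=fr.crashed,
            )
        )
        flasks.append(fr)
        if fr.crashed:
            state = next_concentration(state, [], True, config)
            rates_at_conc = []
        else:
            rates_at_conc.append(rate)
            before = state.current_conc
            state = next_concentration(state, rates_at_conc, False, config)
            if state.current_conc != before:
                rates_at_conc = []
            culture.passage(i)
    return TaleResult(state=state, flasks=tuple(flasks))
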