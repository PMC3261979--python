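"""Integrate composed mixture models under inhalation exposure scenarios.

A scenario is a piecewise-constant inhaled-air concentration schedule per
chemical (ppm converted to nmol/mL via the ideal-gas molar volume).  The
integrator restarts at every exposure switch time and every requested
output time, so discontinuities in C_inh are never smeared across a step.

The stiff compiled Rosenbrock kernel does the work (binding subsystems have
rate constants up to ~2e4 min^-1); default tolerances are rtol 1e-6 and
atol 1e-9 nmol.  Venous and arterial blood are algebraic outputs, not
states, reflecting the quasi-steady blood assumption.  Unit conversion
nmol/mL -> mg/L lives only at the I/O boundary, via packaged molecular
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._fastode import integrate_schedule
from .composer import GlobalModel, enzyme_balance
from .errors import ConfigurationError, DomainError, SimulationError
from .pbpk import MOLAR_VOLUME_ML_PER_MOL, molecular_weight, ppm_to_air_concentration

__all__ = [
    "ExposureScenario",
    "SolverSettings",
    "SimulationResult",
    "simulate",
    "mixture_interaction_ratio",
]


@dataclass(frozen=True)
class ExposureScenario:
    """Per-chemical inhaled-air schedule: intervals of constant ppm.

    ``schedules`` maps chemical -> tuple of (start_min, end_min, ppm);
    intervals must not overlap per chemical.  ``duration`` is the total
    simulated horizon in minutes (exposure plus post-exposure window).
    """

    schedules: Mapping[str, tuple[tuple[float, float, float], ...]]
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("scenario duration must be > 0")
        for chem, intervals in self.schedules.items():
            prev_end = -np.inf
            for start, end, ppm in sorted(intervals):
                if ppm < 0:
                    raise ConfigurationError(f"{chem}: negative ppm")
                if end <= start or start < 0:
                    raise ConfigurationError(f"{chem}: bad interval ({start}, {end})")
                if start < prev_end:
                    raise ConfigurationError(f"{chem}: overlapping exposure intervals")
                prev_end = end

    @classmethod
    def constant(
        cls,
        ppm_by_chemical: Mapping[str, float],
        exposure_min: float = 240.0,
        total_min: float = 360.0,
    ) -> "ExposureScenario":
        """Constant exposure from t=0 to exposure_min, then clean air."""
        return cls(
            schedules={c: ((0.0, float(exposure_min), float(ppm)),)
                       for c, ppm in ppm_by_chemical.items()},
            duration=float(total_min),
        )

    @property
    def chemicals(self) -> tuple[str, ...]:
        return tuple(self.schedules)

    def switch_times(self) -> list[float]:
        times = {0.0, float(self.duration)}
        for intervals in self.schedules.values():
            for start, end, _ in intervals:
                times.update((float(start), float(end)))
        return sorted(t for t in times if 0.0 <= t <= self.duration)

    def ppm_at(self, chemical: str, t: float) -> float:
        """ppm during the interval containing t (half-open: [start, end))."""
        for start, end, ppm in self.schedules.get(chemical, ()):
            if start <= t < end:
                return ppm
        return 0.0


@dataclass(frozen=True)
class SolverSettings:
    """Integrator controls; defaults suit the stiff binding subsystem."""

    rtol: float = 1e-6
    atol: float = 1e-9
    max_steps_per_segment: int = 500_000
    molar_volume: float = MOLAR_VOLUME_ML_PER_MOL


def _build_schedule(
    model: GlobalModel,
    scenario: ExposureScenario,
    times: np.ndarray,
    molar_volume: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Merge output times with switch times into (bounds, per-segment C_inh)."""
    unknown = set(scenario.chemicals) - set(model.chemicals)
    if unknown:
        raise ConfigurationError(f"scenario chemicals not in model: {sorted(unknown)}")
    bounds = np.unique(np.concatenate([times, np.asarray(scenario.switch_times())]))
    if bounds[0] != 0.0:
        bounds = np.concatenate([[0.0], bounds])
    cinh = np.zeros((len(bounds) - 1, len(model.chemicals)))
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    for c, chem in enumerate(model.chemicals):
        for s, tm in enumerate(mids):
            cinh[s, c] = ppm_to_air_concentration(scenario.ppm_at(chem, tm), molar_volume)
    return bounds, cinh


@dataclass
class SimulationResult:
    """Trajectories plus algebraic outputs of one simulation.

    ``states`` has one row per time in ``times``; concentration getters are
    in nmol/mL (``venous_mg_per_l`` converts).  ``diagnostics`` records step
    counts and the most negative raw state seen (non-negativity check).
    """

    model: GlobalModel
    scenario: ExposureScenario
    times: np.ndarray                  # (n_t,)
    states: np.ndarray                 # (n_t, n_state), clipped at 0
    cinh_segments: np.ndarray          # (n_t - 1, n_chem) nmol/mL
    diagnostics: dict = field(default_factory=dict)

    def _chem(self, chemical: str) -> int:
        if chemical not in self.model.chemicals:
            raise ConfigurationError(f"unknown chemical {chemical!r}")
        return self.model.chemical_pos(chemical)

    def tissue_amounts(self, chemical: str) -> np.ndarray:
        """(4, n_t) liver/fat/poor/rich amounts in nmol."""
        c = self._chem(chemical)
        return self.states[:, self.model.tissue_idx[c]].T

    def venous(self, chemical: str) -> np.ndarray:
        c = self._chem(chemical)
        m = self.model
        flows = m.f_card * m.frac
        tissue_out = self.states[:, m.tissue_idx[c]] / (m.vol * m.part[c])
        return tissue_out @ flows / flows.sum()

    def arterial(self, chemical: str) -> np.ndarray:
        c = self._chem(chemical)
        m = self.model
        cinh = self.cinh_at_times()[:, c]
        cven = self.venous(chemical)
        return (m.f_card * cven + m.f_alv * cinh) / (m.f_card + m.f_alv / m.p_art[c])

    def exhaled(self, chemical: str) -> np.ndarray:
        c = self._chem(chemical)
        return self.arterial(chemical) / self.model.p_art[c]

    def cumulative_metabolized(self, chemical: str) -> np.ndarray:
        """Parent-equivalents past the catalysis step (nmol), non-decreasing."""
        c = self._chem(chemical)
        return self.states[:, self.model.met_idx[c]].sum(axis=1)

    def body_burden(self, chemical: str) -> np.ndarray:
        """All parent-derived matter in the body (nmol)."""
        c = self._chem(chemical)
        return self.states[:, self.model.mass_idx[c]].sum(axis=1)

    def cinh_at_times(self) -> np.ndarray:
        """Left-continuous inhaled concentration at each output time."""
        seg = np.vstack([self.cinh_segments[:1], self.cinh_segments])
        return seg

    def venous_mg_per_l(self, chemical: str) -> np.ndarray:
        """Venous concentration in mg/L (nmol/mL * g/mol * 1e-3)."""
        return self.venous(chemical) * molecular_weight(chemical) * 1e-3

    def gas_exchange_integral(self, chemical: str) -> float:
        """Cumulative net inhaled uptake, by per-segment trapezoidal quadrature.

        Independent of any state bookkeeping: integrates
        F_alv * (C_inh - C_exh) over each constant-C_inh segment.
        """
        c = self._chem(chemical)
        m = self.model
        cven = self.venous(chemical)
        total = 0.0
        for s in range(len(self.times) - 1):
            cinh = self.cinh_segments[s, c]
            flux = []
            for row in (s, s + 1):
                cart = (m.f_card * cven[row] + m.f_alv * cinh) / (
                    m.f_card + m.f_alv / m.p_art[c])
                flux.append(m.f_alv * (cinh - cart / m.p_art[c]))
            total += 0.5 * (flux[0] + flux[1]) * (self.times[s + 1] - self.times[s])
        return total

    def mass_balance_residual(self, chemical: str) -> float:
        """|uptake integral - (body burden + metabolized)| / max(uptake, eps)."""
        uptake = self.gas_exchange_integral(chemical)
        held = self.body_burden(chemical)[-1] + 0.0  # metabolized is inside mass_idx
        return abs(uptake - held) / max(abs(uptake), 1e-12)

    def enzyme_conservation_residual(self) -> float:
        """Largest |free+bound-total| / total over pools and stored times."""
        worst = 0.0
        for row in self.states:
            for _, (found, total) in enzyme_balance(row, self.model).items():
                worst = max(worst, abs(found - total) / (total if total > 0 else 1.0))
        return worst

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, chemical, quantity, value, unit) table."""
        rows = []
        for chem in self.model.chemicals:
            for name, values, unit in (
                ("venous", self.venous(chem), "nmol/mL"),
                ("exhaled", self.exhaled(chem), "nmol/mL"),
                ("metabolized", self.cumulative_metabolized(chem), "nmol"),
            ):
                for t, v in zip(self.times, values):
                    rows.append((t, chem, name, v, unit))
        return pd.DataFrame(rows, columns=["time_min", "chemical", "quantity", "value", "unit"])


def simulate(
    model: GlobalModel,
    scenario: ExposureScenario,
    settings: SolverSettings | None = None,
    grid: Sequence[float] | float | None = None,
) -> SimulationResult:
    """Integrate the model under a scenario.

    ``grid`` is either an explicit array of output times or a spacing in
    minutes (default 1.0); switch times are always included.  Raises
    :class:`SimulationError` carrying the last good time and state if the
    integrator fails.
    """
    settings = settings or SolverSettings()
    if grid is None:
        grid = 1.0
    if np.isscalar(grid):
        times = np.arange(0.0, scenario.duration + 0.5 * float(grid), float(grid))
        times[-1] = min(times[-1], scenario.duration)
    else:
        times = np.asarray(sorted(set(float(t) for t in grid)))
        if times.size and (times[0] < 0 or times[-1] > scenario.duration):
            raise ConfigurationError("output grid outside the scenario horizon")
    bounds, cinh = _build_schedule(model, scenario, times, settings.molar_volume)
    states, done, status, steps = integrate_schedule(
        model.y0, bounds, cinh, *model.packed_args(),
        settings.rtol, settings.atol, settings.max_steps_per_segment)
    if status != 0:
        raise SimulationError(
            f"integrator failed with status {status} at t={bounds[done]:.6g} min "
            f"({'step budget' if status == 1 else 'step underflow'})",
            t_last=float(bounds[done]), y_last=states[done].copy())
    min_state = float(states.min())
    clipped = np.clip(states, 0.0, None)
    return SimulationResult(
        model=model, scenario=scenario, times=bounds, states=clipped,
        cinh_segments=cinh,
        diagnostics={"steps": int(steps), "min_state": min_state,
                     "rtol": settings.rtol, "atol": settings.atol})


def mixture_interaction_ratio(
    model: GlobalModel,
    mixture: ExposureScenario,
    singles: Mapping[str, ExposureScenario],
    t_eval: float,
    settings: SolverSettings | None = None,
) -> dict[str, float]:
    """Venous-concentration ratio (mixture / matched single) per chemical.

    Each single scenario must expose its chemical at the same ppm schedule
    as the mixture does.  Competitive sharing of the enzyme pool makes these
    ratios >= 1; values around 2 signal strong metabolic interaction.
    """
    ratios: dict[str, float] = {}
    mix_result = simulate(model, mixture, settings, grid=[0.0, t_eval, mixture.duration])
    it = int(np.argmin(np.abs(mix_result.times - t_eval)))
    for chem, single in singles.items():
        if single.schedules.get(chem) != mixture.schedules.get(chem):
            raise ConfigurationError(
                f"single scenario for {chem!r} does not match the mixture schedule")
        res = simulate(model, single, settings, grid=[0.0, t_eval, single.duration])
        denom = res.venous(chem)[int(np.argmin(np.abs(res.times - t_eval)))]
        if denom <= 0:
            raise DomainError(
                f"single-exposure venous concentration of {chem!r} is zero at t={t_eval}")
        ratios[chem] = float(mix_result.venous(chem)[it] / denom)
    return ratios
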