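"""Monte Carlo sensitivity screen: which parameters deserve calibration.

Parameters are drawn independently and uniformly (by default within +/-10%
of their baseline value), the model is simulated for each draw, and the
correlation between each sampled parameter and the venous concentration at
each output time is computed.  A parameter is flagged sensitive when any
|r| exceeds the threshold (0.3 by default).

Pearson correlation on raw values is the default; rank (Spearman)
correlation is available since the model response is nonlinear.  The whole
screen is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composer import GlobalModel
from .errors import ConfigurationError, MixkinError
from .simulator import ExposureScenario, SolverSettings, simulate

__all__ = ["SensitivityReport", "monte_carlo_sensitivity"]


@dataclass
class SensitivityReport:
    """Correlation table and flags from one Monte Carlo screen."""

    table: pd.DataFrame            # columns: parameter, time_min, r, flagged
    flagged: list[str]             # parameters with any |r| > threshold
    threshold: float
    n_draws: int
    n_failed: int
    seed: int
    method: str

    def r(self, parameter: str, time: float) -> float:
        sel = self.table[(self.table.parameter == parameter)
                         & (np.isclose(self.table.time_min, time))]
        return float(sel.r.iloc[0])


def monte_carlo_sensitivity(
    model: GlobalModel,
    parameters: Sequence[str] | Mapping[str, tuple[float, float]],
    scenario: ExposureScenario,
    output_times: Sequence[float],
    n_draws: int = 500,
    threshold: float = 0.3,
    seed: int = 0,
    rel_range: float = 0.10,
    chemical: str | None = None,
    method: str = "pearson",
    settings: SolverSettings | None = None,
) -> SensitivityReport:
    """Screen parameters by correlation against venous concentration.

    ``parameters`` is either a list of names (ranges default to
    baseline*(1 -/+ rel_range)) or a mapping name -> (lo, hi).  Names
    starting with ``dummy`` are sampled but never applied to the model —
    useful as a null control.  Draws whose simulation fails are recorded,
    excluded from the correlations, and counted in the report.
    """
    if n_draws < 2:
        raise ConfigurationError("n_draws must be >= 2")
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    chemical = chemical or model.chemicals[0]
    output_times = [float(t) for t in output_times]

    if isinstance(parameters, Mapping):
        ranges = {name: (float(lo), float(hi)) for name, (lo, hi) in parameters.items()}
    else:
        ranges = {}
        for name in parameters:
            if name.startswith("dummy"):
                ranges[name] = (0.0, 1.0)
            else:
                base = model.get_param(name)
                ranges[name] = (base * (1.0 - rel_range), base * (1.0 + rel_range))
    for name, (lo, hi) in ranges.items():
        if hi <= lo:
            raise ConfigurationError(f"empty sampling range for {name!r}")

    names = list(ranges)
    rng = np.random.default_rng(seed)
    draws = np.column_stack([rng.uniform(*ranges[n], size=n_draws) for n in names])

    outputs = np.full((n_draws, len(output_times)), np.nan)
    n_failed = 0
    grid = sorted(set(output_times) | {0.0, scenario.duration})
    for d in range(n_draws):
        applied = {n: v for n, v in zip(names, draws[d]) if not n.startswith("dummy")}
        try:
            res = simulate(model.with_params(applied), scenario, settings, grid=grid)
            cven = res.venous(chemical)
            for j, t in enumerate(output_times):
                outputs[d, j] = cven[np.argmin(np.abs(res.times - t))]
        except MixkinError:
            n_failed += 1

    ok = ~np.isnan(outputs).any(axis=1)
    rows = []
    for i, name in enumerate(names):
        for j, t in enumerate(output_times):
            x, y = draws[ok, i], outputs[ok, j]
            if method == "pearson":
                r = stats.pearsonr(x, y).statistic if np.std(y) > 0 else 0.0
            else:
                r = stats.spearmanr(x, y).statistic if np.std(y) > 0 else 0.0
            rows.append((name, t, float(r)))
    table = pd.DataFrame(rows, columns=["parameter", "time_min", "r"])
    table["flagged"] = table.r.abs() > threshold
    flagged = sorted(table.loc[table.flagged, "parameter"].unique())
    return SensitivityReport(table=table, flagged=flagged, threshold=threshold,
                             n_draws=n_draws, n_failed=n_failed, seed=seed,
                             method=method)
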