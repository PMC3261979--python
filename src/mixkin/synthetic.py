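"""Calibration-ready synthetic datasets with the assumed error structure.

The generator emulates the single-chemical inhalation design behind the
calibration data: 4-hr exposures at 50/100/200 ppm, venous blood sampled at
five time points during the 2 hr after exposure, five animals per group,
multiplicative log-normal measurement/individual noise with geometric SD
around 1.28.  Per-animal draws are independent (group means are the data;
no animal random effect), and everything flows from one seed.

``default_btex_truth`` exposes the calibrated maximum-posterior parameter
values together with the packaged baselines as the canonical "true"
parameter set for recovery experiments, and ``build_btex_model`` composes
the corresponding type I global model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import DEFAULT_GSD, KineticDataset
from .composer import GlobalModel, compose
from .errors import ConfigurationError, DomainError
from .pbpk import chemical_table, default_enzyme_totals, default_physiology, default_transport
from .reaction_network import MicroconstantSet, build_type1_pathway
from .simulator import ExposureScenario, SolverSettings, simulate

__all__ = ["StudyDesign", "generate_dataset", "default_btex_truth", "build_btex_model"]

BTEX = ("benzene", "toluene", "ethylbenzene", "m_xylene")


@dataclass(frozen=True)
class StudyDesign:
    """One single-chemical inhalation study arm layout.

    ``sampling_times`` are minutes *after the end of exposure*; defaults are
    five evenly spaced points over the 2-hr post-exposure window.
    """

    exposure_levels_ppm: tuple[float, ...] = (50.0, 100.0, 200.0)
    exposure_duration_min: float = 240.0
    sampling_times_min: tuple[float, ...] = (24.0, 48.0, 72.0, 96.0, 120.0)
    animals_per_group: int = 5
    noise_gsd: float = DEFAULT_GSD
    seed: int = 0

    def __post_init__(self):
        if any(t <= 0 for t in self.sampling_times_min):
            raise ConfigurationError("sampling times must be > 0 (post-exposure)")
        if self.noise_gsd < 1.0:
            raise ConfigurationError("noise GSD must be >= 1")
        if self.animals_per_group < 1:
            raise ConfigurationError("need at least one animal per group")

    def scenario(self, chemical: str, ppm: float) -> ExposureScenario:
        total = self.exposure_duration_min + max(self.sampling_times_min)
        return ExposureScenario.constant({chemical: ppm},
                                         exposure_min=self.exposure_duration_min,
                                         total_min=total)


def generate_dataset(
    model: GlobalModel,
    chemical: str,
    design: StudyDesign,
    true_params: Mapping[str, float] | None = None,
    settings: SolverSettings | None = None,
) -> list[KineticDataset]:
    """Simulate the design and return one dataset per exposure level.

    For every level the model (at ``true_params`` if given) is simulated,
    per-animal concentrations are drawn log-normally around the prediction
    (geometric mean = prediction, geometric SD = design noise), and the
    group arithmetic mean, SD and n are recorded per sampling time.
    """
    if chemical not in model.chemicals:
        raise ConfigurationError(f"model has no chemical {chemical!r}")
    work = model.with_params(true_params or {})
    rng = np.random.default_rng(design.seed)
    log_sd = np.log(design.noise_gsd)
    datasets = []
    for ppm in design.exposure_levels_ppm:
        scenario = design.scenario(chemical, ppm)
        abs_times = [design.exposure_duration_min + t for t in design.sampling_times_min]
        res = simulate(work, scenario, settings, grid=[0.0, *abs_times, scenario.duration])
        cven = res.venous(chemical)
        rows = []
        for t in abs_times:
            pred = float(cven[np.argmin(np.abs(res.times - t))])
            if pred <= 0:
                raise DomainError(
                    f"predicted venous concentration is 0 at t={t} min; "
                    "start sampling later or raise the exposure")
            if design.noise_gsd == 1.0:
                mean, sd = pred, 0.0
            else:
                animals = pred * np.exp(log_sd * rng.standard_normal(design.animals_per_group))
                mean = float(animals.mean())
                sd = float(animals.std(ddof=1)) if design.animals_per_group > 1 else 0.0
            rows.append({"time_min": float(t), "conc_mean": mean, "conc_sd": sd,
                         "n": design.animals_per_group})
        datasets.append(KineticDataset(
            chemical=chemical, scenario=scenario,
            observations=pd.DataFrame(rows),
            scenario_id=f"{chemical}_{ppm:g}ppm"))
    return datasets


def default_btex_truth() -> dict[str, float]:
    """Calibrated posterior-mode parameters as the canonical generating truth.

    Keys follow the ``with_params`` naming: shared physiology
    (alveolar_ventilation, cardiac_output, fat_volume) plus per-chemical
    ``blood_air:<chem>`` and ``k1/k2/k3:<chem>``.
    """
    table = chemical_table()
    phys = table["posterior_mode_physiology"]
    truth: dict[str, float] = {
        "alveolar_ventilation": float(phys["alveolar_ventilation"]),
        "cardiac_output": float(phys["cardiac_output"]),
        "fat_volume": float(phys["fat_volume"]),
    }
    for chem in BTEX:
        mode = table[chem]["posterior_mode"]
        truth[f"blood_air:{chem}"] = float(mode["blood_air"])
        for k in ("k1", "k2", "k3"):
            truth[f"{k}:{chem}"] = float(mode[k])
    return truth


def build_btex_model(
    chemicals: Sequence[str] = BTEX,
    at: str = "mode",
    enzyme_id: str = "CYP2E1",
) -> GlobalModel:
    """Type I global model of the BTEX constituents.

    ``at='mode'`` applies the calibrated posterior-mode values on top of the
    packaged baselines (the configuration used for mixture predictions);
    ``at='baseline'`` keeps Table-value baselines, with microconstants at
    their posterior modes since the baseline tables only fix k3.
    """
    if at not in ("mode", "baseline"):
        raise ConfigurationError(f"unknown parameter set {at!r}")
    table = chemical_table()
    pathways = []
    for chem in chemicals:
        mode = table[chem]["posterior_mode"]
        constants = MicroconstantSet(k1=float(mode["k1"]), k2=float(mode["k2"]),
                                     k3=float(mode["k3"]))
        pathways.append(build_type1_pathway(chem, constants, enzyme_id))
    model = compose(
        pathways,
        default_physiology(),
        {chem: default_transport(chem) for chem in chemicals},
        {enzyme_id: default_enzyme_totals()[enzyme_id]},
    )
    if at == "mode":
        truth = default_btex_truth()
        model = model.with_params({
            k: v for k, v in truth.items()
            if ":" not in k or k.split(":", 1)[1] in chemicals})
    return model
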