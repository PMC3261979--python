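"""Generic four-compartment rat PBPK transport template.

One instance of this template describes the inhalation uptake, distribution
and exhalation of a single volatile chemical through liver, fat, poorly
perfused and richly perfused tissues.  Tissue uptake is flow-limited,

    dQ_i/dt = F_i * (C_art - Q_i / (V_i * P_i)),

blood is quasi-steady so venous, arterial and exhaled concentrations are
algebraic:

    C_ven = sum_i F_i * Q_i/(V_i P_i) / sum_i F_i
    C_art = (F_card * C_ven + F_alv * C_inh) / (F_card + F_alv / P_art)
    C_exh = C_art / P_art

(the venous-equilibration gas-exchange form).  Metabolism is *not* part of
the template: the composer adds mass-action reaction terms onto the liver
amount.  Units throughout: amounts nmol, volumes mL, flows mL/min,
concentrations nmol/mL.

Baseline parameter values for the rat and for the four BTEX constituents
ship as packaged YAML tables (``data/physiology.yaml``,
``data/chemicals.yaml``); two physiological quantities are derived rather
than set — the rich-tissue flow fraction (remainder to 1) and the poorly
perfused volume (0.9 x body volume minus the other tissues).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

from .errors import ConfigurationError, DomainError

__all__ = [
    "TISSUES",
    "PhysiologyParams",
    "ChemicalTransportParams",
    "derive_dependent_params",
    "tissue_rate",
    "arterial_concentration",
    "venous_concentration",
    "exhaled_concentration",
    "ppm_to_air_concentration",
    "default_physiology",
    "default_transport",
    "default_enzyme_totals",
    "molecular_weight",
    "chemical_table",
    "MOLAR_VOLUME_ML_PER_MOL",
]

TISSUES = ("liver", "fat", "poor", "rich")

#: Molar volume of an ideal gas at 25 degC / 1 atm, mL per mol (24.45 L/mol).
MOLAR_VOLUME_ML_PER_MOL = 24_450.0


@dataclass(frozen=True)
class PhysiologyParams:
    """Chemical-independent physiology: flows (mL/min) and volumes (mL).

    ``flow_fractions`` and ``tissue_volumes`` are keyed by tissue name; the
    ``rich`` fraction and ``poor`` volume may be absent on input and filled
    in by :func:`derive_dependent_params`.
    """

    alveolar_ventilation: float
    cardiac_output: float
    flow_fractions: Mapping[str, float]
    body_volume: float
    tissue_volumes: Mapping[str, float]

    def __post_init__(self):
        if self.alveolar_ventilation <= 0 or self.cardiac_output <= 0:
            raise ConfigurationError("flows must be strictly positive")
        if self.body_volume <= 0:
            raise ConfigurationError("body volume must be strictly positive")

    @property
    def complete(self) -> bool:
        return all(t in self.flow_fractions for t in TISSUES) and all(
            t in self.tissue_volumes for t in TISSUES
        )

    def flow(self, tissue: str) -> float:
        """Blood flow through a tissue, mL/min."""
        return self.cardiac_output * self.flow_fractions[tissue]


@dataclass(frozen=True)
class ChemicalTransportParams:
    """Per-chemical partition coefficients (dimensionless)."""

    blood_air: float
    tissue_blood: Mapping[str, float]

    def __post_init__(self):
        if self.blood_air <= 0:
            raise ConfigurationError("blood/air partition coefficient must be > 0")
        for tissue, p in self.tissue_blood.items():
            if p <= 0:
                raise ConfigurationError(f"partition coefficient for {tissue!r} must be > 0")


def derive_dependent_params(raw: PhysiologyParams) -> PhysiologyParams:
    """Fill in the derived rich-flow fraction and poorly perfused volume.

    rich fraction = 1 - (liver + fat + poor fractions);
    poor volume = 0.9 * body volume - (liver + fat + rich volumes).
    Raises a configuration error if either derived value is non-positive.
    """
    fractions = dict(raw.flow_fractions)
    volumes = dict(raw.tissue_volumes)
    if "rich" not in fractions:
        rich = 1.0 - sum(fractions[t] for t in ("liver", "fat", "poor"))
        if rich <= 0:
            raise ConfigurationError(
                f"derived rich-flow fraction is non-positive ({rich:.4g}); "
                "check the other cardiac-output fractions"
            )
        fractions["rich"] = rich
    if "poor" not in volumes:
        poor = 0.9 * raw.body_volume - sum(volumes[t] for t in ("liver", "fat", "rich"))
        if poor <= 0:
            raise ConfigurationError(
                f"derived poorly perfused volume is non-positive ({poor:.4g} mL)"
            )
        volumes["poor"] = poor
    total_fraction = sum(fractions[t] for t in TISSUES)
    if abs(total_fraction - 1.0) > 1e-9:
        raise ConfigurationError(f"flow fractions sum to {total_fraction}, not 1")
    for t in TISSUES:
        if fractions[t] <= 0 or volumes[t] <= 0:
            raise ConfigurationError(f"non-positive flow fraction or volume for {t!r}")
    return PhysiologyParams(
        alveolar_ventilation=raw.alveolar_ventilation,
        cardiac_output=raw.cardiac_output,
        flow_fractions=fractions,
        body_volume=raw.body_volume,
        tissue_volumes=volumes,
    )


def tissue_rate(q: float, flow: float, volume: float, partition: float, c_art: float) -> float:
    """Flow-limited tissue mass balance dQ/dt, nmol/min.

    The liver additionally receives reaction sink/source terms, added by the
    composer on top of this transport term.
    """
    if q < 0:
        raise DomainError("tissue amount must be >= 0")
    if min(flow, volume, partition) <= 0:
        raise DomainError("flow, volume and partition coefficient must be > 0")
    return flow * (c_art - q / (volume * partition))


def venous_concentration(
    q: Mapping[str, float],
    volumes: Mapping[str, float],
    partitions: Mapping[str, float],
    flows: Mapping[str, float],
) -> float:
    """Flow-weighted mixed venous concentration, nmol/mL."""
    total_flow = sum(flows[t] for t in TISSUES)
    if total_flow <= 0:
        raise DomainError("total tissue blood flow must be > 0")
    mixed = sum(flows[t] * q[t] / (volumes[t] * partitions[t]) for t in TISSUES)
    return mixed / total_flow


def arterial_concentration(
    c_ven: float, c_inh: float, f_alv: float, f_card: float, p_art: float
) -> float:
    """Arterial concentration from the venous-equilibration gas exchange."""
    if min(f_alv, f_card, p_art) <= 0:
        raise DomainError("flows and blood/air partition must be > 0")
    return (f_card * c_ven + f_alv * c_inh) / (f_card + f_alv / p_art)


def exhaled_concentration(c_art: float, p_art: float) -> float:
    """Exhaled-air concentration C_exh = C_art / P_art."""
    if p_art <= 0:
        raise DomainError("blood/air partition must be > 0")
    return c_art / p_art


def ppm_to_air_concentration(ppm: float, molar_volume: float = MOLAR_VOLUME_ML_PER_MOL) -> float:
    """Convert a gas mixing ratio in ppm (v/v) to nmol/mL of air.

    C = ppm * 1e-6 / molar_volume [mol/mL] * 1e9 [nmol/mol], with the molar
    volume defaulting to 24,450 mL/mol (25 degC, 1 atm); 100 ppm of any
    ideal gas is then 4.09 nmol per mL of air.
    """
    if ppm < 0:
        raise DomainError("ppm must be >= 0")
    if molar_volume <= 0:
        raise DomainError("molar volume must be > 0")
    return ppm * 1e3 / molar_volume


# ---------------------------------------------------------------------------
# packaged baseline tables

def _load_yaml(name: str) -> dict:
    with resources.files("mixkin.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_physiology() -> PhysiologyParams:
    """Rat physiology baselines with derived quantities filled in."""
    doc = _load_yaml("physiology.yaml")
    return derive_dependent_params(
        PhysiologyParams(
            alveolar_ventilation=doc["alveolar_ventilation"],
            cardiac_output=doc["cardiac_output"],
            flow_fractions=doc["flow_fractions"],
            body_volume=doc["body_volume"],
            tissue_volumes=doc["tissue_volumes"],
        )
    )


def default_enzyme_totals() -> dict[str, float]:
    """Hepatic enzyme pool totals, nmol (CYP2E1 20.9; CYPX 1.16)."""
    return dict(_load_yaml("physiology.yaml")["enzyme_totals"])


def chemical_table() -> dict:
    """Raw per-chemical baseline table (partitions, k3 baseline, posterior modes)."""
    doc = _load_yaml("chemicals.yaml")
    return doc


def default_transport(chemical: str) -> ChemicalTransportParams:
    """Packaged partition coefficients for one of the BTEX constituents."""
    table = chemical_table()
    if chemical not in table or chemical == "posterior_mode_physiology":
        raise ConfigurationError(f"no packaged transport parameters for {chemical!r}")
    p = table[chemical]["partitions"]
    return ChemicalTransportParams(
        blood_air=p["blood_air"],
        tissue_blood={t: p[t] for t in TISSUES},
    )


def molecular_weight(chemical: str) -> float:
    """Molecular weight in g/mol, for nmol/mL <-> mg/L conversion at the I/O boundary."""
    table = chemical_table()
    if chemical not in table or chemical == "posterior_mode_physiology":
        raise ConfigurationError(f"no packaged molecular weight for {chemical!r}")
    return float(table[chemical]["molecular_weight"])
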