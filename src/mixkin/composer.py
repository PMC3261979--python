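"""Assemble the joint mixture model from per-chemical pathways and PBPK templates.

Composition rules:

* every circulating species (the parent of each pathway) gets the four
  flow-limited tissue states of the PBPK template plus algebraic
  venous/arterial/exhaled outputs;
* liver-resident species (enzymes, complexes, metabolites) are not
  transported; mass-action reaction terms act on liver amounts, and the
  parent's liver PBPK amount *is* its pathway substrate state — transport
  and reaction terms add on one variable;
* each shared enzyme appears exactly once in the state, and its time
  derivative is automatically the sum of binding/unbinding/catalysis terms
  over all chemicals, so competitive interactions emerge from depletion of
  the free pool without any pairwise interaction constant;
* type I metabolites are terminal: they get a state recording cumulative
  production, with no transport and no further reactions.

State ordering is canonical: chemicals in input order, each contributing
(Q_liver, Q_fat, Q_poor, Q_rich, then its liver-only non-enzyme species in
pathway order); the shared enzyme pools come last.  ``state_index`` exposes
the layout; nothing downstream relies on positional guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _fastode
from .errors import ConfigurationError
from .kinetics import MichaelisSummary, michaelis_from_micro
from .pbpk import TISSUES, ChemicalTransportParams, PhysiologyParams
from .reaction_network import ChemicalPathway

__all__ = ["GlobalModel", "compose", "enzyme_balance", "michaelis_reduction"]

_TISSUE_KEYS = tuple(f"Q_{t}" for t in TISSUES)


@dataclass
class GlobalModel:
    """The composed joint ODE system for a mixture.

    Physiology and transport parameters live in flat arrays shared with the
    compiled integrator; ``state_index`` maps ``(chemical, quantity)`` pairs
    (and ``(None, enzyme_id)`` for shared pools) to state positions.
    """

    chemicals: list[str]
    variant: str
    enzyme_totals: dict[str, float]
    state_index: dict[tuple[str | None, str], int]
    n_state: int
    # packed physiology/transport
    f_alv: float
    f_card: float
    frac: np.ndarray          # (4,) flow fractions, TISSUES order
    vol: np.ndarray           # (4,) tissue volumes, mL
    part: np.ndarray          # (n_chem, 4) tissue/blood partitions
    p_art: np.ndarray         # (n_chem,) blood/air partitions
    tissue_idx: np.ndarray    # (n_chem, 4) int64 state indices
    # packed reactions
    rate_k: np.ndarray        # (n_rxn,)
    n_reac: np.ndarray
    reac_idx: np.ndarray
    reac_st: np.ndarray
    n_prod: np.ndarray
    prod_idx: np.ndarray
    prod_st: np.ndarray
    # bookkeeping
    y0: np.ndarray
    mass_idx: list[np.ndarray]        # per chemical: states carrying parent-derived matter
    met_idx: list[np.ndarray]         # per chemical: states counting as metabolized
    enzyme_state: dict[str, int]      # enzyme id -> free-pool state index
    enzyme_complexes: dict[str, np.ndarray]  # enzyme id -> complex state indices
    param_map: dict[tuple[str, str], np.ndarray]  # (chemical, constant id) -> reaction rows
    pathways: dict[str, ChemicalPathway] = field(default_factory=dict)
    primary_enzyme: dict[str, str] = field(default_factory=dict)

    # -- indexing helpers ---------------------------------------------------
    def index(self, chemical: str, quantity: str) -> int:
        return self.state_index[(chemical, quantity)]

    def enzyme_index(self, enzyme_id: str) -> int:
        return self.enzyme_state[enzyme_id]

    def chemical_pos(self, chemical: str) -> int:
        return self.chemicals.index(chemical)

    # -- parameter updates --------------------------------------------------
    def with_params(self, params: Mapping[str, float]) -> "GlobalModel":
        """Copy of the model with named parameters replaced.

        Names: ``alveolar_ventilation``, ``cardiac_output``, ``fat_volume``,
        ``blood_air:<chemical>`` and ``<microconstant>:<chemical>`` (e.g.
        ``k1:benzene``).
        """
        model = GlobalModel(**{**self.__dict__})
        model.frac = self.frac.copy()
        model.vol = self.vol.copy()
        model.part = self.part.copy()
        model.p_art = self.p_art.copy()
        model.rate_k = self.rate_k.copy()
        for name, value in params.items():
            model._set_param(name, float(value))
        return model

    def _set_param(self, name: str, value: float) -> None:
        if value <= 0:
            raise ConfigurationError(f"parameter {name!r} must be > 0, got {value}")
        if name == "alveolar_ventilation":
            self.f_alv = value
            return
        if name == "cardiac_output":
            self.f_card = value
            return
        if name == "fat_volume":
            self.vol[TISSUES.index("fat")] = value
            return
        if ":" in name:
            kind, chem = name.split(":", 1)
            if chem not in self.chemicals:
                raise ConfigurationError(f"unknown chemical in parameter {name!r}")
            if kind == "blood_air":
                self.p_art[self.chemical_pos(chem)] = value
                return
            rows = self.param_map.get((chem, kind))
            if rows is not None:
                self.rate_k[rows] = value
                return
        raise ConfigurationError(f"unknown parameter {name!r}")

    def get_param(self, name: str) -> float:
        """Current value of a named parameter (same names as with_params)."""
        if name == "alveolar_ventilation":
            return float(self.f_alv)
        if name == "cardiac_output":
            return float(self.f_card)
        if name == "fat_volume":
            return float(self.vol[TISSUES.index("fat")])
        if ":" in name:
            kind, chem = name.split(":", 1)
            if chem in self.chemicals:
                if kind == "blood_air":
                    return float(self.p_art[self.chemical_pos(chem)])
                rows = self.param_map.get((chem, kind))
                if rows is not None:
                    return float(self.rate_k[rows[0]])
        raise ConfigurationError(f"unknown parameter {name!r}")

    # -- reference right-hand side and algebraic outputs --------------------
    def rhs(self, t: float, y: np.ndarray, c_inh: np.ndarray) -> np.ndarray:
        """Pure-python RHS (oracle path; the simulator uses the compiled kernel)."""
        return _fastode.rhs_reference(
            y, np.asarray(c_inh, dtype=float), self.f_alv, self.f_card, self.frac,
            self.vol, self.part, self.p_art, self.tissue_idx, self.rate_k,
            self.n_reac, self.reac_idx, self.reac_st, self.n_prod,
            self.prod_idx, self.prod_st)

    def outputs(self, y: np.ndarray, c_inh: np.ndarray) -> dict[str, dict[str, float]]:
        """Algebraic blood/air outputs per chemical at one state.

        Returns {chemical: {C_ven, C_art, C_exh, uptake_flux}} with
        concentrations in nmol/mL and the net gas-exchange uptake flux
        F_alv * (C_inh - C_exh) in nmol/min.
        """
        y = np.asarray(y, dtype=float)
        out: dict[str, dict[str, float]] = {}
        flows = self.f_card * self.frac
        for c, chem in enumerate(self.chemicals):
            q = y[self.tissue_idx[c]]
            tissue_out = q / (self.vol * self.part[c])
            c_ven = float(np.dot(flows, tissue_out) / flows.sum())
            c_art = (self.f_card * c_ven + self.f_alv * c_inh[c]) / (
                self.f_card + self.f_alv / self.p_art[c])
            c_exh = c_art / self.p_art[c]
            out[chem] = {
                "C_ven": c_ven,
                "C_art": c_art,
                "C_exh": c_exh,
                "uptake_flux": self.f_alv * (c_inh[c] - c_exh),
            }
        return out

    def packed_args(self) -> tuple:
        """Argument tuple for the compiled integrator (after y0/bounds/cinh)."""
        return (self.f_alv, self.f_card, self.frac, self.vol, self.part,
                self.p_art, self.tissue_idx, self.rate_k, self.n_reac,
                self.reac_idx, self.reac_st, self.n_prod, self.prod_idx,
                self.prod_st)


def compose(
    pathways: Sequence[ChemicalPathway],
    physiology: PhysiologyParams,
    transport: Mapping[str, ChemicalTransportParams],
    enzyme_totals: Mapping[str, float],
) -> GlobalModel:
    """Build the joint global model from per-chemical pathways.

    All pathways must share the same variant; every enzyme referenced by any
    pathway needs a declared total (nmol); chemical ids must be unique.
    """
    if not pathways:
        raise ConfigurationError("at least one pathway is required")
    variants = {p.variant for p in pathways}
    if len(variants) != 1:
        raise ConfigurationError(f"all pathways must share one variant, got {sorted(variants)}")
    chemicals = [p.chemical_id for p in pathways]
    if len(set(chemicals)) != len(chemicals):
        raise ConfigurationError("duplicate chemical ids among pathways")
    if not physiology.complete:
        raise ConfigurationError(
            "physiology is incomplete; run derive_dependent_params first")
    for p in pathways:
        if p.chemical_id not in transport:
            raise ConfigurationError(f"no transport parameters for {p.chemical_id!r}")

    n_chem = len(pathways)
    state_index: dict[tuple[str | None, str], int] = {}
    pos = 0
    tissue_idx = np.zeros((n_chem, 4), dtype=np.int64)
    enzyme_ids: list[str] = []
    for p in pathways:
        for s in p.species:
            if s.role == "enzyme":
                if s.id not in enzyme_totals:
                    raise ConfigurationError(
                        f"pathway {p.chemical_id!r} references enzyme {s.id!r} "
                        "with no declared total")
                if s.id not in enzyme_ids:
                    enzyme_ids.append(s.id)

    # per-chemical states: tissues then liver-only non-enzyme species
    species_state: dict[tuple[str, str], int] = {}
    for c, p in enumerate(pathways):
        for i, key in enumerate(_TISSUE_KEYS):
            state_index[(p.chemical_id, key)] = pos
            tissue_idx[c, i] = pos
            pos += 1
        # the parent's pathway species is the liver amount
        species_state[(p.chemical_id, p.parent_id)] = tissue_idx[c, 0]
        state_index[(p.chemical_id, p.parent_id)] = int(tissue_idx[c, 0])
        for s in p.species:
            if s.role in ("enzyme", "parent"):
                continue
            state_index[(p.chemical_id, s.id)] = pos
            species_state[(p.chemical_id, s.id)] = pos
            pos += 1
    enzyme_state: dict[str, int] = {}
    for eid in enzyme_ids:
        state_index[(None, eid)] = pos
        enzyme_state[eid] = pos
        pos += 1
    n_state = pos

    # reactions -> packed arrays with global indices
    rate_k, n_reac, reac_idx, reac_st, n_prod, prod_idx, prod_st = [], [], [], [], [], [], []
    param_map: dict[tuple[str, str], list[int]] = {}
    enzyme_complexes: dict[str, list[int]] = {eid: [] for eid in enzyme_ids}
    row = 0
    for p in pathways:
        roles = {s.id: s.role for s in p.species}

        def gidx(sid: str, chem=p.chemical_id) -> int:
            if roles[sid] == "enzyme":
                return enzyme_state[sid]
            return species_state[(chem, sid)]

        for rxn in p.reactions:
            if len(rxn.reactants) > 2 or len(rxn.products) > 2:
                raise ConfigurationError(
                    f"reaction {rxn.id!r}: at most two reactants/products supported")
            rate_k.append(p.constants.get(rxn.rate_constant_id))
            param_map.setdefault((p.chemical_id, rxn.rate_constant_id), []).append(row)
            ridx = [gidx(sid) for sid, _ in rxn.reactants]
            rst = [st for _, st in rxn.reactants]
            pidx = [gidx(sid) for sid, _ in rxn.products]
            pst = [st for _, st in rxn.products]
            n_reac.append(len(ridx))
            n_prod.append(len(pidx))
            reac_idx.append(ridx + [0] * (2 - len(ridx)))
            reac_st.append(rst + [0] * (2 - len(rst)))
            prod_idx.append(pidx + [0] * (2 - len(pidx)))
            prod_st.append(pst + [0] * (2 - len(pst)))
            # a complex produced while consuming an enzyme belongs to that pool
            for sid, _ in rxn.reactants:
                if roles[sid] == "enzyme":
                    for psid, _ in rxn.products:
                        if roles[psid] == "complex":
                            cx = gidx(psid)
                            if cx not in enzyme_complexes[sid]:
                                enzyme_complexes[sid].append(cx)
            row += 1

    y0 = np.zeros(n_state)
    for eid in enzyme_ids:
        y0[enzyme_state[eid]] = float(enzyme_totals[eid])

    mass_idx, met_idx = [], []
    for c, p in enumerate(pathways):
        own = [int(tissue_idx[c, i]) for i in range(4)]
        metabolized = []
        for s in p.species:
            if s.role in ("enzyme", "parent"):
                continue
            gi = species_state[(p.chemical_id, s.id)]
            own.append(gi)
            # parent-enzyme complexes still hold parent; everything downstream
            # of catalysis or the metabolite branch counts as metabolized
            is_parent_complex = s.role == "complex" and any(
                rxn for rxn in p.reactions
                if rxn.rate_constant_id in ("k1", "k1p")
                and any(sid == s.id for sid, _ in rxn.products))
            if not is_parent_complex:
                metabolized.append(gi)
        mass_idx.append(np.asarray(own, dtype=np.int64))
        met_idx.append(np.asarray(metabolized, dtype=np.int64))

    frac = np.array([physiology.flow_fractions[t] for t in TISSUES])
    vol = np.array([physiology.tissue_volumes[t] for t in TISSUES])
    part = np.array([[transport[p.chemical_id].tissue_blood[t] for t in TISSUES]
                     for p in pathways])
    p_art = np.array([transport[p.chemical_id].blood_air for p in pathways])

    return GlobalModel(
        chemicals=chemicals,
        variant=pathways[0].variant,
        enzyme_totals={eid: float(enzyme_totals[eid]) for eid in enzyme_ids},
        state_index=state_index,
        n_state=n_state,
        f_alv=float(physiology.alveolar_ventilation),
        f_card=float(physiology.cardiac_output),
        frac=frac,
        vol=vol,
        part=part,
        p_art=p_art,
        tissue_idx=tissue_idx,
        rate_k=np.asarray(rate_k, dtype=float),
        n_reac=np.asarray(n_reac, dtype=np.int64),
        reac_idx=np.asarray(reac_idx, dtype=np.int64),
        reac_st=np.asarray(reac_st, dtype=np.int64),
        n_prod=np.asarray(n_prod, dtype=np.int64),
        prod_idx=np.asarray(prod_idx, dtype=np.int64),
        prod_st=np.asarray(prod_st, dtype=np.int64),
        y0=y0,
        mass_idx=mass_idx,
        met_idx=met_idx,
        enzyme_state=enzyme_state,
        enzyme_complexes={k: np.asarray(v, dtype=np.int64)
                          for k, v in enzyme_complexes.items()},
        param_map={k: np.asarray(v, dtype=np.int64) for k, v in param_map.items()},
        pathways={p.chemical_id: p for p in pathways},
        primary_enzyme={p.chemical_id: p.shared_enzyme_ids[0] for p in pathways},
    )


def enzyme_balance(state: np.ndarray, model: GlobalModel) -> dict[str, tuple[float, float]]:
    """Free + bound enzyme versus the declared total, per enzyme pool.

    Conservation is exact in the ODE algebra; along a simulated trajectory
    the residual measures integrator error only.
    """
    state = np.asarray(state, dtype=float)
    report = {}
    for eid, free_i in model.enzyme_state.items():
        bound = float(state[model.enzyme_complexes[eid]].sum())
        report[eid] = (float(state[free_i]) + bound, model.enzyme_totals[eid])
    return report


def michaelis_reduction(model: GlobalModel) -> dict[str, MichaelisSummary]:
    """Diagnostic (Vmax, Km) implied by each chemical's primary-route microconstants.

    Vmax = k3 * E_total, Km = (k2 + k3)/k1 — the quasi-steady reduction of
    the mass-action triple; purely a summary, never used in simulation.
    """
    out = {}
    for chem, pathway in model.pathways.items():
        enzyme = model.primary_enzyme[chem]
        c = pathway.constants
        out[chem] = michaelis_from_micro(c.k1, c.k2, c.k3, model.enzyme_totals[enzyme])
    return out
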