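"""Microconstant <-> Michaelis-Menten conversions and parameter-count scaling.

The enzymatic step is described by elementary mass-action microconstants:
``k1`` (binding, min^-1 nmol^-1), ``k2`` (unbinding, min^-1) and ``k3``
(catalysis, min^-1).  Under the quasi-steady-state / rapid-equilibrium
reduction these collapse to the familiar pair

    Vmax = k3 * E_total        Km = (k2 + k3) / k1

with ``Km`` in nmol because rates act on liver *amounts*, not concentrations.
Knowing (Vmax, Km) therefore leaves one microconstant free; the inverse
conversion requires one constant to close the system.

The parameter-count calculus contrasts the classical Michaelis-Menten +
pairwise-interaction description of an n-chemical mixture (2 parameters per
chemical-reaction plus 2 empirical interaction constants per unordered pair)
with the microconstant description (3 per chemical-reaction, no pairwise
terms): the classical count grows quadratically with mixture size, the
microconstant count linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "MichaelisSummary",
    "michaelis_from_micro",
    "micro_from_michaelis",
    "parameter_counts",
]


@dataclass(frozen=True)
class MichaelisSummary:
    """Reduced Michaelis-Menten view of one mass-action pathway.

    Attributes
    ----------
    vmax : float
        Maximum velocity, nmol/min.
    km : float
        Michaelis constant, nmol (amount-based rate law).
    """

    vmax: float
    km: float

    def __post_init__(self):
        if self.vmax <= 0 or self.km <= 0:
            raise DomainError("Vmax and Km must be strictly positive")


def michaelis_from_micro(k1: float, k2: float, k3: float, enzyme_total: float) -> MichaelisSummary:
    """Reduce microconstants to (Vmax, Km).

    Parameters
    ----------
    k1, k2, k3 : float
        Binding (min^-1 nmol^-1), unbinding (min^-1) and catalysis (min^-1)
        microconstants; all strictly positive.
    enzyme_total : float
        Total enzyme pool, nmol.
    """
    if min(k1, k2, k3, enzyme_total) <= 0:
        raise DomainError("all microconstants and the enzyme total must be > 0")
    return MichaelisSummary(vmax=k3 * enzyme_total, km=(k2 + k3) / k1)


def micro_from_michaelis(
    vmax: float,
    km: float,
    enzyme_total: float,
    *,
    k2: float | None = None,
    k1: float | None = None,
) -> tuple[float, float, float]:
    """Invert the Michaelis reduction given one closing microconstant.

    Exactly one of ``k2`` or ``k1`` must be supplied; the returned triple
    satisfies ``Vmax = k3 * E_total`` and ``Km = (k2 + k3)/k1`` exactly.

    Raises
    ------
    DomainError
        If inputs are non-positive, if both or neither closure is given, or
        if the closure implies a negative ``k2``.
    """
    if min(vmax, km, enzyme_total) <= 0:
        raise DomainError("Vmax, Km and enzyme total must be > 0")
    if (k2 is None) == (k1 is None):
        raise DomainError("supply exactly one of k2 or k1 to close the system")
    k3 = vmax / enzyme_total
    if k2 is not None:
        if k2 < 0:
            raise DomainError("k2 must be >= 0")
        k1_out = (k2 + k3) / km
        return (k1_out, k2, k3)
    if k1 <= 0:
        raise DomainError("k1 must be > 0")
    k2_out = k1 * km - k3
    if k2_out < 0:
        raise DomainError(
            f"closure k1={k1} implies negative k2 = k1*Km - k3 = {k2_out:.4g}"
        )
    return (k1, k2_out, k3)


def parameter_counts(n_chemicals: int, reactions_per_chemical: int = 1) -> tuple[int, int]:
    """Kinetic-parameter counts for an n-chemical mixture.

    Returns ``(classical, microconstant)`` where

    * classical  = 2*n*r + n*(n-1): Vmax and Km per chemical-reaction plus
      two empirical interaction constants per unordered pair of chemicals;
    * microconstant = 3*n*r: k1, k2, k3 per chemical-reaction, with
      interactions emerging from the shared enzyme pool at no parameter cost.
    """
    if n_chemicals < 1:
        raise DomainError("n_chemicals must be >= 1")
    if reactions_per_chemical < 1:
        raise DomainError("reactions_per_chemical must be >= 1")
    n, r = n_chemicals, reactions_per_chemical
    classical = 2 * n * r + n * (n - 1)
    micro = 3 * n * r
    return classical, micro
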