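"""Reaction networks with law-of-mass-action rate laws.

A :class:`ReactionNetwork` is a list of species names plus a list of
:class:`Reaction` steps.  Each step carries integer stoichiometry and a rate
law — either plain mass action (rate ``k * prod [reactant]^coeff``) or an
empirical autocatalytic law ``k_direct*prod[reactant] +
k_auto*prod[reactant]*[autocatalyst]^p`` with a possibly fractional kinetic
order ``p`` of the autocatalyst.

Concentrations are molar (M) and time is in seconds throughout; rate
coefficients therefore carry units ``M^(1-order) s^-1``.  Reversible steps
are represented as two irreversible reactions.

The stoichiometric matrix ``S`` (species x reactions) gives the net change
of each species per unit extent of each reaction, so the batch ODE is
``dc/dt = S @ v(c)`` and the CSTR (flow) ODE adds ``k0 * (feed - c)`` for
every species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np
import sympy

__all__ = [
    "MassAction",
    "EmpiricalAutocatalytic",
    "Reaction",
    "ReactionNetwork",
    "FlowConfig",
    "NetworkStructureError",
    "NumericalStateError",
    "build_stoichiometric_matrix",
    "evaluate_rates",
    "assemble_rhs",
    "conservation_laws",
]

#: concentrations above this (negative) bound are treated as solver noise
#: and clipped to zero before rate evaluation; anything below it aborts.
NEGATIVE_CLIP_TOL = 1e-9


class NetworkStructureError(ValueError):
    """A reaction references a species missing from the network."""


class NumericalStateError(ValueError):
    """A concentration is negative beyond the solver clip tolerance."""


@dataclass(frozen=True)
class MassAction:
    """Mass-action rate law: ``v = k * prod [reactant]^coeff``.

    ``k`` has units M^(1-order) s^-1 where order is the molecularity.
    """

    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rate coefficient must be >= 0, got {self.k}")


@dataclass(frozen=True)
class EmpiricalAutocatalytic:
    """Two-term empirical autocatalytic rate law.

    ``v = k_direct * prod [reactant]^coeff
        + k_auto * prod [reactant]^coeff * [autocatalyst]^p``

    ``p > 0`` is the formal kinetic order of the autocatalyst; ``0^p`` is
    defined as 0 (continuity from the right) so the law is well defined
    when the autocatalyst starts at zero concentration.
    """

    k_direct: float
    k_auto: float
    p: float
    autocatalyst: str

    def __post_init__(self) -> None:
        if self.k_direct < 0 or self.k_auto < 0:
            raise ValueError("rate coefficients must be >= 0")
        if self.p <= 0:
            raise ValueError(f"autocatalyst order p must be > 0, got {self.p}")


RateLaw = MassAction | EmpiricalAutocatalytic


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction step.

    ``reactants`` and ``products`` map species name -> positive integer
    stoichiometric coefficient.  A reversible step is two Reactions.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_law: RateLaw
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reactants and not self.products:
            raise ValueError("reaction needs at least one reactant or product")
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if not isinstance(coeff, (int, np.integer)) or coeff <= 0:
                    raise ValueError(
                        f"stoichiometric coefficient of {name} must be a "
                        f"positive integer, got {coeff!r}"
                    )

    @property
    def order(self) -> int:
        """Molecularity: total reactant stoichiometry."""
        return sum(self.reactants.values())


class ReactionNetwork:
    """Ordered species + reactions, with derived stoichiometric matrix.

    Parameters
    ----------
    species
        Ordered, unique, nonempty species names.  Every species referenced
        by a reaction must appear here.
    reactions
        Ordered reaction list.
    """

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        species = list(species)
        if len(set(species)) != len(species):
            raise NetworkStructureError("species names must be unique")
        if any(not s for s in species):
            raise NetworkStructureError("species names must be nonempty")
        self.species: list[str] = species
        self.reactions: list[Reaction] = list(reactions)
        self.index: dict[str, int] = {s: i for i, s in enumerate(species)}
        for rxn in self.reactions:
            refs = set(rxn.reactants) | set(rxn.products)
            if isinstance(rxn.rate_law, EmpiricalAutocatalytic):
                refs.add(rxn.rate_law.autocatalyst)
            missing = refs - set(self.index)
            if missing:
                raise NetworkStructureError(
                    f"reaction {rxn.label or '?'} references unknown "
                    f"species {sorted(missing)}"
                )
        self.stoichiometry: np.ndarray = build_stoichiometric_matrix(self)
        # flattened per-reaction reactant (index, coeff) arrays for fast
        # rate/Jacobian evaluation inside ODE solvers
        self._ridx = [
            np.array([self.index[s] for s in r.reactants], dtype=np.intp)
            for r in self.reactions
        ]
        self._rcoef = [
            np.array(list(r.reactants.values()), dtype=np.float64)
            for r in self.reactions
        ]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def state(self, concentrations: Mapping[str, float]) -> np.ndarray:
        """Concentration vector aligned to species order; absent species 0."""
        unknown = set(concentrations) - set(self.index)
        if unknown:
            raise NetworkStructureError(f"unknown species {sorted(unknown)}")
        c = np.zeros(self.n_species)
        for name, value in concentrations.items():
            c[self.index[name]] = value
        return c

    def rates(self, c: np.ndarray) -> np.ndarray:
        return evaluate_rates(self, c)

    def rate_jacobian(self, c: np.ndarray) -> np.ndarray:
        """d(rates)/d(concentrations), shape (n_reactions, n_species).

        The singular derivative of ``[X]^p`` (p < 1) at ``[X] = 0`` is
        replaced by 0; ODE solvers only need an approximate Jacobian there.
        """
        c = np.clip(np.asarray(c, dtype=np.float64), 0.0, None)
        J = np.zeros((self.n_reactions, self.n_species))
        for j, rxn in enumerate(self.reactions):
            idx, coef = self._ridx[j], self._rcoef[j]
            conc = c[idx]
            law = rxn.rate_law
            base = np.prod(conc**coef) if idx.size else 1.0
            # d(prod c_i^m_i)/dc_i computed per reactant without dividing
            # by a possibly-zero concentration
            for pos, i in enumerate(idx):
                others = np.prod(np.delete(conc, pos) ** np.delete(coef, pos))
                m = coef[pos]
                dbase = m * conc[pos] ** (m - 1.0) if m != 1.0 else 1.0
                dbase *= others
                if isinstance(law, MassAction):
                    J[j, i] += law.k * dbase
                else:
                    ca = c[self.index[law.autocatalyst]]
                    auto = ca**law.p if ca > 0.0 else 0.0
                    J[j, i] += (law.k_direct + law.k_auto * auto) * dbase
            if isinstance(law, EmpiricalAutocatalytic):
                ia = self.index[law.autocatalyst]
                ca = c[ia]
                if ca > 0.0:
                    J[j, ia] += law.k_auto * base * law.p * ca ** (law.p - 1.0)
        return J

    def rhs(self, flow: "FlowConfig | None" = None) -> Callable[[float, np.ndarray], np.ndarray]:
        """Solver-facing ``f(t, y)``; clips small negative y to 0 internally."""
        S = self.stoichiometry.astype(np.float64)
        if flow is None:
            def f(t: float, y: np.ndarray) -> np.ndarray:
                return S @ evaluate_rates(self, y, strict=False)
        else:
            k0, feed = flow.k0, flow.feed
            def f(t: float, y: np.ndarray) -> np.ndarray:
                return S @ evaluate_rates(self, y, strict=False) + k0 * (feed - y)
        return f

    def jacobian(self, flow: "FlowConfig | None" = None) -> Callable[[float, np.ndarray], np.ndarray]:
        """Solver-facing ``J(t, y) = S @ dv/dc (- k0 I in flow mode)``."""
        S = self.stoichiometry.astype(np.float64)
        k0 = 0.0 if flow is None else flow.k0
        eye = np.eye(self.n_species)

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            return S @ self.rate_jacobian(y) - k0 * eye

        return jac

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, "
            f"{self.n_reactions} reactions)"
        )


@dataclass(frozen=True)
class FlowConfig:
    """CSTR flow settings: inflow/outflow rate ``k0`` (s^-1) and feed.

    All species flow out at rate ``k0``; species absent from the feed have
    feed concentration 0.  Residence time is ``tau = 1/k0``.
    """

    k0: float
    feed: np.ndarray

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ValueError(f"flow rate k0 must be >= 0, got {self.k0}")

    @property
    def residence_time(self) -> float:
        if self.k0 == 0:
            return np.inf
        return 1.0 / self.k0


def build_stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Integer matrix S with S[i, j] = net production of species i in reaction j."""
    S = np.zeros((len(network.species), len(network.reactions)), dtype=np.int64)
    for j, rxn in enumerate(network.reactions):
        for name, coeff in rxn.reactants.items():
            S[network.index[name], j] -= coeff
        for name, coeff in rxn.products.items():
            S[network.index[name], j] += coeff
    return S


def _clip_state(c: np.ndarray, strict: bool) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64)
    if strict and c.min(initial=0.0) < -NEGATIVE_CLIP_TOL:
        raise NumericalStateError(
            f"concentration {c.min()} below clip tolerance -{NEGATIVE_CLIP_TOL}"
        )
    return np.clip(c, 0.0, None)


def evaluate_rates(
    network: ReactionNetwork, state: np.ndarray, *, strict: bool = True
) -> np.ndarray:
    """Reaction rate vector v(c) in M/s, aligned to reaction order.

    Mass-action rate is ``k * prod [reactant]^coeff``; the empirical law adds
    the autocatalytic term with ``0^p := 0``.  With ``strict`` (the default)
    a concentration below ``-NEGATIVE_CLIP_TOL`` raises
    :class:`NumericalStateError`; small negatives are clipped to 0 either way.
    """
    c = _clip_state(state, strict)
    v = np.empty(network.n_reactions)
    for j, rxn in enumerate(network.reactions):
        idx, coef = network._ridx[j], network._rcoef[j]
        base = np.prod(c[idx] ** coef) if idx.size else 1.0
        law = rxn.rate_law
        if isinstance(law, MassAction):
            v[j] = law.k * base
        else:
            ca = c[network.index[law.autocatalyst]]
            auto = ca**law.p if ca > 0.0 else 0.0
            v[j] = base * (law.k_direct + law.k_auto * auto)
    return v


def assemble_rhs(
    network: ReactionNetwork,
    state: np.ndarray,
    flow: FlowConfig | None = None,
) -> np.ndarray:
    """Time derivative dc/dt (M/s): ``S @ v(c)``, plus ``k0*(feed - c)`` in flow mode."""
    c = _clip_state(state, strict=True)
    dcdt = network.stoichiometry.astype(np.float64) @ evaluate_rates(network, c)
    if flow is not None:
        dcdt = dcdt + flow.k0 * (flow.feed - c)
    return dcdt


def conservation_laws(network: ReactionNetwork) -> list[np.ndarray]:
    """Integer basis of the left null space of S (conserved moieties).

    Each returned vector ``w`` satisfies ``w @ S == 0`` exactly, so
    ``w . c(t)`` is constant along any batch trajectory.  Computed by exact
    rational elimination (sympy nullspace of S^T), then scaled to primitive
    integer vectors with positive leading entry.
    """
    S = sympy.Matrix(network.stoichiometry.tolist())
    basis = S.T.nullspace()
    out: list[np.ndarray] = []
    for vec in basis:
        fracs = [Fraction(sympy.nsimplify(x)) for x in vec]
        denom = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = [int(f * denom) for f in fracs]
        g = np.gcd.reduce([abs(i) for i in ints if i != 0] or [1])
        ints = [i // g for i in ints]
        lead = next((i for i in ints if i != 0), 1)
        if lead < 0:
            ints = [-i for i in ints]
        out.append(np.array(ints, dtype=np.int64))
    return out
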