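"""Mechanism families and named parameter presets.

Four families are provided:

* :func:`landolt` — the three-step Landolt-type core
  ``A+B -> C``, ``B+C -> D``, ``A+D -> 2C``.  The sum of the last two steps
  has the stoichiometry of the first, and the slow step of that loop is
  first order in the product C, so the loop is a mechanistic (first-order)
  autocatalysis.
* :func:`empirical_autocatalysis` — a single step ``A+B -> C`` carrying the
  two-term empirical rate law with fractional autocatalyst order p.
* :func:`supercatalysis_full` / :func:`supercatalysis_reduced` — the core
  extended by a fast pre-equilibrium ``B+C <-> BC`` followed by
  ``BC+C -> D`` and ``A+D -> 3C``; with the pre-equilibrium eliminated the
  autocatalytic step becomes ``B+2C -> D`` at rate ``k'[B][C]^2``
  (second-order autocatalysis, "supercatalysis").
* :func:`hypercycle` — two Landolt-type cycles (autocatalysts C and Z)
  mutually catalysing each other through ``A+Z -> AZ``, ``AZ+B -> C+Z`` and
  ``X+C -> XC``, ``XC+Y -> Z+C``.

Rate-constant naming
--------------------
The hypercycle literature uses two clashing numbering schemes for k1..k10
(one ordered by the equations, one used in figure captions where the fast
steps are k3=k5=k8=k10 and the cross steps are k4 and k9).  This package
uses role-based names throughout; the mapping is

====================  ==========  ================  ====================
role name             step        equation-order k  caption-order k
====================  ==========  ================  ====================
kAB_direct            A+B -> C    k1                k1
kBC_auto              B+C -> D    k2                k2
kAD_fast              A+D -> 2C   k3                k3
kXY_direct            X+Y -> Z    k4                k6
kYZ_auto              Y+Z -> W    k5                k7
kXW_fast              X+W -> 2Z   k6                k8
kAZ_cross             A+Z -> AZ   k7                k4
kAZB_fast             AZ+B -> C+Z k8                k5
kXC_cross             X+C -> XC   k9                k9
kXCY_fast             XC+Y -> Z+C k10               k10
====================  ==========  ================  ====================

Preset parameter values follow the caption-order scheme (the one attached
to the published parameter sets).  Similarly for supercatalysis the five
caption labels kI..kV are used: kI (A+B->C), kII/kIII
(forward/reverse of B+C<->BC), kIV (BC+C->D), kV (A+D->3C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from .network import (
    EmpiricalAutocatalytic,
    MassAction,
    Reaction,
    ReactionNetwork,
)

__all__ = [
    "landolt",
    "empirical_autocatalysis",
    "supercatalysis_full",
    "supercatalysis_reduced",
    "HypercycleParams",
    "hypercycle",
    "figure1_pairs",
    "figure3_pairs",
    "ModelPreset",
    "preset",
    "list_presets",
    "PresetLookupError",
    "FIGURE1_RATIOS",
    "FIGURE1_RATE_PRODUCT",
    "FIGURE3_RATIOS",
    "FIGURE3_RATE_PRODUCT",
    "FIGURE4_CROSS_LIST",
]


def landolt(k_direct: float, k_auto: float, k_fast: float) -> ReactionNetwork:
    """Three-step Landolt-type autocatalytic core over species A, B, C, D.

    Parameters are the rate coefficients (M^-1 s^-1) of the direct step
    ``A+B -> C``, the rate-determining autocatalytic step ``B+C -> D`` and
    the fast step ``A+D -> 2C``.  Sigmoid product growth requires
    ``k_fast >> k_auto, k_direct``.
    """
    return ReactionNetwork(
        ["A", "B", "C", "D"],
        [
            Reaction({"A": 1, "B": 1}, {"C": 1}, MassAction(k_direct), "A + B -> C"),
            Reaction({"B": 1, "C": 1}, {"D": 1}, MassAction(k_auto), "B + C -> D"),
            Reaction({"A": 1, "D": 1}, {"C": 2}, MassAction(k_fast), "A + D -> 2C"),
        ],
    )


def empirical_autocatalysis(k_direct: float, k_auto: float, p: float) -> ReactionNetwork:
    """Single-step ``A+B -> C`` with empirical rate ``kd[A][B] + ka[A][B][C]^p``.

    ``p`` is the formal kinetic order of the autocatalyst (p=1 gives
    "exponential", p=0.5 "parabolic" template growth in the conventional
    nomenclature).
    """
    if p <= 0:
        raise ValueError(f"autocatalyst order p must be > 0, got {p}")
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            Reaction(
                {"A": 1, "B": 1},
                {"C": 1},
                EmpiricalAutocatalytic(k_direct, k_auto, p, "C"),
                "A + B -> C (empirical)",
            )
        ],
    )


def supercatalysis_full(
    kI: float, kII: float, kIII: float, kIV: float, kV: float
) -> ReactionNetwork:
    """Full supercatalysis mechanism over A, B, C, BC, D (5 reactions).

    Steps: ``A+B -> C`` (kI), ``B+C <-> BC`` (kII forward M^-1 s^-1 /
    kIII reverse s^-1, a fast pre-equilibrium with K = kII/kIII),
    ``BC+C -> D`` (kIV), ``A+D -> 3C`` (kV).  The loop (2)-(4) has net
    stoichiometry ``A+B -> C`` and effective rate second order in C.
    """
    return ReactionNetwork(
        ["A", "B", "C", "BC", "D"],
        [
            Reaction({"A": 1, "B": 1}, {"C": 1}, MassAction(kI), "A + B -> C"),
            Reaction({"B": 1, "C": 1}, {"BC": 1}, MassAction(kII), "B + C -> BC"),
            Reaction({"BC": 1}, {"B": 1, "C": 1}, MassAction(kIII), "BC -> B + C"),
            Reaction({"BC": 1, "C": 1}, {"D": 1}, MassAction(kIV), "BC + C -> D"),
            Reaction({"A": 1, "D": 1}, {"C": 3}, MassAction(kV), "A + D -> 3C"),
        ],
    )


def supercatalysis_reduced(kI: float, k_prime: float, kV: float) -> ReactionNetwork:
    """Pre-equilibrium-reduced supercatalysis over A, B, C, D (3 reactions).

    The fast equilibrium ``B+C <-> BC`` is eliminated: with
    ``[BC] = K [B][C]`` (K = kII/kIII) the step ``BC+C -> D`` becomes
    ``B+2C -> D`` at mass-action rate ``k'[B][C]^2`` with ``k' = K*kIV``.
    """
    return ReactionNetwork(
        ["A", "B", "C", "D"],
        [
            Reaction({"A": 1, "B": 1}, {"C": 1}, MassAction(kI), "A + B -> C"),
            Reaction({"B": 1, "C": 2}, {"D": 1}, MassAction(k_prime), "B + 2C -> D"),
            Reaction({"A": 1, "D": 1}, {"C": 3}, MassAction(kV), "A + D -> 3C"),
        ],
    )


@dataclass(frozen=True)
class HypercycleParams:
    """Role-named rate coefficients (all M^-1 s^-1) of the simplest hypercycle.

    Cycle 1 turns A+B into autocatalyst C; cycle 2 turns X+Y into
    autocatalyst Z.  The cross steps couple them: Z catalyses C production
    (kAZ_cross/kAZB_fast) and C catalyses Z production
    (kXC_cross/kXCY_fast).  Sigmoid growth requires every ``*_fast``
    coefficient to dominate the slow ones.
    """

    kAB_direct: float
    kBC_auto: float
    kAD_fast: float
    kXY_direct: float
    kYZ_auto: float
    kXW_fast: float
    kAZ_cross: float
    kAZB_fast: float
    kXC_cross: float
    kXCY_fast: float

    def swapped(self) -> "HypercycleParams":
        """Exchange the cycle-1 and cycle-2 parameter blocks (C <-> Z roles)."""
        return HypercycleParams(
            kAB_direct=self.kXY_direct,
            kBC_auto=self.kYZ_auto,
            kAD_fast=self.kXW_fast,
            kXY_direct=self.kAB_direct,
            kYZ_auto=self.kBC_auto,
            kXW_fast=self.kAD_fast,
            kAZ_cross=self.kXC_cross,
            kAZB_fast=self.kXCY_fast,
            kXC_cross=self.kAZ_cross,
            kXCY_fast=self.kAZB_fast,
        )


#: base parameter set of the hypercycle competition figure (caption-order
#: k1=1e-7, k2=1e-1, k6=1e-6, k7=1e-2, k4=3e-3, fast steps 1e7); the
#: cross coefficient kXC_cross (caption k9) is the swept parameter.
FIGURE4_BASE = HypercycleParams(
    kAB_direct=1e-7,
    kBC_auto=1e-1,
    kAD_fast=1e7,
    kXY_direct=1e-6,
    kYZ_auto=1e-2,
    kXW_fast=1e7,
    kAZ_cross=3e-3,
    kAZB_fast=1e7,
    kXC_cross=3e-7,
    kXCY_fast=1e7,
)

#: swept kXC_cross (caption k9) values of the batch competition figure, in
#: caption order; the decoupled reference case sets both cross terms to 0.
FIGURE4_CROSS_LIST = [3e-7, 1e-4, 1e-3, 1e-1, 1.0, 10.0]


def hypercycle(params: HypercycleParams) -> ReactionNetwork:
    """Simplest hypercycle: 10 species, 10 reactions.

    Setting both cross coefficients to zero decouples the two cycles into
    independent Landolt-type systems.
    """
    p = params
    return ReactionNetwork(
        ["A", "B", "C", "D", "X", "Y", "Z", "W", "AZ", "XC"],
        [
            Reaction({"A": 1, "B": 1}, {"C": 1}, MassAction(p.kAB_direct), "A + B -> C"),
            Reaction({"B": 1, "C": 1}, {"D": 1}, MassAction(p.kBC_auto), "B + C -> D"),
            Reaction({"A": 1, "D": 1}, {"C": 2}, MassAction(p.kAD_fast), "A + D -> 2C"),
            Reaction({"X": 1, "Y": 1}, {"Z": 1}, MassAction(p.kXY_direct), "X + Y -> Z"),
            Reaction({"Y": 1, "Z": 1}, {"W": 1}, MassAction(p.kYZ_auto), "Y + Z -> W"),
            Reaction({"X": 1, "W": 1}, {"Z": 2}, MassAction(p.kXW_fast), "X + W -> 2Z"),
            Reaction({"A": 1, "Z": 1}, {"AZ": 1}, MassAction(p.kAZ_cross), "A + Z -> AZ"),
            Reaction({"AZ": 1, "B": 1}, {"C": 1, "Z": 1}, MassAction(p.kAZB_fast), "AZ + B -> C + Z"),
            Reaction({"X": 1, "C": 1}, {"XC": 1}, MassAction(p.kXC_cross), "X + C -> XC"),
            Reaction({"XC": 1, "Y": 1}, {"Z": 1, "C": 1}, MassAction(p.kXCY_fast), "XC + Y -> Z + C"),
        ],
    )


# --- printed sweep constraints ------------------------------------------------

#: k_auto/k_direct ratios of the Landolt parametrisation sweep, in printed order
FIGURE1_RATIOS = [1e5, 2.5e4, 1.111e4, 6250.0, 4000.0, 1562.5, 1000.0, 250.0,
                  40.0, 10.0, 1.0, 0.1]
#: the constant product k_direct * k_auto (M^-2 s^-2) held during that sweep
FIGURE1_RATE_PRODUCT = 1e-5


def figure1_pairs() -> list[tuple[float, float]]:
    """(k_direct, k_auto) pairs solving k1*k2 = 1e-5 with each listed ratio."""
    return [
        (math.sqrt(FIGURE1_RATE_PRODUCT / r), math.sqrt(FIGURE1_RATE_PRODUCT * r))
        for r in FIGURE1_RATIOS
    ]


#: kIV/kI ratios of the supercatalysis sweep, stored verbatim in printed order
FIGURE3_RATIOS = [1e7, 1e5, 1e3, 2.5e4, 4000.0, 250.0, 10.0]
#: the constant product kI * K * kIV (M^-3 s^-2) held during that sweep
FIGURE3_RATE_PRODUCT = 1e-5
#: pre-equilibrium constant K = kII/kIII (M^-1)
FIGURE3_K_EQ = 1e6 / 1e8


def figure3_pairs() -> list[tuple[float, float]]:
    """(kI, kIV) pairs solving kI*K*kIV = 1e-5 with each listed kIV/kI ratio."""
    return [
        (
            math.sqrt(FIGURE3_RATE_PRODUCT / (FIGURE3_K_EQ * r)),
            math.sqrt(FIGURE3_RATE_PRODUCT * r / FIGURE3_K_EQ),
        )
        for r in FIGURE3_RATIOS
    ]


# --- preset registry ----------------------------------------------------------


class PresetLookupError(KeyError):
    """Unknown preset name; the message lists the available names."""


@dataclass(frozen=True)
class ModelPreset:
    """A mechanism + initial state + optional sweep, traceable to a caption."""

    name: str
    network: ReactionNetwork
    initial: dict[str, float]
    sweep: tuple[dict[str, float], ...] | None = None
    notes: str = ""

    def initial_state(self):
        return self.network.state(self.initial)


_BATCH_INIT_2 = {"A": 1.0, "B": 1.0}
_BATCH_INIT_4 = {"A": 1.0, "B": 1.0, "X": 1.0, "Y": 1.0}


def _build_presets() -> dict[str, ModelPreset]:
    presets: dict[str, ModelPreset] = {}

    k1_f2, k2_f2, k3 = 1e-6, 1e-2, 1e7
    presets["fig1"] = ModelPreset(
        name="fig1",
        network=landolt(*figure1_pairs()[0], k3),
        initial=_BATCH_INIT_2,
        sweep=tuple(
            {"k_direct": kd, "k_auto": ka, "ratio": r}
            for (kd, ka), r in zip(figure1_pairs(), FIGURE1_RATIOS)
        ),
        notes=(
            "Landolt core, k_auto/k_direct swept over 12 printed ratios at "
            "constant k_direct*k_auto = 1e-5 M^-2 s^-2; k_fast = 1e7 M^-1 s^-1, "
            "[A]0=[B]0=1.0 M, [C]0=0."
        ),
    )
    presets["fig2_landolt"] = ModelPreset(
        name="fig2_landolt",
        network=landolt(k1_f2, k2_f2, k3),
        initial=_BATCH_INIT_2,
        notes="Landolt core with k1=1e-6, k2=1e-2, k3=1e7 M^-1 s^-1 (black curve).",
    )
    presets["fig2_empirical"] = ModelPreset(
        name="fig2_empirical",
        network=empirical_autocatalysis(1e-13, 8e-3, 0.5),
        initial=_BATCH_INIT_2,
        notes=(
            "Empirical two-term law, k_direct=1e-13 M^-1 s^-1, "
            "k_auto=8e-3 M^-1.5 s^-1, p=0.5 (blue curve)."
        ),
    )

    kI0, kIV0 = figure3_pairs()[0]
    presets["fig3"] = ModelPreset(
        name="fig3",
        network=supercatalysis_full(kI0, 1e6, 1e8, kIV0, 1e7),
        initial=_BATCH_INIT_2,
        sweep=tuple(
            {"kI": kI, "kIV": kIV, "ratio": r}
            for (kI, kIV), r in zip(figure3_pairs(), FIGURE3_RATIOS)
        ),
        notes=(
            "Supercatalysis, kIV/kI swept over 7 printed ratios (verbatim "
            "order) at constant kI*K*kIV = 1e-5 M^-3 s^-2 with K = kII/kIII "
            "= 0.01 M^-1 (kII=1e6 M^-1 s^-1, kIII=1e8 s^-1); kV=1e7."
        ),
    )

    presets["fig4"] = ModelPreset(
        name="fig4",
        network=hypercycle(FIGURE4_BASE),
        initial=_BATCH_INIT_4,
        sweep=tuple({"kXC_cross": k9} for k9 in FIGURE4_CROSS_LIST),
        notes=(
            "Hypercycle batch competition; caption-order k1=1e-7, k2=1e-1, "
            "k6=1e-6, k7=1e-2, k4=3e-3, fast steps 1e7 M^-1 s^-1; caption k9 "
            "(kXC_cross) swept; the decoupled reference sets k4=k9=0."
        ),
    )
    presets["fig5_optionA"] = ModelPreset(
        name="fig5_optionA",
        network=hypercycle(FIGURE4_BASE),  # kXC_cross = 3e-7 (solid-line case)
        initial=_BATCH_INIT_4,
        notes=(
            "Option A: hypercycle base parameters with kXC_cross=3e-7 "
            "(solid-line batch case); C ignites far earlier than Z, so flow "
            "selects C as the residence time shortens."
        ),
    )
    presets["fig6_optionB"] = ModelPreset(
        name="fig6_optionB",
        network=hypercycle(replace(FIGURE4_BASE, kXC_cross=0.093)),
        initial=_BATCH_INIT_4,
        notes=(
            "Option B: kXC_cross=0.093 makes the batch C and Z profiles "
            "overlap; the flow-rate sweep cannot select between them."
        ),
    )
    presets["fig7_optionC"] = ModelPreset(
        name="fig7_optionC",
        network=hypercycle(
            replace(FIGURE4_BASE, kXY_direct=0.002, kYZ_auto=0.02, kXC_cross=0.03)
        ),
        initial=_BATCH_INIT_4,
        notes=(
            "Option C: k6=0.002, k7=0.02, k9=0.03 (caption order); batch "
            "profiles cross near half conversion, giving an undershoot-"
            "overshoot selection ratio under flow."
        ),
    )
    return presets


_PRESETS = _build_presets()


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ModelPreset:
    """Look up a registered preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise PresetLookupError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None
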