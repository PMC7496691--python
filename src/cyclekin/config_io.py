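"""Load and save mechanisms as YAML/JSON configs with reaction strings.

Config layout::

    species: [A, B, C, D]          # optional; inferred from reactions
    reactions:
      - equation: "A + B -> C"
        k: 1.0e-6
        label: direct              # optional
      - equation: "B + C <-> BC"   # reversible: expands to two reactions
        k_forward: 1.0e+6
        k_reverse: 1.0e+8
      - equation: "A + B -> C"     # empirical autocatalytic rate law
        rate:
          kind: empirical
          k_direct: 1.0e-13
          k_auto: 8.0e-3
          p: 0.5
          autocatalyst: C
    initial: {A: 1.0, B: 1.0}      # M; absent species start at 0
    flow:                          # optional CSTR block
      k0: 1.0e-2                   # s^-1
      feed: {A: 1.0, B: 1.0}       # M

``load_mechanism``/``dump_mechanism`` round-trip: dumping a loaded config
and loading it again reproduces the same network, initial state and flow
settings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .network import (
    EmpiricalAutocatalytic,
    FlowConfig,
    MassAction,
    Reaction,
    ReactionNetwork,
)

__all__ = [
    "Mechanism",
    "parse_equation",
    "format_equation",
    "load_mechanism",
    "loads_mechanism",
    "dump_mechanism",
    "dumps_mechanism",
]

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s*)?([A-Za-z][A-Za-z0-9_]*)\s*$")


@dataclass
class Mechanism:
    """A parsed mechanism config: network + initial state (+ optional flow)."""

    network: ReactionNetwork
    initial: np.ndarray
    flow: FlowConfig | None = None


def _parse_side(text: str) -> dict[str, int]:
    side: dict[str, int] = {}
    text = text.strip()
    if not text or text == "0":
        return side
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"cannot parse reaction term {term!r}")
        coeff = int(m.group(1) or 1)
        name = m.group(2)
        side[name] = side.get(name, 0) + coeff
    return side


def parse_equation(text: str) -> tuple[dict[str, int], dict[str, int], bool]:
    """Parse ``"A + 2 B -> C"`` / ``"B + C <-> BC"``.

    Returns (reactants, products, reversible).
    """
    if "<->" in text:
        lhs, rhs = text.split("<->")
        reversible = True
    elif "->" in text:
        lhs, rhs = text.split("->")
        reversible = False
    else:
        raise ValueError(f"reaction {text!r} needs '->' or '<->'")
    return _parse_side(lhs), _parse_side(rhs), reversible


def format_equation(
    reactants: Mapping[str, int], products: Mapping[str, int], reversible: bool = False
) -> str:
    def fmt(side: Mapping[str, int]) -> str:
        if not side:
            return "0"
        return " + ".join(
            (f"{c} {s}" if c != 1 else s) for s, c in side.items()
        )

    arrow = "<->" if reversible else "->"
    return f"{fmt(reactants)} {arrow} {fmt(products)}"


def _rate_law_from_entry(entry: Mapping[str, Any]) -> Any:
    rate = entry.get("rate")
    if rate is not None:
        kind = rate.get("kind", "mass_action")
        if kind == "empirical":
            return EmpiricalAutocatalytic(
                k_direct=float(rate["k_direct"]),
                k_auto=float(rate["k_auto"]),
                p=float(rate["p"]),
                autocatalyst=str(rate["autocatalyst"]),
            )
        if kind == "mass_action":
            return MassAction(k=float(rate["k"]))
        raise ValueError(f"unknown rate law kind {kind!r}")
    return MassAction(k=float(entry["k"]))


def loads_mechanism(config: Mapping[str, Any] | str) -> Mechanism:
    """Build a :class:`Mechanism` from a config dict or YAML string."""
    if isinstance(config, str):
        config = yaml.safe_load(config)
    assert isinstance(config, Mapping)

    reactions: list[Reaction] = []
    referenced: list[str] = []

    def note(names) -> None:
        for n in names:
            if n not in referenced:
                referenced.append(n)

    for entry in config["reactions"]:
        reactants, products, reversible = parse_equation(entry["equation"])
        note(reactants)
        note(products)
        label = str(entry.get("label", ""))
        if reversible:
            reactions.append(
                Reaction(reactants, products, MassAction(float(entry["k_forward"])),
                         label=label or format_equation(reactants, products))
            )
            reactions.append(
                Reaction(products, reactants, MassAction(float(entry["k_reverse"])),
                         label=(label + " (reverse)") if label
                         else format_equation(products, reactants))
            )
        else:
            law = _rate_law_from_entry(entry)
            if isinstance(law, EmpiricalAutocatalytic):
                note([law.autocatalyst])
            reactions.append(
                Reaction(reactants, products, law,
                         label=label or format_equation(reactants, products))
            )

    species = [str(s) for s in config.get("species", referenced)]
    network = ReactionNetwork(species, reactions)

    initial = network.state({str(k): float(v)
                             for k, v in (config.get("initial") or {}).items()})

    flow = None
    if config.get("flow") is not None:
        fb = config["flow"]
        feed = network.state({str(k): float(v)
                              for k, v in (fb.get("feed") or {}).items()})
        flow = FlowConfig(k0=float(fb["k0"]), feed=feed)
    return Mechanism(network=network, initial=initial, flow=flow)


def load_mechanism(path: str | Path) -> Mechanism:
    """Load a mechanism config from a YAML (or JSON) file."""
    with open(path) as fh:
        return loads_mechanism(yaml.safe_load(fh))


def _mechanism_to_config(mech: Mechanism) -> dict[str, Any]:
    net = mech.network
    entries: list[dict[str, Any]] = []
    skip: set[int] = set()
    for j, rxn in enumerate(net.reactions):
        if j in skip:
            continue
        # re-join a reversible pair (consecutive mass-action mirror steps)
        nxt = net.reactions[j + 1] if j + 1 < len(net.reactions) else None
        if (
            nxt is not None
            and isinstance(rxn.rate_law, MassAction)
            and isinstance(nxt.rate_law, MassAction)
            and dict(nxt.reactants) == dict(rxn.products)
            and dict(nxt.products) == dict(rxn.reactants)
        ):
            entries.append({
                "equation": format_equation(rxn.reactants, rxn.products, True),
                "k_forward": rxn.rate_law.k,
                "k_reverse": nxt.rate_law.k,
            })
            skip.add(j + 1)
            continue
        entry: dict[str, Any] = {
            "equation": format_equation(rxn.reactants, rxn.products)
        }
        if isinstance(rxn.rate_law, MassAction):
            entry["k"] = rxn.rate_law.k
        else:
            law = rxn.rate_law
            entry["rate"] = {
                "kind": "empirical",
                "k_direct": law.k_direct,
                "k_auto": law.k_auto,
                "p": law.p,
                "autocatalyst": law.autocatalyst,
            }
        if rxn.label and rxn.label != format_equation(rxn.reactants, rxn.products):
            entry["label"] = rxn.label
        entries.append(entry)

    config: dict[str, Any] = {
        "species": list(net.species),
        "reactions": entries,
        "initial": {
            s: float(c) for s, c in zip(net.species, mech.initial) if c != 0.0
        },
    }
    if mech.flow is not None:
        config["flow"] = {
            "k0": float(mech.flow.k0),
            "feed": {
                s: float(c)
                for s, c in zip(net.species, mech.flow.feed)
                if c != 0.0
            },
        }
    return config


def dumps_mechanism(mech: Mechanism) -> str:
    """Serialise a mechanism back to YAML text (round-trips with loads)."""
    return yaml.safe_dump(_mechanism_to_config(mech), sort_keys=False)


def dump_mechanism(mech: Mechanism, path: str | Path) -> None:
    Path(path).write_text(dumps_mechanism(mech))
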