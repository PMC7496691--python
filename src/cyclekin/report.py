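"""Config-driven runs and the end-to-end verification report.

This is the workhorse behind the command-line interface: a
:class:`RunConfig` names either a registered preset or a mechanism config
file, a mode (batch / flow / sweep) and solver settings; :func:`run`
executes it and writes deterministic CSV + JSON artifacts (and optional
plots) to the output directory.

:func:`verify` re-derives the headline quantitative statements of the
hypercycle flow-selection analysis from scratch and reports pass/fail:
the coexistence ratio at long residence time, the selection-transition
residence time, the option-C winner share, and the agreement between the
full and pre-equilibrium-reduced supercatalysis models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import dynamics, models
from .config_io import load_mechanism
from .dynamics import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    FlowConfig,
    integrate_batch,
    log_k0_grid,
    steady_state_flow,
    sweep_flow,
    transition_flow_rate,
)
from .network import MassAction, Reaction, ReactionNetwork

__all__ = [
    "RunConfig",
    "run",
    "verify",
    "VerificationCheck",
    "option_a_low_flow_ratio",
    "option_a_transition",
    "option_c_winner_share",
    "supercatalysis_reduction_error",
]

log = logging.getLogger("cyclekin")

_BATCH_FEED = {"A": 1.0, "B": 1.0, "X": 1.0, "Y": 1.0}


@dataclass
class RunConfig:
    """One simulation run: exactly one of ``preset`` / ``mechanism``."""

    preset: str | None = None
    mechanism: str | Path | None = None
    mode: str = "batch"  # batch | flow | sweep
    overrides: Mapping[str, float] = field(default_factory=dict)
    t_end: float = 5000.0
    k0: float = 1e-2
    k0_grid: tuple[float, float, int] = (-5.0, 1.0, 25)  # log10 lo, hi, per decade
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    out_dir: str | Path = "cyclekin_out"
    plot: bool = False

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.mechanism is None):
            raise ValueError("specify exactly one of preset / mechanism file")
        if self.mode not in {"batch", "flow", "sweep"}:
            raise ValueError(f"unknown mode {self.mode!r}")


def _apply_overrides(
    network: ReactionNetwork, overrides: Mapping[str, float]
) -> ReactionNetwork:
    """Replace mass-action coefficients by reaction label."""
    if not overrides:
        return network
    labels = [r.label for r in network.reactions]
    unknown = set(overrides) - set(labels)
    if unknown:
        raise ValueError(
            f"override targets {sorted(unknown)} not among reaction labels {labels}"
        )
    new_reactions = []
    for rxn in network.reactions:
        if rxn.label in overrides:
            if not isinstance(rxn.rate_law, MassAction):
                raise ValueError(
                    f"can only override mass-action coefficients ({rxn.label})"
                )
            rxn = Reaction(
                rxn.reactants, rxn.products,
                MassAction(float(overrides[rxn.label])), rxn.label,
            )
        new_reactions.append(rxn)
    return ReactionNetwork(network.species, new_reactions)


def _resolve(config: RunConfig):
    if config.preset is not None:
        p = models.preset(config.preset)
        network = _apply_overrides(p.network, config.overrides)
        y0 = p.network.state(p.initial)
        feed = y0.copy()
        notes = p.notes
    else:
        mech = load_mechanism(config.mechanism)
        network = _apply_overrides(mech.network, config.overrides)
        y0 = mech.initial
        feed = mech.flow.feed if mech.flow is not None else y0.copy()
        notes = f"mechanism file {config.mechanism}"
    return network, y0, feed, notes


def _json_default(o: Any):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run(config: RunConfig) -> dict[str, Any]:
    """Execute a run config; returns (and writes) the summary dict."""
    network, y0, feed, notes = _resolve(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    solver = {"method": "BDF", "rtol": config.rtol, "atol": config.atol}
    log.info("run mode=%s species=%s", config.mode, network.species)
    for rxn in network.reactions:
        log.info("  %s  k=%r", rxn.label, rxn.rate_law)
    summary: dict[str, Any] = {
        "mode": config.mode,
        "provenance": notes,
        "solver": solver,
        "species": network.species,
        "overrides": dict(config.overrides),
    }

    if config.mode == "batch":
        traj = integrate_batch(
            network, y0, config.t_end, rtol=config.rtol, atol=config.atol
        )
        traj.to_frame().to_csv(out / "trajectory.csv", index=False)
        metrics: dict[str, Any] = {}
        for sp in ("C", "Z"):
            if sp in network.species:
                metrics[f"conversion_{sp}"] = dynamics.conversion(traj, sp, 1.0)
                ip = dynamics.induction_period(traj, sp)
                metrics[f"induction_period_{sp}"] = ip
        summary |= {"t_end": config.t_end, "final": traj.final, "metrics": metrics}
        if config.plot:
            _plot_trajectory(traj, out / "trajectory.png")
    elif config.mode == "flow":
        flow = FlowConfig(k0=config.k0, feed=feed)
        st = steady_state_flow(
            network, flow, y0, rtol=config.rtol, atol=config.atol
        )
        summary |= {
            "k0": config.k0,
            "steady_state": st.concentrations,
            "residual": st.residual,
            "converged": bool(st.converged),
            "t_reached": st.t_reached,
        }
    else:  # sweep
        lo, hi, per_decade = config.k0_grid
        grid = log_k0_grid(lo, hi, int(per_decade))
        sweep = sweep_flow(
            network, feed, grid, y0, rtol=config.rtol, atol=config.atol
        )
        sweep.to_frame().to_csv(out / "sweep.csv", index=False)
        tr = transition_flow_rate(sweep)
        summary |= {
            "k0_grid": [lo, hi, per_decade],
            "ratio_low_k0": float(sweep.ratio[0]),
            "ratio_high_k0": float(sweep.ratio[-1]),
            "all_converged": bool(sweep.converged.all()),
            "transition": None
            if tr is None
            else {"k0": tr.k0, "tau": tr.tau, "level": tr.level},
        }
        if config.plot:
            _plot_sweep(sweep, out / "sweep.png")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
    return summary


def _plot_trajectory(traj, path):  # pragma: no cover - convenience output only
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for sp in traj.species:
        ax.plot(traj.times, traj[sp], label=sp)
    ax.set_xlabel("t / s")
    ax.set_ylabel("concentration / M")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_sweep(sweep, path):  # pragma: no cover - convenience output only
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(np.log10(sweep.k0_grid), sweep.ratio, "o-")
    ax.set_xlabel("log10 k0")
    ax.set_ylabel(f"[{sweep.z_species}] / ([{sweep.c_species}]+[{sweep.z_species}])")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --- headline quantitative checks --------------------------------------------


def _hypercycle_setup(preset_name: str):
    p = models.preset(preset_name)
    y0 = p.network.state(p.initial)
    return p.network, y0


def option_a_low_flow_ratio(
    k0: float = 1e-5, *, rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL
) -> float:
    """Selection ratio r = [Z]/([C]+[Z]) of the option-A CSTR at low flow.

    At long residence time both cycles convert fully and the equal feeds
    give equal autocatalyst amounts, so r -> 0.5.
    """
    network, y0 = _hypercycle_setup("fig5_optionA")
    st = steady_state_flow(
        network, FlowConfig(k0=k0, feed=y0.copy()), y0, rtol=rtol, atol=atol
    )
    c = st.concentrations[network.species.index("C")]
    z = st.concentrations[network.species.index("Z")]
    return float(z / (c + z))


def option_a_transition(
    lo: float = -4.0, hi: float = 0.0, per_decade: int = 25
) -> tuple[dynamics.TransitionResult | None, dynamics.FlowSweepResult]:
    """Sweep the option-A CSTR and locate the r = 0.25 midpoint crossing.

    Returns the interpolated transition (k0*, tau* = 1/k0*) and the sweep.
    """
    network, y0 = _hypercycle_setup("fig5_optionA")
    grid = log_k0_grid(lo, hi, per_decade)
    sweep = sweep_flow(network, y0.copy(), grid, y0)
    return transition_flow_rate(sweep, level=0.25), sweep


def option_c_winner_share(log10_k0: float = -1.1) -> float:
    """Percent of total autocatalyst present as C in the option-C CSTR."""
    network, y0 = _hypercycle_setup("fig7_optionC")
    st = steady_state_flow(
        network, FlowConfig(k0=10.0**log10_k0, feed=y0.copy()), y0
    )
    c = st.concentrations[network.species.index("C")]
    z = st.concentrations[network.species.index("Z")]
    return float(100.0 * c / (c + z))


def supercatalysis_reduction_error(t_end: float = 5000.0) -> tuple[float, float]:
    """(K, worst sup-norm relative error of [C]) over the supercatalysis sweep.

    Builds each (kI, kIV) pair of the printed sweep as both the full
    5-step mechanism and its pre-equilibrium reduction with
    k' = K*kIV, integrates both in batch, and compares [C](t) on a common
    grid relative to the maximum concentration.
    """
    K = models.FIGURE3_K_EQ
    worst = 0.0
    for kI, kIV in models.figure3_pairs():
        full = models.supercatalysis_full(kI, 1e6, 1e8, kIV, 1e7)
        red = models.supercatalysis_reduced(kI, K * kIV, 1e7)
        t_eval = np.linspace(0.0, t_end, 400)
        tf = integrate_batch(full, full.state({"A": 1.0, "B": 1.0}), t_end,
                             t_eval=t_eval, refine=False)
        tr = integrate_batch(red, red.state({"A": 1.0, "B": 1.0}), t_end,
                             t_eval=t_eval, refine=False)
        err = np.max(np.abs(tf["C"] - tr["C"])) / max(np.max(tf["C"]), 1e-300)
        worst = max(worst, float(err))
    return K, worst


@dataclass
class VerificationCheck:
    name: str
    value: float
    expected: str
    passed: bool


def verify(quick: bool = False) -> list[VerificationCheck]:
    """Recompute the headline flow-selection quantities and check them.

    With ``quick`` the sweep resolution is reduced (the located transition
    moves by far less than its factor-of-two acceptance band).
    """
    checks: list[VerificationCheck] = []

    r = option_a_low_flow_ratio()
    checks.append(VerificationCheck(
        "optionA coexistence ratio at k0=1e-5 s^-1", r,
        "0.5 +/- 0.01", abs(r - 0.5) <= 0.01,
    ))

    per_decade = 10 if quick else 25
    tr, _sweep = option_a_transition(per_decade=per_decade)
    tau = np.nan if tr is None else tr.tau
    checks.append(VerificationCheck(
        "optionA selection transition residence time tau*", float(tau),
        "100 s within factor 2", tr is not None and 50.0 <= tau <= 200.0,
    ))

    share = option_c_winner_share()
    checks.append(VerificationCheck(
        "optionC winner share of C at log10 k0 = -1.1", share,
        "> 80 %", share > 80.0,
    ))

    K, err = supercatalysis_reduction_error()
    checks.append(VerificationCheck(
        "supercatalysis pre-equilibrium constant K", K,
        "0.01 M^-1 exactly", K == 0.01,
    ))
    checks.append(VerificationCheck(
        "full vs reduced supercatalysis [C](t) sup-norm error", err,
        "< 1 %", err < 0.01,
    ))
    assert checks, "verification report must never be empty"
    return checks
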