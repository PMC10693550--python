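"""Experiment runner and command-line interface.

``run_experiment`` executes the slab workflow plus analysis for a set of
design-panel entries, votes over seeds, and compares each predicted phase
against the experimentally observed label.  The CLI is a thin wrapper:
``build``, ``slab run``, ``analyze``, ``panel``, ``calibrate``,
``params show``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from ccphase import io as ccio
from ccphase.analysis import (
    classify_phase,
    cluster_distribution,
    coil_engagement,
    density_profile,
    msd_diffusion,
)
from ccphase.constructs import PanelEntry, SystemSpec, design_panel, parse_construct
from ccphase.forcefield import ForceFieldParams, InteractionMatrix
from ccphase.slab import (
    DESK_PROTOCOL,
    FULL_PROTOCOL,
    MODEL_TEMPERATURE,
    SlabProtocolParams,
    calibrate_temperature_scale,
    default_calibration_targets,
    run_slab,
)
from ccphase.topology import build_system_topology

log = logging.getLogger("ccphase")

__all__ = ["RunConfig", "PanelReport", "run_experiment", "cli"]

#: Desk-scale copy numbers by component count (chains kept small enough for
#: interactive turnaround; reports always carry the scale flag).
DESK_COPIES = {1: 8, 2: 6, 3: 4}

#: Panel entries whose phase call the runner treats as the required core.
CORE_ENTRIES = (
    "mixed_3h_pair",
    "matched_3h_pair",
    "appapappap",
    "pppppp_aaaa",
    "blind_poisoned_triple",
    "blind_s_pair",
)


@dataclass
class RunConfig:
    """One panel campaign: which entries, seeds, scale, output directory."""

    entries: list | None = None  # panel keys; None = all
    seeds: tuple = (1, 2, 3)
    scale: str = "desk"
    protocol_overrides: dict = field(default_factory=dict)
    copies: dict | None = None  # n_components -> copies per component
    out_dir: str | None = None

    def protocol(self) -> SlabProtocolParams:
        base = DESK_PROTOCOL if self.scale == "desk" else FULL_PROTOCOL
        return base.with_(**self.protocol_overrides) if self.protocol_overrides else base

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a campaign config from YAML or JSON.

        Recognized keys mirror the dataclass fields; ``copies`` maps
        component counts (as strings or ints) to copy numbers.
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "copies" in data and data["copies"] is not None:
            data["copies"] = {int(k): int(v) for k, v in data["copies"].items()}
        if "seeds" in data:
            data["seeds"] = tuple(data["seeds"])
        return cls(**data)


@dataclass
class PanelReport:
    """Predicted vs expected phase per entry, with majority-vote evidence."""

    entries: list  # list of dicts
    n_agree: int
    n_total: int
    scale: str
    seeds: tuple

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def agreement(self, keys=None) -> float:
        rows = [e for e in self.entries if keys is None or e["key"] in keys]
        return sum(e["agree"] for e in rows) / len(rows)


def _system_for_entry(entry: PanelEntry, config: RunConfig, seed: int) -> SystemSpec:
    copies_map = config.copies or DESK_COPIES
    copies = copies_map[len(entry.constructs)]
    comps = [(parse_construct(s), copies) for s in entry.constructs]
    return SystemSpec(components=comps, temperature=config.protocol().temperature,
                      seed=seed)


def evaluate_entry(
    entry: PanelEntry,
    config: RunConfig,
    matrix: InteractionMatrix | None = None,
    ff: ForceFieldParams | None = None,
) -> dict:
    """Slab + analysis for one panel entry, majority vote over seeds."""
    protocol = config.protocol()
    votes, evidence = [], []
    for seed in config.seeds:
        system = _system_for_entry(entry, config, seed)
        try:
            result = run_slab(system, protocol, matrix, ff)
            traj = result.trajectories[0]
            dens = density_profile(traj)
            clus = cluster_distribution(traj, matrix=matrix)
            call = classify_phase(dens, clus)
            votes.append(call.label)
            evidence.append(
                {
                    "seed": seed,
                    "label": call.label,
                    "density_ratio": round(call.density_ratio, 3),
                    "largest_cluster_fraction": round(call.largest_cluster_fraction, 3),
                    "dimer_dominance_fraction": round(call.dimer_dominance_fraction, 3),
                }
            )
        except Exception as exc:
            log.error("entry %s seed %s failed: %s", entry.key, seed, exc)
            evidence.append({"seed": seed, "label": "failed", "error": str(exc)})
    ok = [v for v in votes]
    if not ok:
        return {
            "key": entry.key,
            "expected": entry.expected,
            "predicted": "failed",
            "agree": False,
            "evidence": evidence,
            "note": entry.note,
        }
    cond_votes = sum(v == "condensate" for v in ok)
    predicted_cond = cond_votes * 2 > len(ok)
    predicted = (
        "condensate"
        if predicted_cond
        else Counter(v for v in ok if v != "condensate").most_common(1)[0][0]
    )
    if entry.strict:
        agree = predicted == entry.expected
    else:
        agree = predicted_cond == entry.expected_condensate
    return {
        "key": entry.key,
        "expected": entry.expected,
        "predicted": predicted,
        "agree": bool(agree),
        "evidence": evidence,
        "note": entry.note,
    }


def run_experiment(
    config: RunConfig,
    matrix: InteractionMatrix | None = None,
    ff: ForceFieldParams | None = None,
) -> PanelReport:
    """Run the design panel (or a subset) and score against observed labels."""
    panel = design_panel()
    if config.entries is not None:
        keys = set(config.entries)
        panel = [e for e in panel if e.key in keys]
    if not panel:
        raise ValueError("empty panel selection")
    rows = [evaluate_entry(e, config, matrix, ff) for e in panel]
    report = PanelReport(
        entries=rows,
        n_agree=sum(r["agree"] for r in rows),
        n_total=len(rows),
        scale=config.scale,
        seeds=config.seeds,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "panel_report.json").write_text(report.to_json())
        pd.DataFrame(
            [{k: r[k] for k in ("key", "expected", "predicted", "agree")} for r in rows]
        ).to_csv(out / "panel_report.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging to stderr")
def cli(verbose):
    """Coarse-grained coiled-coil phase-separation simulations."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.argument("construct")
@click.option("--json", "as_json", is_flag=True, help="print topology JSON")
@click.option("--out", type=click.Path(), default=None)
def build(construct, as_json, out):
    """Parse a construct string and build its bead topology."""
    spec = parse_construct(construct)
    top = build_system_topology([(spec, 1)])
    if out:
        ccio.save_topology(out, top)
    if as_json:
        click.echo(top.to_json())
    else:
        click.echo(
            f"{spec.name}: {spec.coil_count} coils, arrangement {spec.arrangement}, "
            f"{top.n_beads} beads"
        )


@cli.group()
def params():
    """Force-field parameter utilities."""


@params.command("show")
def params_show():
    """Print the default force-field parameters."""
    p = ForceFieldParams()
    for f in dataclasses.fields(p):
        click.echo(f"{f.name} = {getattr(p, f.name)}")
    click.echo(f"cutoff_rep = {p.cutoff_rep}")
    m = InteractionMatrix.default(p)
    from ccphase.topology import COIL_TYPE_NAMES

    for a in COIL_TYPE_NAMES:
        for b in COIL_TYPE_NAMES:
            e = m.entry(a, b)
            if e != "none" and a <= b:
                click.echo(f"{a}-{b}: {e[1]}, epsilon={m.epsilon(a, b):.3f} kJ/mol")


@cli.group()
def slab():
    """Slab phase-coexistence runs."""


@slab.command("run")
@click.option("--construct", "constructs", multiple=True, required=True)
@click.option("--copies", type=int, default=None, help="copies per construct")
@click.option("--seed", type=int, default=1)
@click.option("--scale", type=click.Choice(["desk", "full"]), default="desk")
@click.option("--temperature", type=float, default=None, help="model K")
@click.option("--out", type=click.Path(), required=True)
def slab_run(constructs, copies, seed, scale, temperature, out):
    """Run the slab workflow for one system and write trajectory + reports."""
    protocol = DESK_PROTOCOL if scale == "desk" else FULL_PROTOCOL
    if temperature is not None:
        protocol = protocol.with_(temperature=temperature)
    if copies is None:
        copies = DESK_COPIES.get(len(constructs), 6)
    comps = [(parse_construct(c), copies) for c in constructs]
    system = SystemSpec(components=comps, temperature=protocol.temperature, seed=seed)
    result = run_slab(system, protocol)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    traj = result.trajectories[0]
    ccio.write_xyz(outdir / "production.xyz", traj)
    ccio.save_topology(outdir / "topology.json", traj.topology)
    (outdir / "stages.json").write_text(json.dumps(result.stage_log, indent=2))
    click.echo(f"wrote {outdir}/production.xyz ({traj.n_frames} frames)")


@cli.command()
@click.argument("trajectory", type=click.Path(exists=True))
@click.option("--topology", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), default="analysis")
@click.option("--seed", type=int, default=0)
def analyze(trajectory, topology, out, seed):
    """Density, cluster, phase, MSD and engagement reports for a trajectory."""
    top = ccio.load_topology(topology)
    traj = ccio.read_xyz(trajectory, top)
    dens = density_profile(traj)
    clus = cluster_distribution(traj)
    call = classify_phase(dens, clus)
    eng = coil_engagement(traj)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"z_nm": dens.bin_centers, "chains_per_nm3": dens.density}
    ).to_csv(outdir / "density_profile.csv", index=False)
    summary = {
        "phase": call.label,
        "density_ratio": call.density_ratio,
        "largest_cluster_fraction": call.largest_cluster_fraction,
        "dimer_dominance_fraction": call.dimer_dominance_fraction,
        "mean_engaged_fraction": eng.mean_engaged_fraction,
        "mean_unique_partners": eng.mean_unique_partners,
    }
    try:
        diff = msd_diffusion(traj, seed=seed)
        summary["D_cm2_s"] = diff.D_cm2_s
        summary["D_sd_cm2_s"] = diff.D_sd_cm2_s
        pd.DataFrame({"lag_ps": diff.lags_ps, "msd_nm2": diff.msd}).to_csv(
            outdir / "msd.csv", index=False
        )
    except ValueError:
        pass
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    click.echo(json.dumps(summary, indent=2))


@cli.command()
@click.option("--scale", type=click.Choice(["desk", "full"]), default="desk")
@click.option("--seed", type=int, default=1)
@click.option("--entries", default=None, help="comma-separated panel keys")
@click.option("--config", "config_file", type=click.Path(exists=True),
              default=None, help="YAML/JSON campaign config")
@click.option("--out", type=click.Path(), default="panel_out")
def panel(scale, seed, entries, config_file, out):
    """Run the design panel and compare with the observed phase labels."""
    if config_file:
        config = RunConfig.from_file(config_file)
        if config.out_dir is None:
            config.out_dir = out
    else:
        config = RunConfig(
            entries=entries.split(",") if entries else None,
            seeds=(seed, seed + 1, seed + 2),
            scale=scale,
            out_dir=out,
        )
    report = run_experiment(config)
    click.echo(report.to_json())
    core = [e for e in report.entries if e["key"] in CORE_ENTRIES]
    if any(not e["agree"] for e in core):
        sys.exit(1)


@cli.command()
@click.option("--pair", "pairs", multiple=True,
              help="coil pair like S1h:S2h; default all ITC pairs")
@click.option("--temp", "temps", multiple=True, type=float, required=True)
@click.option("--steps", type=int, default=1_000_000)
@click.option("--volume", type=float, default=512.0, help="box volume nm^3")
@click.option("--seed", type=int, default=1)
@click.option("--out", type=click.Path(), default=None)
def calibrate(pairs, temps, steps, volume, seed, out):
    """Fit the model temperature scale against measured dimer affinities."""
    targets = default_calibration_targets()
    if pairs:
        want = {tuple(p.split(":")) for p in pairs}
        targets = [t for t in targets if t.pair in want]
    report = calibrate_temperature_scale(
        targets, list(temps), box_volume_nm3=volume, n_steps=steps, seed=seed
    )
    payload = {
        "assignments": {"-".join(k): v for k, v in report.assignments.items()},
        "failures": ["-".join(p) for p in report.failures],
        "grid": report.grid,
    }
    text = json.dumps(payload, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


if __name__ == "__main__":
    cli()
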