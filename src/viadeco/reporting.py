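"""CLI entry points, configuration loading and artifact exporters.

Artifacts are deterministic: floats are formatted at 12 significant digits,
all randomness flows from the single seed in :class:`RunConfig`, and two
runs with identical configuration produce byte-identical files.  Every run
writes a ``manifest.json`` listing each artifact with the parameters that
produced it.
"""

from __future__ import annotations

import json
import math
import re
import sys
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import click
import networkx as nx
import numpy as np
import yaml

from . import fixtures as fx
from .decomposition import (
    Manifold,
    SeparationReport,
    find_tangency_points,
    mortality_manifold,
    verify_separation,
)
from .dynsys import Trajectory, VectorField, field_from_dict, find_equilibria
from .hybrid import (
    HybridTrajectory,
    configuration_graph,
    simulate_hybrid,
)
from .intrinsic import (
    CAConfiguration,
    enumerate_perturbations,
    viability_partition,
)
from .viability import LabelGrid, ViabilityRegion, box_region, classify_grid

__all__ = [
    "RunConfig",
    "run",
    "export_graph",
    "fmt",
    "trajectory_to_csv",
    "label_grid_to_csv",
    "manifold_to_csv",
    "separation_to_json",
    "load_system_file",
    "cli",
]

#: fixed significand width for all exported floating-point values
FLOAT_FMT = "%.12g"


def fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# Exporters
# ---------------------------------------------------------------------------


def trajectory_to_csv(traj: Trajectory, names: Sequence[str]) -> str:
    """CSV with columns ``t, x1..xn, termination`` (fixed column order)."""
    header = ",".join(["t", *names, "termination"])
    term = traj.termination.reason
    if traj.termination.constraint_ids:
        term += ":" + "|".join(traj.termination.constraint_ids)
    rows = [header]
    for t, x in zip(traj.times, traj.states):
        rows.append(",".join([fmt(t), *(fmt(v) for v in x), term]))
    return "\n".join(rows) + "\n"


def label_grid_to_csv(grid: LabelGrid, names: Sequence[str]) -> str:
    """CSV with columns ``x1..xn, status, violated, death_time``."""
    header = ",".join([*names, "status", "violated", "death_time"])
    rows = [header]
    for p, lab in zip(grid.points, grid.labels):
        rows.append(
            ",".join(
                [
                    *(fmt(v) for v in p),
                    lab.status,
                    "|".join(lab.violated),
                    fmt(lab.death_time) if lab.death_time is not None else "",
                ]
            )
        )
    return "\n".join(rows) + "\n"


def manifold_to_csv(manifold: Manifold, names: Sequence[str]) -> str:
    """CSV polyline with columns ``kind, seed, t, x1..xn``."""
    header = ",".join(["kind", "seed", "t", *names])
    seed_txt = "|".join(fmt(v) for v in manifold.seed)
    rows = [header]
    for t, x in zip(manifold.times, manifold.points):
        rows.append(
            ",".join([manifold.kind, seed_txt, fmt(t), *(fmt(v) for v in x)])
        )
    return "\n".join(rows) + "\n"


def separation_to_json(report: SeparationReport) -> str:
    payload = {
        "fraction": float(report.fraction),
        "n_evaluated": report.n_evaluated,
        "n_skipped": report.n_skipped,
        "counterexamples": [
            {
                "probe_plus": [float(v) for v in p],
                "probe_minus": [float(v) for v in m],
                "label_plus": lp,
                "label_minus": lm,
            }
            for p, m, lp, lm in report.counterexamples
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _subset_label(subset) -> str:
    return "{" + ",".join(sorted(subset)) + "}" if subset else "{}"


def export_graph(graph: nx.DiGraph, path: Optional[Path] = None) -> str:
    """Serialize a configuration graph as DOT.

    One node per alive subset (labelled ``{a,b,...}``); realized edges are
    drawn solid, unrealized ones dashed.  The emitted subset round-trips
    through a DOT parser (see the test suite's minimal reader).
    """
    lines = ["digraph configuration {"]
    for node in sorted(graph.nodes, key=lambda s: (len(s), sorted(s))):
        lines.append(f'  "{_subset_label(node)}";')
    for u, v, data in sorted(
        graph.edges(data=True),
        key=lambda e: (_subset_label(e[0]), _subset_label(e[1])),
    ):
        style = "solid" if data.get("realized") else "dashed"
        dying = _subset_label(data.get("dying", frozenset()))
        lines.append(
            f'  "{_subset_label(u)}" -> "{_subset_label(v)}" '
            f'[style={style}, label="{dying}"];'
        )
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def hybrid_events_to_jsonl(traj: HybridTrajectory) -> str:
    rows = []
    for e in traj.events:
        rows.append(
            json.dumps(
                {
                    "time": float(e.time),
                    "dying": sorted(e.dying),
                    "pre_alive": sorted(e.pre_alive),
                    "pre_state": [float(v) for v in e.pre_state],
                    "post_state": [float(v) for v in e.post_state],
                    "constraints": list(e.constraint_ids),
                },
                sort_keys=True,
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------


def load_system_file(path: Path) -> tuple[VectorField, ViabilityRegion]:
    """Load a field + region from a YAML system file.

    Schema::

        field: {type: linear|polynomial, ...}   # see field_from_dict
        bounds: [[lo, hi], ...]                 # per-variable, null = open
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "field" not in data or "bounds" not in data:
        raise click.UsageError(
            f"system file {path} must define 'field' and 'bounds'"
        )
    field = field_from_dict(data["field"])
    bounds = [
        (
            -math.inf if lo is None else float(lo),
            math.inf if hi is None else float(hi),
        )
        for lo, hi in data["bounds"]
    ]
    names = data["field"].get("names")
    return field, box_region(bounds, names=names)


def _resolve_single_cell(source: str) -> tuple[VectorField, ViabilityRegion, dict]:
    if source in fx.SINGLE_CELL_SCENARIOS:
        field, region, spec = fx.make_single_cell_fixture(source)
        return field, region, {"fixture": spec.name, "parameters": spec.parameters}
    p = Path(source)
    if p.exists():
        field, region = load_system_file(p)
        return field, region, {"system_file": str(p)}
    raise click.UsageError(
        f"unknown system {source!r}: not a fixture "
        f"{fx.SINGLE_CELL_SCENARIOS} and no such file"
    )


# ---------------------------------------------------------------------------
# RunConfig + run
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """One reproducible invocation of a top-level operation.

    ``system`` is a fixture name (``A``/``B``/``C``/``two_cell``/a GoL
    fixture) or a path to a YAML system file; all tolerances and the seed
    are echoed into the manifest of every run.
    """

    operation: str  # classify | decompose | hybrid | gol
    system: str
    out_dir: Path
    seed: int = 1234
    resolution: int = 20
    horizon: float = 50.0
    n_probes: int = 100
    band: float = 1e-2
    x0: Optional[tuple[float, ...]] = None
    window: tuple[int, int] = (3, 3)
    window_offset: tuple[int, int] = (4, 4)
    max_flips: int = 1
    ca_horizon: int = 64
    extra: dict = dc_field(default_factory=dict)


def _write(out_dir: Path, name: str, text: str, manifest: list, params: dict):
    path = out_dir / name
    path.write_text(text)
    manifest.append({"file": name, "parameters": params})


def run(config: RunConfig) -> dict:
    """Execute one operation and write its artifacts plus a manifest.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    common = {"seed": config.seed, "operation": config.operation, "system": config.system}

    if config.operation == "classify":
        field, region, src = _resolve_single_cell(config.system)
        eq = find_equilibria(
            field, region.bounding_box(), n_starts=32, seed=config.seed
        )
        grid = classify_grid(
            field,
            region,
            (config.resolution, config.resolution),
            horizon=config.horizon,
            attractors=eq,
        )
        names = field.variable_names()
        params = {**common, **src, "resolution": config.resolution, "horizon": config.horizon}
        _write(out, "labels.csv", label_grid_to_csv(grid, names), manifest, params)
        summary = {
            "counts": dict(sorted(grid.counts.items())),
            "total": grid.total,
            "fractions": {
                k: round(v / grid.total, 12) for k, v in sorted(grid.counts.items())
            },
        }
        _write(
            out,
            "summary.json",
            json.dumps(summary, indent=2, sort_keys=True) + "\n",
            manifest,
            params,
        )
    elif config.operation == "decompose":
        field, region, src = _resolve_single_cell(config.system)
        eq = find_equilibria(
            field, region.bounding_box(), n_starts=32, seed=config.seed
        )
        params = {
            **common,
            **src,
            "n_probes": config.n_probes,
            "band": config.band,
            "horizon": config.horizon,
        }
        tangencies = []
        for con in region.constraints:
            tangencies.extend(
                find_tangency_points(
                    field, region, con.id, attractors=eq, horizon=config.horizon
                )
            )
        tp_payload = [
            {
                "location": [float(v) for v in tp.location],
                "constraint": tp.constraint_id,
                "forward_fate": tp.forward_fate.status,
                "crossing_character": tp.crossing_character,
                "organizing": tp.organizing,
            }
            for tp in tangencies
        ]
        _write(
            out,
            "tangencies.json",
            json.dumps(tp_payload, indent=2, sort_keys=True) + "\n",
            manifest,
            params,
        )
        names = field.variable_names()
        from .viability import classify_state

        for k, tp in enumerate(t for t in tangencies if t.organizing):
            man = mortality_manifold(field, region, tp)
            _write(
                out, f"mortality_{k}.csv", manifold_to_csv(man, names), manifest, params
            )
            report = verify_separation(
                man,
                lambda x: classify_state(
                    field, region, x, horizon=config.horizon, attractors=eq
                ).status,
                n_probes=config.n_probes,
                band=config.band,
                seed=config.seed,
                region=region,
            )
            _write(
                out,
                f"separation_{k}.json",
                separation_to_json(report),
                manifest,
                params,
            )
    elif config.operation == "hybrid":
        if config.system != "two_cell":
            raise click.UsageError("hybrid runs use the 'two_cell' fixture")
        system, spec = fx.make_two_cell_fixture()
        graph = configuration_graph(system)
        x0 = config.x0 if config.x0 is not None else (0.8, 0.6)
        traj = simulate_hybrid(system, np.asarray(x0), config.horizon, graph=graph)
        params = {**common, "x0": list(x0), "horizon": config.horizon,
                  "parameters": spec.parameters}
        _write(out, "events.jsonl", hybrid_events_to_jsonl(traj), manifest, params)
        for k, (alive, seg) in enumerate(traj.segments):
            names = [f"x{i+1}" for i in range(seg.states.shape[1])]
            _write(
                out,
                f"segment_{k}_{'_'.join(sorted(alive))}.csv",
                trajectory_to_csv(seg, names),
                manifest,
                params,
            )
        _write(out, "configuration.dot", export_graph(graph), manifest, params)
    elif config.operation == "gol":
        base = fx.make_gol_fixture(config.system) if config.system in fx.GOL_FIXTURES else None
        if not isinstance(base, CAConfiguration):
            raise click.UsageError(
                "gol runs need a glider configuration fixture "
                "('glider' or 'glider_vs_block')"
            )
        h, w = config.window
        dr, dc = config.window_offset
        window = [(dr + r, dc + c) for r in range(h) for c in range(w)]
        configs = enumerate_perturbations(base, window, config.max_flips)
        summary = viability_partition(configs, horizon=config.ca_horizon)
        params = {
            **common,
            "window": [list(config.window), list(config.window_offset)],
            "max_flips": config.max_flips,
            "ca_horizon": config.ca_horizon,
        }
        rows = ["index,label,steps_to_disintegration,recovered,n_env_cells"]
        for i, rec in enumerate(summary.records):
            rows.append(
                ",".join(
                    [
                        str(i),
                        rec.label,
                        "" if rec.steps_to_disintegration is None
                        else str(rec.steps_to_disintegration),
                        str(rec.recovered).lower(),
                        str(len(rec.config.environment)),
                    ]
                )
            )
        _write(out, "partition.csv", "\n".join(rows) + "\n", manifest, params)
        _write(
            out,
            "partition_summary.json",
            json.dumps(
                {"counts": summary.counts, "total": summary.total,
                 "horizon": summary.horizon, "mode": summary.mode},
                indent=2,
                sort_keys=True,
            )
            + "\n",
            manifest,
            params,
        )
    else:
        raise click.UsageError(f"unknown operation {config.operation!r}")

    manifest_doc = {"config": _config_dict(config), "artifacts": manifest}
    (out / "manifest.json").write_text(
        json.dumps(manifest_doc, indent=2, sort_keys=True) + "\n"
    )
    return manifest_doc


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["out_dir"] = str(d["out_dir"])
    if d.get("x0") is not None:
        d["x0"] = list(d["x0"])
    d["window"] = list(d["window"])
    d["window_offset"] = list(d["window_offset"])
    return d


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def cli():
    """Viability-space decomposition toolkit."""


def _common_options(f):
    f = click.option("--out", "out_dir", type=click.Path(), required=True)(f)
    f = click.option("--seed", type=int, default=1234, show_default=True)(f)
    return f


@cli.command()
@click.option("--system", required=True, help="fixture A/B/C or a YAML system file")
@click.option("--resolution", type=int, default=20, show_default=True)
@click.option("--horizon", type=float, default=50.0, show_default=True)
@_common_options
def classify(system, resolution, horizon, out_dir, seed):
    """Classify a grid of states as asymptotically/transiently viable."""
    run(
        RunConfig(
            "classify", system, Path(out_dir), seed=seed,
            resolution=resolution, horizon=horizon,
        )
    )


@cli.command()
@click.option("--system", required=True)
@click.option("--n-probes", type=int, default=100, show_default=True)
@click.option("--band", type=float, default=1e-2, show_default=True)
@click.option("--horizon", type=float, default=50.0, show_default=True)
@_common_options
def decompose(system, n_probes, band, horizon, out_dir, seed):
    """Find tangency points and mortality manifolds; verify separation."""
    run(
        RunConfig(
            "decompose", system, Path(out_dir), seed=seed,
            n_probes=n_probes, band=band, horizon=horizon,
        )
    )


@cli.command()
@click.option("--system", default="two_cell", show_default=True)
@click.option("--x0", type=str, default="0.8,0.6", show_default=True,
              help="comma-separated full-system initial state")
@click.option("--horizon", type=float, default=50.0, show_default=True)
@_common_options
def hybrid(system, x0, horizon, out_dir, seed):
    """Simulate the multicellular hybrid system and export its graph."""
    x0_t = tuple(float(v) for v in x0.split(","))
    run(
        RunConfig(
            "hybrid", system, Path(out_dir), seed=seed, x0=x0_t, horizon=horizon,
        )
    )


@cli.command()
@click.option("--pattern", "system", default="glider", show_default=True)
@click.option("--window", type=str, default="3x3@4,4", show_default=True,
              help="HxW@dr,dc perturbation window (offset from glider corner)")
@click.option("--flips", type=int, default=1, show_default=True)
@click.option("--horizon", type=int, default=64, show_default=True)
@_common_options
def gol(system, window, flips, horizon, out_dir, seed):
    """Partition glider-environment configurations by intrinsic viability."""
    m = re.match(r"^(\d+)x(\d+)@(-?\d+),(-?\d+)$", window)
    if not m:
        raise click.UsageError("--window must look like 3x3@4,4")
    h, w, dr, dc = (int(g) for g in m.groups())
    run(
        RunConfig(
            "gol", system, Path(out_dir), seed=seed,
            window=(h, w), window_offset=(dr, dc),
            max_flips=flips, ca_horizon=horizon,
        )
    )


def main(argv: Optional[Sequence[str]] = None) -> int:
    try:
        cli.main(args=argv, standalone_mode=False)
    except click.UsageError as exc:
        print(f"error: {exc.format_message()}", file=sys.stderr)
        return 2
    except click.exceptions.Exit as exc:  # --help
        return exc.exit_code
    return 0
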