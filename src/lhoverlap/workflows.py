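"""Config-driven workflows: anatomy, quadrant, flybowl, flight, simulate.

Each workflow reads a YAML config, validates every referenced input before
any computation, runs deterministically for a given (config, inputs, seed),
and writes its outputs plus a provenance record (config hash, input hashes,
package version) and a manifest listing every file written.  Warnings that
affect interpretation (dropped flies, empty rows) are machine-readable in
the manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .flight import fly_response, per_timepoint_test, traces_from_csv
from .maskpipe import MaskPipelineParams, make_mask
from .overlap import classify_interactions, cluster_matrix, pairwise_matrix
from .quadrant import (
    ArenaGeometry,
    TrialTrack,
    delta_metric,
    flybowl_locomotion,
    pi_timeseries,
    schedule_from_yaml,
    single_value_pi,
)
from .synthetic import (
    ArborParams,
    ArenaDesign,
    FlightDesign,
    OverlapStackDesign,
    generate_flight_session,
    generate_flybowl_trial,
    generate_overlap_stacks,
    generate_quadrant_trial,
    generate_replicate_stacks,
)
from .volumes import read_volume, write_volume

WORKFLOWS = ("anatomy", "quadrant", "flybowl", "flight", "simulate")

EXIT_OK = 0
EXIT_VALIDATION = 1
EXIT_COMPUTATION = 2


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (reported before computing)."""


@dataclass
class RunResult:
    exit_code: int
    manifest: dict
    out_dir: Path


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "workflow" not in doc:
        raise ConfigError("config must be a mapping with a 'workflow' key")
    if doc["workflow"] not in WORKFLOWS:
        raise ConfigError(f"unknown workflow {doc['workflow']!r}; choose from {WORKFLOWS}")
    return doc


def run_workflow(config: dict, out_dir, seed: int | None = None) -> RunResult:
    """Dispatch a validated config to its workflow and write the manifest."""
    out_dir = Path(out_dir)
    workflow = config.get("workflow")
    if workflow not in WORKFLOWS:
        raise ConfigError(f"unknown workflow {workflow!r}")
    if seed is not None:
        config = dict(config, seed=int(seed))
    # validate referenced files before any computation
    input_paths = [Path(p) for p in _referenced_paths(config)]
    missing = [str(p) for p in input_paths if not p.exists()]
    if missing:
        raise ConfigError(f"missing input files: {missing}")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    warnings_log: list[str] = []
    runner = {
        "anatomy": _run_anatomy,
        "quadrant": _run_quadrant,
        "flybowl": _run_flybowl,
        "flight": _run_flight,
        "simulate": _run_simulate,
    }[workflow]
    runner(config, out_dir, written, warnings_log)
    manifest = {
        "workflow": workflow,
        "package_version": __version__,
        "config_hash": _hash_config(config),
        "input_hashes": {str(p): _hash_file(p) for p in input_paths},
        "seed": config.get("seed"),
        "files": sorted(written),
        "warnings": warnings_log,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(exit_code=EXIT_OK, manifest=manifest, out_dir=out_dir)


def _referenced_paths(config: dict):
    for key in ("masks", "replicates", "tracks", "traces"):
        for p in config.get(key, []) or []:
            yield p
    for key in ("schedule", "track", "region"):
        if config.get(key):
            yield config[key]


def _write(df, path: Path, written: list[str]):
    df.to_csv(path, index=False)
    written.append(path.name)


def _run_anatomy(config: dict, out_dir: Path, written: list[str], warn: list[str]):
    """Masks (from files or simulated stacks) -> overlap matrix -> threshold
    classification -> clustering."""
    combine = config.get("combine", "mean")
    threshold = float(config.get("threshold", 15.0))
    masks = []
    if config.get("masks"):
        for p in config["masks"]:
            m = read_volume(p)
            masks.append(m)
    else:
        sim = config.get("simulate", {})
        n_types = int(sim.get("n_types", 4))
        seed = int(config.get("seed", 0))
        params = MaskPipelineParams()
        for i in range(n_types):
            stacks = generate_replicate_stacks(
                ArborParams(seed=seed + i), n_replicates=params.n_replicates
            )
            masks.append(
                make_mask(
                    stacks.volumes,
                    params,
                    metadata={"cell_type": f"type{i}", "compartment": "whole"},
                )
            )
    matrix = pairwise_matrix(masks, masks, combine=combine)
    matrix.to_csv(out_dir / "overlap_matrix.csv")
    written.append("overlap_matrix.csv")
    summary = classify_interactions(matrix, threshold=threshold)
    summary.significant.to_csv(out_dir / "significant.csv")
    written.append("significant.csv")
    (out_dir / "interaction_summary.json").write_text(
        json.dumps(
            {
                "threshold": summary.threshold,
                "frac_rows_with_any": summary.frac_rows_with_any,
                "frac_rows_with_none": summary.frac_rows_with_none,
            },
            indent=2,
        )
    )
    written.append("interaction_summary.json")
    if matrix.values.shape[0] >= 2:
        order = cluster_matrix(matrix)
        order.ordered_values(matrix).to_csv(out_dir / "overlap_matrix_clustered.csv")
        written.append("overlap_matrix_clustered.csv")


def _load_track(config: dict) -> TrialTrack:
    schedule = schedule_from_yaml(config["schedule"])
    arena = ArenaGeometry(diameter_mm=float(config.get("diameter_mm", 100.0)))
    return TrialTrack.from_csv(
        config["track"],
        arena=arena,
        schedule=schedule,
        frame_rate=float(config.get("frame_rate", 30.0)),
    )


def _run_quadrant(config: dict, out_dir: Path, written: list[str], warn: list[str]):
    track = _load_track(config)
    series = pi_timeseries(track)
    _write(series, out_dir / "pi_series.csv", written)
    sv = single_value_pi(series, track.schedule)
    (out_dir / "single_value_pi.json").write_text(json.dumps({"single_value_pi": sv}))
    written.append("single_value_pi.json")
    for metric in ("forward_locomotion", "turning", "distance_from_center"):
        dm = delta_metric(track, metric)
        _write(dm, out_dir / f"delta_{metric}.csv", written)
        n_dropped = int((~dm["included"]).sum())
        if n_dropped:
            warn.append(f"delta_{metric}: {n_dropped} flies excluded")


def _run_flybowl(config: dict, out_dir: Path, written: list[str], warn: list[str]):
    track = _load_track(config)
    loco = flybowl_locomotion(track)
    _write(loco.reset_index(), out_dir / "flybowl_locomotion.csv", written)


def _run_flight(config: dict, out_dir: Path, written: list[str], warn: list[str]):
    parameter = config.get("parameter", "yaw")
    condition = config.get("visual_condition", "closed_loop_stripe")
    traces = []
    for p in config["traces"]:
        traces.extend(traces_from_csv(p))
    exp = [t for t in traces if t.has_effector]
    ctl = [t for t in traces if not t.has_effector]
    resp_exp = fly_response(exp, parameter, condition)
    resp_exp.to_frame().to_csv(out_dir / "response_experimental.csv", index=False)
    written.append("response_experimental.csv")
    if ctl:
        resp_ctl = fly_response(ctl, parameter, condition)
        resp_ctl.to_frame().to_csv(out_dir / "response_control.csv", index=False)
        written.append("response_control.csv")
        sig = per_timepoint_test(resp_exp, resp_ctl, decimate=int(config.get("decimate", 1)))
        _write(sig, out_dir / "significance.csv", written)
    else:
        warn.append("no control traces: per-timepoint test skipped")


def _run_simulate(config: dict, out_dir: Path, written: list[str], warn: list[str]):
    what = config.get("what", "volumes")
    seed = int(config.get("seed", 0))
    if what == "volumes":
        stacks = generate_replicate_stacks(
            ArborParams(seed=seed), n_replicates=int(config.get("n_replicates", 3))
        )
        for i, v in enumerate(stacks.volumes):
            name = f"replicate_{i}.nrrd"
            write_volume(out_dir / name, v)
            written.append(name)
        write_volume(out_dir / "truth.nrrd", stacks.truth)
        written.extend(["truth.nrrd", "truth.nrrd.json"])
    elif what == "masks":
        design = OverlapStackDesign(
            target_p1=float(config.get("target_p1", 0.5)), seed=seed
        )
        _, _, truth_a, truth_b, true_p1 = generate_overlap_stacks(design)
        write_volume(out_dir / "mask_a.nrrd", truth_a)
        write_volume(out_dir / "mask_b.nrrd", truth_b)
        written.extend(["mask_a.nrrd", "mask_a.nrrd.json", "mask_b.nrrd", "mask_b.nrrd.json"])
        (out_dir / "ground_truth.json").write_text(json.dumps({"true_p1": true_p1}))
        written.append("ground_truth.json")
    elif what in ("quadrant", "flybowl"):
        design = ArenaDesign(
            arena_kind="four_quadrant" if what == "quadrant" else "flybowl",
            n_flies=int(config.get("n_flies", 20)),
            seed=seed,
        )
        track = (
            generate_quadrant_trial(design)
            if what == "quadrant"
            else generate_flybowl_trial(design)
        )
        track.to_csv(out_dir / "track.csv")
        written.append("track.csv")
        from .quadrant import schedule_to_yaml

        schedule_to_yaml(track.schedule, out_dir / "schedule.yaml")
        written.append("schedule.yaml")
    elif what == "flight":
        from .flight import traces_to_csv

        design = FlightDesign(
            n_flies=int(config.get("n_flies", 6)),
            effect_sizes=config.get("effect_sizes", {}),
            seed=seed,
        )
        traces = generate_flight_session(design)
        traces_to_csv(traces, out_dir / "flight_traces.csv")
        written.append("flight_traces.csv")
    else:
        raise ConfigError(f"unknown simulate target {what!r}")
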