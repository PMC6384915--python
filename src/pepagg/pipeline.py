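"""End-to-end pipeline: trajectory in, report bundle out.

Stages: clustering -> secondary structure -> interactions -> the two
Markov state models -> table/series writers.  Every number written to a
CSV is computed by the corresponding library function; the writers only
round for display (full precision goes to the JSON manifest).  Outputs
are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, interactions, io, msm, secondary_structure as ss
from .config import RunConfig, validate_config
from .core import Trajectory
from .synthetic import AggregationParams, gen_aggregation_trajectory
from .residues import mutant_sequence

log = logging.getLogger("pepagg")


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}")


def _stage(name, fn, *args, **kwargs):
    log.info("stage %s ...", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(name, exc) from exc


def load_input(config: RunConfig) -> Trajectory:
    """Trajectory from files or from the synthetic generator."""
    if config.generator is not None:
        g = config.generator
        params = AggregationParams(
            n_peptides=g.n_peptides,
            box_edge=g.box_edge,
            grid_spacing=g.grid_spacing,
            sequence=g.sequence or mutant_sequence(g.label),
            label=g.label,
            step_size=g.step_size,
            rotation_deg=g.rotation_deg,
            drift=g.drift,
            stick_probability=g.stick_probability,
            unstick_probability=g.unstick_probability,
            n_frames=g.n_frames,
            stride_ps=g.stride_ps,
            helix_fraction=g.helix_fraction,
            seed=config.seed,
            radii_table=config.radii_table,
        )
        return gen_aggregation_trajectory(params)
    topo = io.load_topology(config.topology_path, radii_table=config.radii_table)
    return io.load_trajectory(
        topo,
        config.trajectory_paths,
        dialect=config.trajectory_dialect,
        stride_ps=config.stride_ps,
        box_edge=config.box_edge,
    )


def run_pipeline(config: RunConfig | dict | str) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict with the in-memory results and the output paths.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    traj = _stage("input", load_input, config)
    t_end = float(traj.times[-1])
    w0 = config.window_start_ps
    w1 = config.window_end_ps
    if w0 is None:
        w0 = 0.7 * t_end  # default window: last 30% of the run
    if w1 is None:
        w1 = t_end

    clusters = _stage("clustering", clustering.mcs_time_series, traj)
    ssm = _stage("secondary_structure", ss.assign_ss, traj)
    hbonds = _stage(
        "hbonds",
        interactions.hbond_summary,
        traj, w0, w1,
        da_cutoff=config.hbond_da_cutoff,
        ha_cutoff=config.hbond_ha_cutoff,
        min_angle=config.hbond_min_angle,
    )
    contacts = _stage(
        "contacts",
        interactions.contact_summary,
        traj, w0, w1, cutoff=config.sidechain_cutoff,
    )
    stacking = _stage(
        "stacking",
        interactions.phe_stacking_series,
        traj, cutoff=config.stacking_cutoff,
    )

    n_steps = config.msm_n_steps or max(len(traj) - 1, 1)

    def _cluster_msm():
        series = msm.assign_cluster_states(clusters)
        result = msm.MarkovStateModel(series, lag=config.msm_lag).fit()
        return result, result.propagate(n_steps=n_steps)

    def _residue_msm():
        series = msm.assign_residue_states(
            ssm, clusters, traj.topology.residue_peptide
        )
        result = msm.MarkovStateModel(series, lag=config.msm_lag).fit()
        return result, result.propagate(n_steps=n_steps)

    nmer_msm, nmer_prop = _stage("msm_nmer", _cluster_msm)
    res_msm, res_prop = _stage("msm_residue", _residue_msm)

    beta_series, helix_series = ss.ss_fraction_series(ssm)
    report = {
        "trajectory": traj,
        "clusters": clusters,
        "ss": ssm,
        "hbonds": hbonds,
        "contacts": contacts,
        "stacking": stacking,
        "nmer_msm": nmer_msm,
        "nmer_propagation": nmer_prop,
        "residue_msm": res_msm,
        "residue_propagation": res_prop,
        "window": (w0, w1),
        "summary": {
            "label": traj.topology.label,
            "n_peptides": traj.topology.n_peptides,
            "n_frames": len(traj),
            "final_mcs": float(clusters.mcs[-1]),
            "window_mean_mcs": clustering.window_average_mcs(clusters, w0, w1),
            "beta_percent_window": ss.ss_fractions(ssm, w0, w1)[0],
            "helix_percent_window": ss.ss_fractions(ssm, w0, w1)[1],
            "max_oligomeric_helix_percent": msm.max_state_fraction(
                res_prop, ["oligomeric helix"]
            ),
            "max_oligomeric_strand_percent": msm.max_state_fraction(
                res_prop, ["oligomeric strand"]
            ),
            "hbonds_per_residue": hbonds,
            "contact_total_per_residue": contacts.total_per_residue,
            "contact_highest_pair": contacts.highest_pair[0],
            "contact_highest_percent": contacts.highest_pair[1],
            "mean_stacked_phe_pairs": float(np.mean(stacking)),
        },
    }
    report["paths"] = _stage(
        "write_outputs", write_outputs, outdir, config, report
    )
    return report


# --------------------------------------------------------------------------
# writers (display rounding happens here only)
# --------------------------------------------------------------------------

def write_outputs(outdir: Path, config: RunConfig, report: dict) -> dict:
    paths = {}

    def save(name, df, float_format="%.10g"):
        path = outdir / name
        df.to_csv(path, index=False, float_format=float_format)
        paths[name] = str(path)

    clusters = report["clusters"]
    save(
        "mcs_series.csv",
        pd.DataFrame({"time_ps": clusters.times, "mcs": clusters.mcs}),
    )

    beta, helix = ss.ss_fraction_series(report["ss"])
    save(
        "ss_series.csv",
        pd.DataFrame(
            {
                "time_ps": report["ss"].times,
                "beta_percent": beta,
                "helix_percent": helix,
            }
        ),
    )

    nmer_prop = report["nmer_propagation"]
    curves = msm.nmer_fraction_series(
        nmer_prop, threshold=config.nmer_display_threshold
    )
    nmer_df = pd.DataFrame({"step": np.arange(nmer_prop.pi.shape[0])})
    for state, curve in curves.items():
        nmer_df[f"{state}mer_fraction"] = curve
    save("nmer_fractions.csv", nmer_df)

    summary = report["summary"]
    save(
        "msm_table.csv",
        pd.DataFrame(
            {
                "quantity": [
                    "oligomeric_helix_max_percent",
                    "oligomeric_strand_max_percent",
                ],
                "value": [
                    summary["max_oligomeric_helix_percent"],
                    summary["max_oligomeric_strand_percent"],
                ],
            }
        ),
        float_format="%.0f",  # table printed as whole percents
    )

    hb = report["hbonds"]
    save(
        "hbond_table.csv",
        pd.DataFrame(
            {
                "class": ["Total", "MM", "MS", "SS"],
                "per_residue": [hb["Total"], hb["MM"], hb["MS"], hb["SS"]],
            }
        ),
        float_format="%.2f",
    )

    contacts = report["contacts"]
    pair_rows = [
        {"pair": "-".join(k), "mean_count_per_frame": v}
        for k, v in contacts.pair_counts.items()
    ]
    save(
        "contact_pairs.csv",
        pd.DataFrame(pair_rows, columns=["pair", "mean_count_per_frame"]),
    )
    hc_pair = contacts.highest_pair[0]
    save(
        "contact_table.csv",
        pd.DataFrame(
            {
                "total_per_residue": [round(contacts.total_per_residue, 2)],
                "hc_percent": [round(contacts.highest_pair[1], 1)],
                "hc_pair": ["-".join(hc_pair) if hc_pair else ""],
            }
        ),
    )

    save(
        "stacking_series.csv",
        pd.DataFrame(
            {
                "time_ps": report["trajectory"].times,
                "stacked_phe_pairs": report["stacking"],
            }
        ),
    )

    manifest = {
        "package": "pepagg",
        "version": _pkg_version("pepagg"),
        "config": json.loads(config.model_dump_json()),
        "window_ps": list(report["window"]),
        "summary": _jsonable(summary),
        "outputs": sorted(paths),
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = str(mpath)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
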