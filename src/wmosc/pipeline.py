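"""Pipeline orchestration: simulate -> behavior -> tfr -> clusterstat ->
correlate, with a run manifest (config snapshot, per-stage outputs with
content checksums, exclusion counts, timings) and a human-readable
markdown report. Stages can be re-run individually against a prior run
directory; all randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import summarize_behavior
from .cluster import extract_mask_power, permutation_cluster_test
from .config import PipelineConfig
from .containers import TrialOutcomes
from .errors import DependencyError, StageError
from .io import (
    read_epochs,
    read_layout,
    read_table,
    read_tfr,
    write_epochs,
    write_layout,
    write_table,
    write_tfr,
)
from .layout import make_layout
from .simulate import generate_behavior, generate_eeg, generate_structure, subject_ids, subject_relchange
from .spectral import average_power, baseline_correct, morlet_transform
from .stats import run_association_battery

__all__ = [
    "run_pipeline",
    "write_report",
    "stage_simulate",
    "stage_behavior",
    "stage_tfr",
    "stage_clusterstat",
    "stage_correlate",
]

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires missing input {path}")
    return path


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NaN"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    """Generate layout, EEG epochs, the trial table and the subject table."""
    sim = cfg.simulation
    layout = make_layout(sim.n_channels, cfg.analysis.neighbor_radius)
    write_layout(out / "layout.json", layout)
    outcomes = generate_behavior(sim)
    write_table(out / "trials.tsv", outcomes.trials)
    for ep in generate_eeg(sim, layout):
        write_epochs(out / "epochs", ep)
    # structural scalars condition on realized d' and the latent power change
    from .behavior import compute_dprime

    dp = compute_dprime(outcomes).pivot(index="subject_id", columns="load", values="dprime")
    rel = subject_relchange(sim).set_index("subject_id")
    cond = pd.DataFrame(
        {
            "subject_id": subject_ids(sim),
        }
    )
    for load in ("medium", "high"):
        cond[f"dprime_{load}"] = dp.loc[cond["subject_id"], load].to_numpy()
        cond[f"power_{load}"] = rel.loc[cond["subject_id"], f"relchange_{load}"].to_numpy()
    merged = generate_structure(sim, cond)
    subjects = merged.drop(columns=[c for c in merged.columns if c.startswith(("dprime_", "power_"))])
    write_table(out / "subjects.tsv", subjects)
    return {"n_subjects": sim.n_subjects, "n_trials": len(outcomes.trials)}


def stage_behavior(cfg: PipelineConfig, out: Path) -> dict:
    """Score d' and median RT; run the load ANOVAs and planned contrasts."""
    trials = read_table(_require(out / "trials.tsv", "behavior"))
    outcomes = TrialOutcomes.from_trials(trials)
    summary = summarize_behavior(outcomes, loads=cfg.simulation.loads)
    write_table(out / "behavior_summary.tsv", summary["scores"])
    stats_doc = {}
    counts = {}
    for measure in ("dprime", "median_rt"):
        s = summary[measure]
        stats_doc[measure] = {
            "anova": s.anova,
            "contrasts": [
                {**c, "pair": list(c["pair"])} for c in s.contrasts
            ],
            "corrected_alpha": s.corrected_alpha,
            "n_excluded_3sd": int((~s.outlier_include).sum()),
        }
        counts[f"{measure}_excluded_3sd"] = int((~s.outlier_include).sum())
    with open(out / "behavior_stats.json", "w") as fh:
        json.dump(stats_doc, fh, indent=1)
    return counts


def stage_tfr(cfg: PipelineConfig, out: Path) -> dict:
    """Morlet decomposition, trial averaging, relative baseline correction."""
    ana = cfg.analysis
    sim = cfg.simulation
    n_maps = 0
    for sid in subject_ids(sim):
        _require(out / "epochs" / f"{sid}_eeg.json", "tfr")
        ep = read_epochs(out / "epochs", sid)
        tp = morlet_transform(ep, freqs=ana.freqs, n_cycles=ana.n_cycles, time_step=ana.time_step)
        for cond, tfr in average_power(tp).items():
            corrected = baseline_correct(tfr, ana.baseline_window)
            write_tfr(out / "tfr", corrected)
            n_maps += 1
    return {"n_tfr_maps": n_maps}


def stage_clusterstat(cfg: PipelineConfig, out: Path) -> dict:
    """Cluster permutation test on the configured contrast; extract
    per-subject mean power within the group significance mask."""
    ana = cfg.analysis
    sim = cfg.simulation
    layout = read_layout(_require(out / "layout.json", "clusterstat"))
    cond_a, cond_b = ana.contrast
    maps = {
        load: [read_tfr(out / "tfr", sid, load) for sid in subject_ids(sim)]
        for load in sim.loads
    }
    report = permutation_cluster_test(
        maps[cond_a],
        maps[cond_b],
        layout,
        analysis_window=ana.analysis_window,
        n_permutations=ana.n_permutations,
        seed=cfg.seed,
        alpha=ana.alpha,
        cluster_alpha=ana.cluster_alpha,
        min_neighbor_channels=ana.min_neighbor_channels,
    )
    doc = {
        "contrast": list(ana.contrast),
        "analysis_window_s": list(ana.analysis_window),
        "n_permutations": report.n_permutations,
        "method": report.method,
        "seed": cfg.seed,
        "corrected_alpha": report.corrected_alpha,
        "cluster_alpha": ana.cluster_alpha,
        "min_neighbor_channels": ana.min_neighbor_channels,
        "clusters": report.summary_table().to_dict(orient="records"),
    }
    with open(out / "clusters.json", "w") as fh:
        json.dump(doc, fh, indent=1)
    mask = report.significance_mask
    mask.astype("<f4").tofile(out / "mask.bin")
    with open(out / "mask.json", "w") as fh:
        json.dump(
            {
                "shape": list(mask.shape),
                "order": "[channel][frequency][time]",
                "freqs_hz": report.t_map.freqs.tolist(),
                "times_s": report.t_map.times.tolist(),
                "channel_names": list(layout.channel_names),
                "n_masked": int(mask.sum()),
            },
            fh,
            indent=1,
        )
    if mask.any():
        flat = [m for load in sim.loads for m in maps[load]]
        mp = extract_mask_power(flat, report)
        mp = mp.rename(columns={"condition": "load"})
    else:
        log.warning("no significant clusters; mask power table is empty")
        mp = pd.DataFrame(columns=["subject_id", "load", "mean_power"])
    write_table(out / "mask_power.tsv", mp)
    return {
        "n_clusters": len(report.clusters),
        "n_significant_clusters": len(report.significant_clusters()),
        "mask_samples": int(mask.sum()),
    }


def stage_correlate(cfg: PipelineConfig, out: Path) -> dict:
    """Structure-function association battery on the merged subject table."""
    subjects = read_table(_require(out / "subjects.tsv", "correlate"))
    behavior = read_table(_require(out / "behavior_summary.tsv", "correlate"))
    dp = behavior.pivot(index="subject_id", columns="load", values="dprime")
    measures = subjects.copy()
    for load in cfg.simulation.loads:
        if load == "low" and cfg.exclude_low_load:
            continue
        measures[f"dprime_{load}"] = dp.loc[measures["subject_id"], load].to_numpy()
    mask_power = read_table(_require(out / "mask_power.tsv", "correlate"))
    if len(mask_power):
        mp = mask_power.pivot(index="subject_id", columns="load", values="mean_power")
        for load in mp.columns:
            measures[f"power_{load}"] = mp.loc[measures["subject_id"], load].to_numpy()
    plan, skipped = [], 0
    for entry in cfg.association_plan:
        cols = [entry["x"], entry["y"], *entry.get("covariates", [])]
        missing = [c for c in cols if c not in measures.columns]
        if missing and all(c.startswith("power_") for c in missing):
            log.warning("skipping %s ~ %s: no mask power available", entry["x"], entry["y"])
            skipped += 1
            continue
        plan.append(entry)
    results = run_association_battery(measures, plan)
    df = pd.DataFrame([r.to_dict() for r in results])
    if len(df):
        df["covariate_names"] = df["covariate_names"].map(lambda c: ",".join(c))
    write_table(out / "associations.tsv", df)
    with open(out / "associations.json", "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)
    return {
        "n_tests": len(results),
        "n_skipped_no_power": skipped,
        "n_excluded_3sd_total": int(sum(r.n_excluded for r in results)),
    }


STAGES = [
    ("simulate", stage_simulate),
    ("behavior", stage_behavior),
    ("tfr", stage_tfr),
    ("clusterstat", stage_clusterstat),
    ("correlate", stage_correlate),
]


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run all stages in dependency order and write manifest + report.

    Returns the manifest dict. Any stage failure raises
    :class:`StageError` naming the stage; the manifest is written last.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {},
    }
    tracked = set()
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            counts = fn(cfg, out)
        except DependencyError:
            raise
        except Exception as e:
            raise StageError(f"stage {name!r} failed: {e}") from e
        elapsed = time.perf_counter() - t0
        outputs = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.suffix in (".tsv", ".json", ".bin") and p.name not in (
                "manifest.json",
            ):
                rel = str(p.relative_to(out))
                if rel not in tracked:
                    outputs[rel] = _sha256(p)
                    tracked.add(rel)
        manifest["stages"][name] = {
            "wall_clock_s": round(elapsed, 3),
            "counts": counts,
            "outputs": outputs,
        }
        log.info("stage %s done in %.2f s: %s", name, elapsed, counts)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    write_report(out)
    return manifest


# ---------------------------------------------------------------------------
# report


def write_report(out_dir) -> Path:
    """Render report.md from the stage outputs of a completed run.

    The report is regenerated deterministically from the same outputs
    (no timestamps). A missing stage output leaves an explicit gap and
    raises :class:`StageError` after writing the partial report.
    """
    out = Path(out_dir)
    lines = ["# Working-memory pipeline report", ""]
    gaps = []

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        lines += [f"Package version {manifest['version']}, seed {manifest['seed']}.", ""]

    lines += ["## Behavior", ""]
    try:
        scores = read_table(out / "behavior_summary.tsv")
        with open(out / "behavior_stats.json") as fh:
            bstats = json.load(fh)
        by_load = scores.groupby("load", sort=False)[["dprime", "median_rt"]].mean()
        lines.append("| load | mean d' | mean median RT (ms) |")
        lines.append("|---|---|---|")
        for load, row in by_load.iterrows():
            lines.append(f"| {load} | {row['dprime']:.3f} | {row['median_rt']:.1f} |")
        lines.append("")
        for measure, label in (("dprime", "d'"), ("median_rt", "median RT")):
            a = bstats[measure]["anova"]
            lines.append(
                f"- {label}: F({a['df1']}, {a['df2']}) = {a['F']:.2f}, p = {_fmt_p(a['p'])}"
            )
            for c in bstats[measure]["contrasts"]:
                flag = "significant" if c["significant_at_corrected_alpha"] else "n.s."
                lines.append(
                    f"  - {c['pair'][0]} vs {c['pair'][1]}: t({c['df']}) = {c['t']:.2f}, "
                    f"p = {_fmt_p(c['p'])} ({flag} at "
                    f"{bstats[measure]['corrected_alpha']:.3f})"
                )
        lines.append("")
    except FileNotFoundError as e:
        gaps.append(str(e))
        lines += ["*behavior outputs missing*", ""]

    lines += ["## Oscillatory power: cluster permutation test", ""]
    try:
        with open(out / "clusters.json") as fh:
            cdoc = json.load(fh)
        lines.append(
            f"Contrast {cdoc['contrast'][0]} vs {cdoc['contrast'][1]}, "
            f"{cdoc['n_permutations']} permutations ({cdoc['method']}), "
            f"alpha {cdoc['corrected_alpha']} per direction."
        )
        lines.append("")
        sig = [c for c in cdoc["clusters"] if c["significant"]]
        if not sig:
            lines.append("no significant clusters")
        else:
            lines.append("| sign | mass | p | samples | freq (Hz) | time (s) |")
            lines.append("|---|---|---|---|---|---|")
            for c in sig:
                lines.append(
                    f"| {c['sign']} | {c['mass']:.1f} | {_fmt_p(c['p_mc'])} | "
                    f"{c['n_samples']} | {c['freq_min']:.1f}-{c['freq_max']:.1f} | "
                    f"{c['time_min']:.2f}-{c['time_max']:.2f} |"
                )
        lines.append("")
    except FileNotFoundError as e:
        gaps.append(str(e))
        lines += ["*cluster outputs missing*", ""]

    lines += ["## Structure-function associations", ""]
    try:
        with open(out / "associations.json") as fh:
            adoc = json.load(fh)
        if not adoc:
            lines.append("no associations computed")
        else:
            lines.append("| x | y | covariates | r | df | p | threshold | sig | excluded |")
            lines.append("|---|---|---|---|---|---|---|---|---|")
            for r in adoc:
                lines.append(
                    f"| {r['x_name']} | {r['y_name']} | {','.join(r['covariate_names'])} "
                    f"| {r['r_partial']:.3f} | {r['df']} | {_fmt_p(r['p'])} "
                    f"| {r['alpha_corrected']:.4f} | {'yes' if r['significant'] else 'no'} "
                    f"| {r['n_excluded']} |"
                )
        lines.append("")
    except FileNotFoundError as e:
        gaps.append(str(e))
        lines += ["*association outputs missing*", ""]

    report = out / "report.md"
    report.write_text("\n".join(lines))
    if gaps:
        raise StageError("report incomplete; missing outputs: " + "; ".join(gaps))
    return report
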