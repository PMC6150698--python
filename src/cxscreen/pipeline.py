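"""End-to-end orchestration: simulate → (preprocess) → stats → infer → report.

Every stage reads and writes plain files, so any stage can be rerun in
isolation; a single master seed in the configuration drives all stochastic
stages through derived sub-seeds.  ``run_all`` is deterministic: the same
configuration and seed reproduce every CSV byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import infer, stats
from .config import PipelineConfig
from .synth import ScreenDataset, simulate_experiment

logger = logging.getLogger("cxscreen")

__all__ = ["simulate_stage", "stats_stage", "infer_stage", "run_all",
           "ground_truth_comparison", "write_movies", "preprocess_stage"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending pair."""


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        raise StageError(f"stage {name!r} failed: {err}") from err


def simulate_stage(config: PipelineConfig) -> ScreenDataset:
    """Simulate the screen described by the configuration."""
    gt = config.connectome()
    return simulate_experiment(
        gt, n_flies=config.n_flies, protocols=config.protocols(),
        sampling_rate=config.sampling_rate, duration=config.duration,
        seed=config.seed, n_repeats=config.n_repeats)


def stats_stage(dataset: ScreenDataset, config: PipelineConfig
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Compute the statistic hierarchy and attach overlap labels."""
    repeat_df, run_df, pair_df = stats.compute_screen_stats(
        dataset, fbase_floor=config.fbase_floor)
    labels = {(a, b): v
              for (a, b), v in dataset.ground_truth.overlap_labels.items()}
    pair_df["overlapping"] = [
        labels[(row.pre, row.post)] for row in pair_df.itertuples()]
    return repeat_df, run_df, pair_df


def infer_stage(pair_df: pd.DataFrame, config: PipelineConfig
                ) -> tuple[list[infer.ConnectivityEdge], infer.NullModel, np.ndarray]:
    """Fit the null on control pairs, bootstrap the threshold, classify."""
    points = infer.feature_points(pair_df, pulse_filter=config.analysis_pulses)
    null_points = [p for p in points if not p.overlapping]
    model = infer.fit_null(null_points,
                           support_fraction=config.support_fraction,
                           seed=config.mcd_seed)
    threshold, pvals = infer.significance_threshold(
        null_points, model, B=config.bootstrap_B, alpha=config.alpha,
        seed=config.seed + 1, refit=config.bootstrap_refit)
    model.threshold = threshold
    model.alpha = config.alpha
    edges = infer.classify_edges(points, model, threshold)
    return edges, model, pvals


def write_movies(dataset: ScreenDataset, outdir: str | Path,
                 max_drift: float = 3.0) -> dict:
    """Render every run of a dataset as a multi-page TIFF with planted drift.

    Each run gets one 16-bit TIFF (its 4 repeats concatenated) and a small
    whole-run translation drawn deterministically from the dataset seed.
    Returns the ground-truth shifts, which are also written alongside.
    """
    import tifffile

    from .synth import simulate_run_movie

    outdir = Path(outdir)
    moviedir = outdir / "movies"
    moviedir.mkdir(parents=True, exist_ok=True)
    truth = {}
    for idx, ((pre, post, fly, n_pulses), reps) in enumerate(dataset.runs.items()):
        rng = np.random.default_rng([dataset.seed, 777, idx])
        drift = (0.0, 0.0) if idx % 4 == 0 else tuple(
            np.round(rng.uniform(-max_drift, max_drift, 2), 2))
        movie = simulate_run_movie(reps, drift=drift, seed=rng)
        name = f"{pre}__{post}__fly{fly}__p{n_pulses}.tif"
        tifffile.imwrite(moviedir / name, movie.frames)
        truth[name] = list(movie.true_shift)
    (moviedir / "true_shifts.json").write_text(json.dumps(truth, indent=1))
    return truth


def preprocess_stage(data_dir: str | Path, outdir: str | Path,
                     upsample_factor: int = 10) -> dict:
    """Movies -> ΔF/F0 traces, one experiment (pair, fly) at a time.

    Reads the TIFFs and manifest written by the simulate stage (or user data
    in the same layout), registers each experiment's runs, extracts traces
    and writes a trace dataset the stats stage can read, plus a
    preprocessing report (shifts, background, F0, ROI size per experiment).
    """
    import tifffile

    from .preprocess import preprocess_experiment

    data_dir, outdir = Path(data_dir), Path(outdir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    tracedir = outdir / "traces"
    tracedir.mkdir(parents=True, exist_ok=True)

    by_experiment: dict[tuple, list[dict]] = {}
    for entry in manifest["runs"]:
        by_experiment.setdefault((entry["pre"], entry["post"], entry["fly"]),
                                 []).append(entry)

    n_repeats = manifest["n_repeats"]
    fs = manifest["sampling_rate"]
    report = {}
    new_runs = []
    for (pre, post, fly), entries in by_experiment.items():
        movies = []
        for entry in entries:
            name = f"{pre}__{post}__fly{fly}__p{entry['n_pulses']}.tif"
            movies.append(tifffile.imread(data_dir / "movies" / name))
        try:
            dff_runs, exp_report = preprocess_experiment(
                movies, n_repeats=n_repeats, upsample_factor=upsample_factor)
        except Exception as err:  # noqa: BLE001
            raise StageError(
                f"stage 'preprocess' failed on pair ({pre}, {post}), "
                f"fly {fly}: {err}") from err
        report[f"{pre}__{post}__fly{fly}"] = exp_report
        for entry, repeats in zip(entries, dff_runs):
            fname = f"{pre}__{post}__fly{fly}__p{entry['n_pulses']}.csv"
            cols = {"time": np.arange(repeats[0].size) / fs}
            for i, rep in enumerate(repeats, 1):
                cols[f"repeat{i}"] = rep
            pd.DataFrame(cols).to_csv(tracedir / fname, index=False)
            new_runs.append({**entry, "file": f"traces/{fname}"})

    new_manifest = {**manifest, "runs": new_runs}
    (outdir / "manifest.json").write_text(json.dumps(new_manifest, indent=1))
    if (data_dir / "metadata.csv").exists():
        (outdir / "metadata.csv").write_bytes(
            (data_dir / "metadata.csv").read_bytes())
    (outdir / "preprocess_report.json").write_text(json.dumps(report, indent=1))
    return report


def ground_truth_comparison(edges: list[infer.ConnectivityEdge],
                            dataset: ScreenDataset) -> pd.DataFrame:
    """Confusion table of calls against the planted connectome.

    A pair counts as correctly recovered when its significance matches the
    planted presence of a connection and, for significant calls, the sign
    matches the planted response direction.
    """
    gt = dataset.ground_truth
    rows = []
    for e in edges:
        cls = gt.response_for((e.pre, e.post))
        planted = cls.kind.value != "none"
        planted_sign = int(np.sign(cls.peak_amplitude)) if planted else 0
        correct = (e.significant == planted
                   and (not e.significant or e.sign == planted_sign))
        rows.append({"pre": e.pre, "post": e.post,
                     "planted_kind": cls.kind.value,
                     "planted_sign": planted_sign,
                     "significant": e.significant, "sign": e.sign,
                     "control": e.control, "correct": correct})
    return pd.DataFrame(rows)


def run_all(config: PipelineConfig, outdir: str | Path,
            write_dataset: bool = False) -> dict:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Writes repeat/run/pair statistics CSVs, ``edges.csv``, the null-model
    JSON, the network exports, a ground-truth comparison (when the planted
    connectome is available) and a run log with every effective parameter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset = _stage("simulate", simulate_stage, config)
    if write_dataset:
        _stage("simulate", dataset.to_disk, outdir / "dataset")
    repeat_df, run_df, pair_df = _stage("stats", stats_stage, dataset, config)
    edges, model, _ = _stage("infer", infer_stage, pair_df, config)

    repeat_df.to_csv(outdir / "repeat_stats.csv", index=False)
    run_df.to_csv(outdir / "run_stats.csv", index=False)
    pair_df.to_csv(outdir / "pair_stats.csv", index=False)
    edges_df = infer.edges_to_dataframe(edges)
    edges_df.to_csv(outdir / "edges.csv", index=False)
    model.to_json(outdir / "null_model.json")
    infer.write_network(edges, outdir)

    comparison = ground_truth_comparison(edges, dataset)
    comparison.to_csv(outdir / "ground_truth_comparison.csv", index=False)

    log = {"config": config.to_dict(),
           "n_pairs": int(len(edges)),
           "n_significant": int(edges_df["significant"].sum()),
           "threshold": model.threshold}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1))
    logger.info("pipeline finished: %d pairs, %d significant, threshold %.3f",
                log["n_pairs"], log["n_significant"], model.threshold)
    return {"dataset": dataset, "repeat_df": repeat_df, "run_df": run_df,
            "pair_df": pair_df, "edges": edges, "edges_df": edges_df,
            "model": model, "comparison": comparison}
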