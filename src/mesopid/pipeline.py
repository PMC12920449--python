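"""End-to-end orchestration of the analysis.

A pipeline run takes a set of datasets (each either simulated on the fly
or loaded from disk), and per dataset: binarizes traces if needed,
computes the distance-binned Pearson-correlation profile and its
exponential-decay fit, the per-pair PID table with NuMIT z-scores, the
z-scored synergy/redundancy spatial profiles with effective information
lengths, and the multiplex path decomposition of the kNN synergy and
redundancy layers. Across datasets it contrasts the summary metrics
between conditions with permutation tests and Hedges' g.

All artifacts are written under the output directory; the run report
collects every per-dataset summary and cross-condition comparison.
Determinism: a single global seed is stretched into per-stage seeds by
hashing (seed, stage, dataset), so identical configs give identical runs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import networks, numit, pid, spatial, stats, synthetic
from .exceptions import FitFailureError
from .state_inference import binarize_dataset

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

COMPARISON_METRICS = (
    "lambda_um",
    "lambda_eff_corr_um",
    "lambda_eff_z_si_um",
    "lambda_eff_z_ri_um",
    "long_complementary",
    "long_shared",
    "long_unique_a",
    "long_unique_b",
)


def derive_seed(global_seed: int, *tokens) -> int:
    """Stable stage seed from the global seed and arbitrary string tokens."""
    key = ":".join([str(global_seed), *map(str, tokens)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class DatasetSpec:
    """One recording: either simulation parameters or paths to files."""

    name: str
    condition: str  # 'spontaneous' | 'stimulated'
    # simulation parameters (used when paths are absent)
    n_neurons: int = 200
    n_frames: int = 10_000
    lambda_true_um: Optional[float] = None  # default set by condition
    c0_latent: float = 0.3
    c_inf_latent: float = 0.02
    rate: float = 0.05
    ar_coeff: float = 0.5
    as_traces: bool = False  # emit calcium-like traces to exercise the HMM
    amp_active: float = 1.0
    noise_sd: float = 0.25
    # file inputs (override simulation)
    positions_path: Optional[str] = None
    matrix_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.condition not in ("spontaneous", "stimulated"):
            raise ValueError("condition must be 'spontaneous' or 'stimulated'")
        if self.lambda_true_um is None:
            self.lambda_true_um = 400.0 if self.condition == "spontaneous" else 900.0


@dataclass
class PipelineConfig:
    datasets: List[DatasetSpec] = field(default_factory=list)
    field_width_um: float = 3000.0
    field_height_um: float = 3000.0
    tau: int = 1
    min_distance_um: float = 100.0
    d_min_um: float = 100.0
    d_max_um: float = 3000.0
    n_bins: int = 20
    min_pairs: int = 50
    d0_um: float = 100.0
    dmax_um: float = 1500.0
    n_null: int = 100
    numit_tolerance: Optional[float] = None
    numit_max_retries: int = 50
    max_pairs: Optional[int] = None  # PID pair subsample for quick runs
    k: int = 10
    long_threshold: int = 4
    n_perm: int = 10_000
    seed: int = 0
    outdir: str = "mesopid_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        datasets = [DatasetSpec(**d) for d in raw.pop("datasets", [])]
        return cls(datasets=datasets, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def simulate_dataset(spec: DatasetSpec, config: PipelineConfig):
    """Generate a synthetic dataset per its spec (binary or trace form)."""
    pop_seed = derive_seed(config.seed, "population", spec.name)
    act_seed = derive_seed(config.seed, "activity", spec.name)
    pop = synthetic.generate_population(
        spec.n_neurons, config.field_width_um, config.field_height_um, pop_seed
    )
    params = synthetic.ActivityParams(
        lambda_true_um=spec.lambda_true_um,
        c0_latent=spec.c0_latent,
        c_inf_latent=spec.c_inf_latent,
        rate=spec.rate,
        ar_coeff=spec.ar_coeff,
        n_frames=spec.n_frames,
        seed=act_seed,
    )
    activity = synthetic.generate_correlated_activity(pop, params)
    if spec.as_traces:
        traces = synthetic.generate_calcium_like_traces(
            activity, spec.amp_active, spec.noise_sd,
            seed=derive_seed(config.seed, "traces", spec.name),
        )
        return pop, traces, "traces", params
    return pop, activity, "binary", params


def _profile_metrics(
    pairs: pd.DataFrame, value_column: str, config: PipelineConfig, tag: str
) -> dict:
    """Bin, fit, and summarize one per-pair quantity; NaNs on failure."""
    out = {f"lambda_{tag}_um": np.nan, f"lambda_eff_{tag}_um": np.nan,
           f"c0_{tag}": np.nan, f"c_inf_{tag}": np.nan, f"fit_ok_{tag}": False}
    try:
        profile = spatial.bin_by_distance(
            pairs, config.d_min_um, config.d_max_um, config.n_bins,
            config.min_pairs, value_column=value_column,
        )
        fit = spatial.fit_exponential_decay(profile)
    except (ValueError, FitFailureError) as exc:
        logger.warning("profile fit failed for %s: %s", tag, exc)
        return out
    out[f"fit_ok_{tag}"] = fit.fit_ok
    if fit.fit_ok:
        out[f"lambda_{tag}_um"] = fit.lambda_um
        out[f"c0_{tag}"] = fit.c0
        out[f"c_inf_{tag}"] = fit.c_inf
        try:
            eff = spatial.effective_information_length(fit, config.d0_um, config.dmax_um)
            out[f"lambda_eff_{tag}_um"] = eff.lambda_eff_um
        except ZeroDivisionError:
            pass
    out[f"profile_{tag}"] = profile
    out[f"fit_{tag}"] = fit
    return out


def analyze_dataset(
    spec: DatasetSpec, config: PipelineConfig, outdir: Path
) -> dict:
    """Run every stage on one dataset and write its artifacts."""
    timings = {}
    t0 = time.perf_counter()
    if spec.positions_path and spec.matrix_path:
        pop, matrix, mode = mio.read_dataset(
            spec.positions_path, spec.matrix_path,
            config.field_width_um, config.field_height_um,
        )
        params = None
    else:
        pop, matrix, mode, params = simulate_dataset(spec, config)
    timings["ingest_s"] = time.perf_counter() - t0

    ds_dir = outdir / spec.name
    ds_dir.mkdir(parents=True, exist_ok=True)
    mio.write_population(pop, ds_dir / "positions.csv")
    if params is not None:
        mio.write_json(dataclasses.asdict(params), ds_dir / "generation_params.json")

    t0 = time.perf_counter()
    if mode == "traces":
        activity, fit_report = binarize_dataset(
            matrix, seed=derive_seed(config.seed, "hmm", spec.name)
        )
        mio.write_table(fit_report, ds_dir / "hmm_fit_report.tsv")
    else:
        activity = mio.validate_binary(matrix)
    mio.write_matrix(activity, ds_dir / "activity.h5")
    timings["binarize_s"] = time.perf_counter() - t0

    summary: dict = {"dataset": spec.name, "condition": spec.condition}

    t0 = time.perf_counter()
    corr_pairs = spatial.pairwise_pearson(activity, pop, config.min_distance_um)
    corr_metrics = _profile_metrics(corr_pairs, "value", config, "corr")
    timings["correlation_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pid_table = pid.all_pairs_pid(
        activity, pop, tau=config.tau,
        min_distance_um=config.min_distance_um,
        max_pairs=config.max_pairs,
        subsample_seed=derive_seed(config.seed, "pairsub", spec.name),
    )
    timings["pid_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    z_table = numit.normalize_pair_table(
        pid_table,
        series_length=activity.shape[0] - config.tau,
        n_null=config.n_null,
        tolerance=config.numit_tolerance,
        max_retries=config.numit_max_retries,
        seed=derive_seed(config.seed, "numit", spec.name),
    )
    mio.write_table(z_table, ds_dir / "pair_pid_zscored.tsv")
    timings["numit_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    ok = z_table[z_table["numit_flag"] == "ok"]
    z_si_metrics = _profile_metrics(ok, "z_si", config, "z_si")
    z_ri_metrics = _profile_metrics(ok, "z_ri", config, "z_ri")
    timings["profiles_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    syn_layer = networks.build_knn_layer(ok, "z_si", config.k, "synergy",
                                         nodes=range(pop.n_neurons))
    red_layer = networks.build_knn_layer(ok, "z_ri", config.k, "redundancy",
                                         nodes=range(pop.n_neurons))
    paths, proportions = networks.decompose_multiplex(
        syn_layer, red_layer, config.long_threshold
    )
    mio.write_table(
        pd.concat([syn_layer.to_frame(), red_layer.to_frame()]),
        ds_dir / "layers.tsv",
    )
    mio.write_table(paths, ds_dir / "paths.tsv")
    mio.write_table(proportions, ds_dir / "path_proportions.tsv")
    timings["networks_s"] = time.perf_counter() - t0

    for metrics in (corr_metrics, z_si_metrics, z_ri_metrics):
        for key, value in metrics.items():
            if key.startswith(("profile_", "fit_")) and not key.startswith("fit_ok"):
                continue  # objects are written to disk, not to the report
            summary[key] = value
    summary["lambda_um"] = summary["lambda_corr_um"]
    long_row = proportions[proportions["path_length"] == "long"]
    for cat in networks.CATEGORIES:
        summary[f"long_{cat}"] = (
            float(long_row[cat].iloc[0]) if len(long_row) else np.nan
        )
    summary["n_pairs_pid"] = int(len(pid_table))
    summary["timings"] = timings
    profiles = {
        tag: m.get(f"profile_{tag}")
        for tag, m in (("corr", corr_metrics), ("z_si", z_si_metrics),
                       ("z_ri", z_ri_metrics))
    }
    for tag, profile in profiles.items():
        if profile is not None:
            mio.write_table(profile.to_frame(), ds_dir / f"profile_{tag}.tsv")
    mio.write_json(
        {k: v for k, v in summary.items() if k != "timings"},
        ds_dir / "summary.json",
    )
    return {"summary": summary, "proportions": proportions}


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on every dataset and contrast conditions."""
    if not config.datasets:
        raise ValueError("config lists no datasets")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = []
    for spec in config.datasets:
        logger.info("analyzing dataset %s (%s)", spec.name, spec.condition)
        try:
            results.append(analyze_dataset(spec, config, outdir))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for dataset {spec.name!r}: {exc}"
            ) from exc

    metrics = pd.DataFrame([r["summary"] for r in results]).drop(columns=["timings"])
    comparisons = {}
    conditions = set(metrics["condition"])
    if {"spontaneous", "stimulated"} <= conditions:
        for metric in COMPARISON_METRICS:
            sub = metrics.dropna(subset=[metric])
            counts = sub["condition"].value_counts()
            if counts.get("spontaneous", 0) >= 2 and counts.get("stimulated", 0) >= 2:
                cmp_seed = derive_seed(config.seed, "compare", metric)
                comparison = stats.compare_conditions(
                    sub, metric, n_perm=config.n_perm, seed=cmp_seed
                )
                comparisons[metric] = dataclasses.asdict(comparison)

    aggregate = networks.aggregate_over_datasets(
        [r["proportions"] for r in results]
    )
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "datasets": [r["summary"] for r in results],
        "comparisons": comparisons,
        "path_proportions_aggregate": aggregate.to_dict(orient="records"),
    }
    mio.write_table(metrics, outdir / "dataset_metrics.tsv")
    mio.write_json(report, outdir / "run_report.json")
    return report
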