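"""One-command orchestration of the full dialect analysis.

Sequence: read (or simulate) f0 traces -> gap fill -> spline smooth -> pairwise
DTW -> log transform -> principal coordinates -> standardize PC1/PC2 ->
pseudo-ID pooling for unlabeled calls -> multilevel fit per axis -> scale
summaries, level means, city contrasts, variant tables. Every intermediate
artifact is written as plain CSV so any stage can be inspected or swapped, and
a manifest records the seed, configuration hash, package versions, and
convergence diagnostics. Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance import DtwConfig, normalize_log, pairwise_distances
from .errors import ConfigurationError
from .model import ModelSpec, build_model_data, city_contrasts, fit, level_means, summarize_sd
from .ordination import pcoa, standardize
from .synthetic import GeneratorConfig, corrupt_ids, simulate_contours
from .traces import SmoothingConfig, fill_gaps, qc_report, read_traces, smooth_trace, write_traces
from .variants import summarize_sampling, variant_proportions

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending ids."""


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    Exactly one of (``traces_path`` + ``metadata_path``) or ``generator``
    must be given. ``seed`` governs every random component (MCMC chains and,
    when simulating, the generator).
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    traces_path: str | None = None
    metadata_path: str | None = None
    generator: GeneratorConfig | None = None
    dtw: DtwConfig = field(default_factory=DtwConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    window_s: float = 300.0
    rhat_threshold: float = 1.01

    def __post_init__(self):
        has_files = self.traces_path is not None and self.metadata_path is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ConfigurationError(
                "exactly one of (traces_path + metadata_path) or generator must be set"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and d["generator"] is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key, typ in (("dtw", DtwConfig), ("smoothing", SmoothingConfig), ("model_spec", ModelSpec)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d, default=str))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _config_dict(cfg)
    cfg_hash = hashlib.sha256(json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "versions": {"contactcalls": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    # --- input stage
    if cfg.generator is not None:
        gen = GeneratorConfig(**{**asdict(cfg.generator), "seed": cfg.seed})
        traces, metadata, truth = _stage("simulate")(simulate_contours)(gen)
        write_traces(traces, out / "traces_raw.csv")
        metadata.to_csv(out / "metadata.csv", index=False)
    else:
        traces = _stage("read")(read_traces)(cfg.traces_path)
        metadata = pd.read_csv(cfg.metadata_path, dtype={"call_id": str})
        ids = {t.call_id for t in traces}
        missing = [c for c in metadata["call_id"] if c not in ids]
        extra = [t.call_id for t in traces if t.call_id not in set(metadata["call_id"])]
        if missing or extra:
            raise PipelineError(
                f"stage 'read' failed: metadata/trace mismatch; "
                f"missing traces: {missing[:5]}, unreferenced traces: {extra[:5]}"
            )
        order = {c: i for i, c in enumerate(metadata["call_id"])}
        traces = sorted(traces, key=lambda t: order[t.call_id])
    manifest["stages"].append({"stage": "input", "n_calls": len(traces)})

    # --- conditioning
    filled = [_stage("fill_gaps")(fill_gaps)(t, step=cfg.smoothing.step) for t in traces]
    smoothed = [_stage("smooth")(smooth_trace)(t, cfg.smoothing) for t in filled]
    qc = qc_report(filled, smoothed)
    qc.to_csv(out / "qc_report.csv", index=False)
    write_traces(smoothed, out / "traces_conditioned.csv")
    manifest["stages"].append(
        {"stage": "conditioning", "median_residual_rms_hz": float(qc["residual_rms_hz"].median())}
    )

    # --- distances and ordination
    dm = _stage("distance")(pairwise_distances)(smoothed, cfg.dtw)
    dm.to_csv(out / "distances_raw.csv")
    dml = _stage("normalize_log")(normalize_log)(dm, cfg.dtw)
    dml.to_csv(out / "distances_log.csv")
    ord_ = _stage("ordinate")(pcoa)(dml, k=2)
    ord_.to_frame().to_csv(out / "ordination.csv", index=False)
    ord_.eigenvalue_report().to_csv(out / "eigenvalues.csv", index=False)
    manifest["stages"].append(
        {
            "stage": "ordination",
            "proportion_explained": [float(p) for p in ord_.proportion_explained],
        }
    )

    # --- model data (pool unlabeled calls into 5-minute pseudo-IDs)
    md = metadata.set_index("call_id").loc[list(ord_.ids)].reset_index()
    pooled = _stage("pool_ids")(corrupt_ids)(md, window_s=cfg.window_s, mode="strip_unlabeled")
    posts = {}
    for m, axis in enumerate(("pc1", "pc2")):
        scores = _stage("standardize")(standardize)(ord_.axis(m))
        data = _stage("build_model_data")(build_model_data)(pooled, scores)
        posts[axis] = _stage(f"fit_{axis}")(fit)(
            data,
            cfg.model_spec,
            chains=cfg.chains,
            warmup=cfg.warmup,
            samples=cfg.samples,
            seed=cfg.seed + m,
            rhat_threshold=cfg.rhat_threshold,
        )
        posts[axis].to_frame().to_csv(out / f"draws_{axis}.csv", index=False)
        summarize_sd(posts[axis]).to_csv(out / f"sigma_summary_{axis}.csv", index=False)
        level_means(posts[axis]).to_csv(out / f"level_means_{axis}.csv", index=False)
        manifest["stages"].append(
            {"stage": f"fit_{axis}", **{k: v for k, v in posts[axis].sampler_stats.items()}}
        )

    contrasts = _stage("contrasts")(city_contrasts)(posts["pc1"], posts["pc2"])
    contrasts.table.to_csv(out / "city_contrasts.csv", index=False)
    contrasts.pair_summary.to_csv(out / "city_contrast_summary.csv", index=False)

    # --- variants and sampling effort
    if "variant" in metadata.columns:
        counts, pct, n_unlabeled = _stage("variants")(variant_proportions)(metadata)
        counts.to_csv(out / "variant_counts.csv")
        pct.to_csv(out / "variant_percentages.csv")
        manifest["stages"].append({"stage": "variants", "n_unlabeled": n_unlabeled})
    sampling = _stage("sampling")(summarize_sampling)(metadata)
    sampling["per_park"].to_csv(out / "sampling_per_park.csv", index=False)
    manifest["stages"].append(
        {
            "stage": "sampling",
            "park_median": sampling["park_median"],
            "city_median": sampling["city_median"],
        }
    )

    sig1 = summarize_sd(posts["pc1"]).set_index("parameter")
    manifest["results"] = {
        "sigma_city_pc1_mean": float(sig1.loc["sigma_city", "mean"]),
        "sigma_park_pc1_mean": float(sig1.loc["sigma_park", "mean"]),
    }
    sig2 = summarize_sd(posts["pc2"]).set_index("parameter")
    manifest["results"].update(
        {
            "sigma_city_pc2_mean": float(sig2.loc["sigma_city", "mean"]),
            "sigma_park_pc2_mean": float(sig2.loc["sigma_park", "mean"]),
        }
    )
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
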