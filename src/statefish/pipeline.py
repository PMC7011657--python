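"""End-to-end orchestration: simulate, featurize, (optionally) decode,
decompose, and write a reproducible run report.

A single global seed fans out to per-stage seeds through a fixed splitting
rule (`numpy.random.SeedSequence` with a documented spawn key per stage),
so each module run is independently reproducible and a rerun from the same
saved config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sfio
from .calcium import features_for_trajectory_set
from .codebook import build_codebook, decoding_threshold
from .decode import (
    call_genes,
    decode_pixels,
    estimate_error_rates,
    preprocess_codestack,
)
from .decomposition import VarianceDecomposition
from .simulate import (
    default_gene_models,
    generate_cell_states,
    generate_expression,
)
from .simulate_calcium import CalciumSimParams, generate_calcium_trajectories
from .simulate_imaging import generate_codestack, random_spots

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

log = logging.getLogger("statefish")

#: fixed spawn keys: stage name -> key used with SeedSequence
_SEED_STREAMS = {
    "cell_states": 1,
    "gene_models": 2,
    "expression": 3,
    "trajectories": 4,
    "codebook": 5,
    "codestack": 6,
    "spots": 7,
    "shuffle": 8,
    "significance": 9,
}


def derive_seed(seed: int, stream: str) -> int:
    """Per-stage seed derived from the global seed (stable, < 2**31)."""
    key = _SEED_STREAMS[stream]
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    n_cells: int = 2000
    n_genes: int = 150
    mode: str = "poisson"  # or "bursting"
    burst_size: float = 9.0
    n_hidden: int = 2
    use_extracted_calcium: bool = False
    # synthetic decoding rehearsal (off by default: imaging-scale)
    decode_codestack: bool = False
    # spot density ~1.5e-3 per px^2: dense enough for statistics, sparse
    # enough that overlapping point-spread tails stay rare
    n_spots: int = 400
    per_bit_detection: float = 0.908
    background_sd: float = 2.0
    stack_shape: tuple = (512, 512)
    n_blanks: int = 48
    deconvolve: bool = False
    out_dir: str = "statefish_run"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data["stack_shape"] = tuple(data.get("stack_shape", (512, 512)))
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run generate -> featurize -> (decode) -> decompose and write outputs.

    Returns the run report (also written as ``report.json``).  Any stage
    failure raises with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "stages": {}}
    try:
        config.to_json(out / "config.json")

        stage = "simulate"
        log.info("generating %d cells x %d genes", config.n_cells, config.n_genes)
        states = generate_cell_states(config.n_cells, derive_seed(config.seed, "cell_states"))
        models = default_gene_models(
            config.n_genes,
            derive_seed(config.seed, "gene_models"),
            mode=config.mode,
            burst_size=config.burst_size,
        )
        dataset = generate_expression(states, models, derive_seed(config.seed, "expression"))
        sfio.write_table(dataset.expression, out / "expression.csv")
        sfio.write_counts_mtx(dataset.expression, out / "expression.mtx")
        sfio.write_table(dataset.features, out / "features_truth.csv")
        sfio.write_table(states, out / "cell_states.csv", index=False)

        stage = "calcium"
        traj = generate_calcium_trajectories(
            states, CalciumSimParams(), derive_seed(config.seed, "trajectories")
        )
        sfio.write_table(traj.to_long_dataframe(), out / "trajectories.csv", index=False)
        extracted = features_for_trajectory_set(traj)
        sfio.write_table(extracted, out / "features_extracted.csv")
        ca_cols = [c for c in dataset.features.columns if c.startswith("ca_")]
        fidelity = {
            c: float(
                pd.Series(extracted[c]).corr(
                    pd.Series(dataset.features[c].to_numpy(), index=extracted.index),
                    method="spearman",
                )
            )
            for c in ca_cols
        }
        report["stages"]["calcium"] = {"truth_vs_extracted_spearman": fidelity}

        if config.decode_codestack:
            stage = "decode"
            cb = build_codebook(
                24, 4, 4, config.n_genes, config.n_blanks,
                seed=derive_seed(config.seed, "codebook"),
            )
            cb.to_csv(out / "codebook.csv")
            spots = random_spots(
                cb, config.n_spots, config.stack_shape, 3,
                seed=derive_seed(config.seed, "spots"),
            )
            stack, truth = generate_codestack(
                spots, cb,
                per_bit_detection=config.per_bit_detection,
                background_sd=config.background_sd,
                seed=derive_seed(config.seed, "codestack"),
                shape=config.stack_shape, n_z=3,
            )
            sfio.write_table(truth, out / "spot_truth.csv", index=False)
            processed = preprocess_codestack(stack, deconvolve=config.deconvolve)
            labels, dists = decode_pixels(processed, cb)
            calls = call_genes(labels, dists, processed, cb)
            sfio.write_table(calls, out / "gene_calls.csv", index=False)
            est, fpr = estimate_error_rates(
                calls, processed, cb, n_cells=config.n_cells, n_true_spots=len(truth)
            )
            report["stages"]["decode"] = {
                "threshold": decoding_threshold(cb),
                "n_calls": int(len(calls)),
                "f_full": est.f_full,
                "p_bit": est.p_bit,
                "sensitivity": est.sensitivity,
                "false_positive_rate": fpr,
            }
            (out / "error_rates.json").write_text(
                json.dumps(report["stages"]["decode"], indent=2, sort_keys=True) + "\n"
            )

        stage = "decompose"
        features = dataset.features.copy()
        if config.use_extracted_calcium:
            for c in ca_cols:
                features[c] = extracted[c].to_numpy()
        model = VarianceDecomposition(
            counts=dataset.expression,
            features=features,
            categories=dataset.feature_categories,
            n_hidden=config.n_hidden,
            shuffle_seed=derive_seed(config.seed, "shuffle"),
        )
        results = model.fit()
        summary = results.summary_frame()
        sfio.write_table(summary, out / "decomposition_summary.csv")
        for st in results.stages:
            sfio.write_table(st.dispersion, out / f"dispersion_{st.name}.csv")
        report["stages"]["decompose"] = {
            "stage_names": results.stage_names,
            "median_fano": {s.name: s.median_fano for s in results.stages},
            "median_r2": {s.name: s.median_r_squared for s in results.stages},
            "pc12_explained_variance": {
                s.name: s.correlation.pc_explained_variance for s in results.stages
            },
            "shuffled_pc12": results.final.correlation.shuffled_pc_explained_variance,
            "overdispersion_retained": bool(results.final.median_fano > 2.0),
        }

        report["ok"] = True
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return report
    except Exception as exc:  # pragma: no cover - failure path
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
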