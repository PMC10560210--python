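"""End-to-end orchestration: network construction through robustness scoring.

A single :class:`PipelineConfig` drives every stage; stage defaults mirror
the study conditions (288-sample subsampling, 1000 bootstrap attempts, 95%
consensus, 1000 shuffles, K in 2..15, 20 x 5-fold prediction, 100 random
removal replicates). Every stochastic stage derives its seed from the master
seed and its own stage name, so inserting or skipping a stage never perturbs
the others, and one master seed fully determines the bundle.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import build_consensus_network
from .core import (
    MultilayerNetwork,
    read_expression,
    read_network_layers,
    validate_multilayer,
    write_network_layers,
)
from .linkpred import prediction_grid
from .nestedness import nestedness_test, realized_niche_matrix, specialization_matrix
from .niche import layer_similarity, niche_table, partner_fidelity, within_layer_overlap
from .nullmodels import shuffle_network, zscore
from .robustness import correlate_T_with_niche, robustness_suite
from .sbm import MembershipModel, hard_assignments, select_K
from .synthetic import generate_sbm_multilayer

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = ("network", "niche", "nestedness", "nulls", "sbm", "prediction", "robustness")


@dataclass
class PipelineConfig:
    """Parameters for every pipeline stage.

    ``input_mode`` is one of ``simulate`` (draw a synthetic multilayer
    network), ``networks`` (read edge lists from ``network_dir``), or
    ``expression`` (build consensus layers from per-environment CSVs listed
    in ``expression_files``).
    """

    input_mode: str = "simulate"
    out_dir: str = "results"
    master_seed: int = 0
    # simulate mode
    sim: dict = field(
        default_factory=lambda: {
            "n_chaperones": 15,
            "n_clients": 1000,
            "n_layers": 12,
            "K": 2,
            "affinity_contrast": 10.0,
            "membership_concentration": 0.05,
        }
    )
    # networks mode
    network_dir: str | None = None
    manifest: str = "manifest.yaml"
    # expression mode
    expression_files: dict = field(default_factory=dict)  # layer_id -> csv path
    chaperone_ids: list = field(default_factory=list)
    client_ids: list = field(default_factory=list)
    n_subsample: int | None = 288
    n_boot: int = 1000
    consensus_threshold: float = 0.95
    alpha: float = 0.05
    # downstream stages
    n_shuffles: int = 1000
    K_min: int = 2
    K_max: int = 15
    sbm_restarts: int = 10
    prediction_reps: int = 20
    prediction_folds: int = 5
    random_removal_reps: int = 100
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed mixed with a CRC of the stage name."""
    return int(np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")


def _stage_network(cfg: PipelineConfig, out: Path) -> MultilayerNetwork:
    if cfg.input_mode == "simulate":
        net, _ = generate_sbm_multilayer(seed=stage_seed(cfg.master_seed, "network"), **cfg.sim)
    elif cfg.input_mode == "networks":
        if not cfg.network_dir:
            raise ValueError("networks mode requires network_dir")
        net = read_network_layers(cfg.network_dir, cfg.manifest)
    elif cfg.input_mode == "expression":
        expr_set = [read_expression(p, layer_id=lid) for lid, p in cfg.expression_files.items()]
        net = build_consensus_network(
            expr_set,
            cfg.chaperone_ids,
            cfg.client_ids,
            n_subsample=cfg.n_subsample,
            n_boot=cfg.n_boot,
            consensus_threshold=cfg.consensus_threshold,
            alpha=cfg.alpha,
            seed=stage_seed(cfg.master_seed, "network"),
        )
    else:
        raise ValueError(f"unknown input_mode {cfg.input_mode!r}")
    report = validate_multilayer(net)
    if not report.ok:
        raise ValueError(f"constructed network is invalid: {report.violations}")
    write_network_layers(net, out / "network")
    return net


def _stage_niche(net: MultilayerNetwork, out: Path) -> dict:
    tab = niche_table(net)
    fid = partner_fidelity(net)
    overlap = within_layer_overlap(net)
    lsim = layer_similarity(net)
    _write_df(tab.per_chaperone, out / "niche" / "per_chaperone.csv")
    _write_df(tab.per_layer, out / "niche" / "per_layer.csv")
    _write_df(fid.between_layers, out / "niche" / "between_layers.csv")
    _write_df(fid.fidelity, out / "niche" / "fidelity.csv")
    _write_df(overlap.within_layer, out / "niche" / "within_layer.csv")
    _write_df(lsim, out / "niche" / "layer_similarity.csv", index=True)
    return {"niche": tab, "fidelity": fid, "overlap": overlap}


def _stage_nestedness(net: MultilayerNetwork, cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    rows = []
    builders = {"realized_niche": realized_niche_matrix, "specialization": specialization_matrix}
    seed = stage_seed(cfg.master_seed, "nestedness")
    for i, (name, builder) in enumerate(builders.items()):
        res = nestedness_test(net, builder, n_shuffles=cfg.n_shuffles, seed=seed + i)
        null_sd = float(res.null_samples.std(ddof=1)) if res.n_shuffles > 1 else float("nan")
        rows.append(
            {
                "statistic": name,
                "rho_observed": res.rho_observed,
                "null_mean": float(res.null_samples.mean()),
                "null_sd": null_sd,
                # degree-preserving shuffles leave some statistic matrices
                # invariant (e.g. S_ca depends only on row sums); flag those
                # so a p of 0 from an all-ties null is not read as evidence
                "degenerate_null": bool(null_sd == 0.0),
                "p_value": res.p_value,
                "n_shuffles": res.n_shuffles,
            }
        )
    df = pd.DataFrame(rows)
    _write_df(df, out / "nestedness" / "nestedness.csv")
    return df


def _stage_nulls(net: MultilayerNetwork, cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    """Partner-fidelity z-scores against per-layer curveball shuffles."""
    observed = partner_fidelity(net).fidelity.set_index("chaperone")["J_c"]
    rng = np.random.default_rng(stage_seed(cfg.master_seed, "nulls"))
    null = np.empty((cfg.n_shuffles, net.n_chaperones))
    for s in range(cfg.n_shuffles):
        shuffled = shuffle_network(net, seed=rng)
        null[s] = (
            partner_fidelity(shuffled).fidelity.set_index("chaperone")["J_c"]
            .reindex(net.chaperone_ids)
            .to_numpy()
        )
    rows = []
    for i, c in enumerate(net.chaperone_ids):
        z = zscore(float(observed[c]), null[:, i])
        rows.append(
            {
                "chaperone": c,
                "J_c": float(observed[c]),
                "null_mean": float(np.nanmean(null[:, i])),
                "z": z,
                "significant": bool(np.isfinite(z) and abs(z) > 1.96),
            }
        )
    df = pd.DataFrame(rows)
    _write_df(df, out / "nulls" / "fidelity_z.csv")
    return df


def _stage_sbm(net: MultilayerNetwork, cfg: PipelineConfig, out: Path) -> MembershipModel:
    model, trace = select_K(
        net,
        cfg.K_min,
        cfg.K_max,
        seed=stage_seed(cfg.master_seed, "sbm"),
        n_restarts=cfg.sbm_restarts,
    )
    (out / "sbm").mkdir(parents=True, exist_ok=True)
    with open(out / "sbm" / "model.json", "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
    _write_df(pd.DataFrame(trace, columns=["K", "BIC", "log_likelihood"]), out / "sbm" / "bic_trace.csv")
    labels = hard_assignments(model)
    _write_df(
        pd.DataFrame({"chaperone": net.chaperone_ids, "group": labels}),
        out / "sbm" / "chaperone_groups.csv",
    )
    return model


def _stage_prediction(net: MultilayerNetwork, cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    res = prediction_grid(
        net,
        n_reps=cfg.prediction_reps,
        n_folds=cfg.prediction_folds,
        seed=stage_seed(cfg.master_seed, "prediction"),
    )
    _write_df(res.auc_matrix, out / "prediction" / "auc.csv", index=True)
    return res.auc_matrix


def _stage_robustness(net, model, niche_tab, cfg: PipelineConfig, out: Path) -> pd.DataFrame:
    labels = hard_assignments(model)
    T = robustness_suite(
        net,
        labels,
        n_random_reps=cfg.random_removal_reps,
        seed=stage_seed(cfg.master_seed, "robustness"),
    )
    _write_df(T, out / "robustness" / "T.csv")
    if net.n_layers >= 3:
        corr = correlate_T_with_niche(T, niche_tab)
        _write_df(corr, out / "robustness" / "T_niche_correlation.csv")
    return T


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute the configured stages in order; returns the in-memory results.

    Writes tidy CSVs, the SBM model JSON, and a ``run_manifest.yaml``
    (config + derived stage seeds + package version) under ``out_dir``.
    Stages not listed in ``config.stages`` are skipped; downstream stages
    that need an upstream product recompute it in memory if it was skipped
    on disk.
    """
    cfg = PipelineConfig(**config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        res = fn(*args)
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2f s", stage, timings[stage])
        return res

    if "network" in cfg.stages:
        net = timed("network", _stage_network, cfg, out)
    else:
        net = read_network_layers(out / "network", "manifest.yaml")
    results["network"] = net

    if "niche" in cfg.stages:
        results.update(timed("niche", _stage_niche, net, out))
    else:
        results["niche"] = niche_table(net)
    if "nestedness" in cfg.stages:
        results["nestedness"] = timed("nestedness", _stage_nestedness, net, cfg, out)
    if "nulls" in cfg.stages:
        results["nulls"] = timed("nulls", _stage_nulls, net, cfg, out)
    if "sbm" in cfg.stages:
        model = timed("sbm", _stage_sbm, net, cfg, out)
        results["sbm"] = model
    else:
        model_path = out / "sbm" / "model.json"
        model = MembershipModel.from_dict(json.loads(model_path.read_text())) if model_path.exists() else None
        results["sbm"] = model
    if "prediction" in cfg.stages:
        results["prediction"] = timed("prediction", _stage_prediction, net, cfg, out)
    if "robustness" in cfg.stages:
        if model is None:
            raise ValueError("robustness stage requires the sbm stage (or a saved model.json)")
        results["robustness"] = timed(
            "robustness", _stage_robustness, net, model, results["niche"], cfg, out
        )

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stage_seeds": {s: stage_seed(cfg.master_seed, s) for s in STAGES},
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "run.log", "a") as fh:
        for stage, dt in timings.items():
            fh.write(f"{stage}\t{dt:.3f}s\n")
    return results
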