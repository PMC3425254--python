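"""End-to-end orchestration: simulate -> normalize -> QC -> call -> associate.

The pipeline contrasts two normalization modes on the same cohort: the
cohort-based mode (what a standard array-processing pipeline does, and what
fails at a common deletion) and the reference mode (clusters from known
two-copy samples, which recovers the deletions).  The results bundle
collects deletion counts per mode, the QC summary, the association table
and truth-comparison metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os

import numpy as np
import pandas as pd
import yaml

from . import assoc, hmm, io, normalize, qc
from .simulate import (
    DiseaseModel,
    SimulationConfig,
    simulate_cohort,
)

logger = logging.getLogger("cnvlrr.pipeline")

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline",
            "load_config", "save_config"]


@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig
    )
    #: normalization modes to run ("cohort", "reference").
    modes: tuple = ("cohort", "reference")
    qc_thresholds: qc.QCThresholds = dataclasses.field(
        default_factory=qc.QCThresholds
    )
    hmm_overrides: dict = dataclasses.field(default_factory=dict)
    #: association methods: subset of {"probe_lrr", "trend", "mixture"}.
    association: tuple = ("probe_lrr", "trend", "mixture")
    mixture_components: int = 2
    out_dir: str = "results"
    log_level: str = "INFO"
    write_final_report: bool = False

    def validate(self) -> None:
        if not self.modes:
            raise ValueError("at least one normalization mode is required")
        for m in self.modes:
            if m not in ("cohort", "reference"):
                raise ValueError(f"unknown normalization mode {m!r}")
        for a in self.association:
            if a not in ("probe_lrr", "trend", "mixture"):
                raise ValueError(f"unknown association method {a!r}")
        self.simulation.validate()


def _config_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        out = {}
        for f in dataclasses.fields(cfg):
            out[f.name] = _config_dict(getattr(cfg, f.name))
        return out
    if isinstance(cfg, np.ndarray):
        return cfg.tolist()
    if isinstance(cfg, (tuple, list)):
        return [_config_dict(v) for v in cfg]
    return cfg


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (paths excluded)."""
    d = _config_dict(config)
    d.pop("out_dir", None)
    d.pop("log_level", None)
    js = json.dumps(d, sort_keys=True)
    return hashlib.sha256(js.encode()).hexdigest()[:12]


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", {})
    dm = sim.pop("disease_model", {}) if isinstance(sim, dict) else {}
    thr = raw.pop("qc_thresholds", {})
    for key in ("genotype_class_freqs", "compressed_class_means"):
        if key in sim and sim[key] is not None:
            sim[key] = tuple(sim[key])
    cfg = PipelineConfig(
        simulation=SimulationConfig(
            disease_model=DiseaseModel(**dm), **sim
        ),
        qc_thresholds=qc.QCThresholds(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in thr.items()}
        ),
        **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()},
    )
    cfg.validate()
    return cfg


@dataclasses.dataclass
class ResultsBundle:
    deletion_counts: dict
    qc_summary: dict
    association: pd.DataFrame
    calling_metrics: dict
    concordance: float | None
    mixture_bic: dict
    seed: int
    config_hash: str


def _normalize(raw, cohort, mode):
    theta, R = normalize.compute_polar(raw.X, raw.Y)
    mask = cohort.true_copy_number == 2 if mode == "reference" else None
    model = normalize.fit_cluster_model(
        theta, R, mode, reference_mask=mask
    )
    return normalize.compute_lrr_baf(theta, R, model), model


def _called_copy_numbers(paths, locus_idx):
    """Modal called state over the locus probes, clipped to {0,1,2}."""
    states = np.vstack([p.states for p in paths])[:, locus_idx]
    med = np.median(states, axis=1)
    return np.clip(np.round(med).astype(int), 0, 2)


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run every stage and write the results bundle under ``out_dir``."""
    config.validate()
    out = io.ensure_dir(config.out_dir)
    chash = config_hash(config)
    seed = config.simulation.seed
    logger.info("pipeline start: seed=%d config=%s", seed, chash)
    save_config(config, os.path.join(out, "config.yaml"))

    cohort, raw, probes = simulate_cohort(config.simulation)
    locus_idx = [j for j, p in enumerate(probes) if p.is_locus_probe]
    probe_ids = [p.probe_id for p in probes]
    locus_ids = [probe_ids[j] for j in locus_idx]
    logger.info("simulated %d samples x %d probes (%d locus probes)",
                cohort.n, len(probes), len(locus_idx))
    io.write_sample_sheet(os.path.join(out, "sample_sheet.tsv"), cohort)
    io.write_truth(os.path.join(out, "truth.tsv"), cohort)
    if config.write_final_report:
        io.write_final_report(os.path.join(out, "final_report.tsv"),
                              cohort, raw, probes)

    params = hmm.HMMParams(**config.hmm_overrides)
    signals = {}
    deletion_counts = {}
    calls = {}
    qc_pass = np.ones(cohort.n, dtype=bool)
    qc_summary = {}
    for mode in config.modes:
        sig, model = _normalize(raw, cohort, mode)
        signals[mode] = sig
        io.write_matrix(os.path.join(out, f"lrr_{mode}.tsv"), sig.lrr,
                        cohort.sample_id, probe_ids)
        io.write_matrix(os.path.join(out, f"baf_{mode}.tsv"), sig.baf,
                        cohort.sample_id, probe_ids)
        io.write_cluster_model(
            os.path.join(out, f"clusters_{mode}.tsv"), model
        )
        if mode == config.modes[0]:
            metrics = qc.qc_table(sig.lrr, sig.baf, cohort.sample_id)
            flags = qc.apply_qc(metrics, config.qc_thresholds)
            flags.to_csv(os.path.join(out, "qc_metrics.tsv"), sep="\t",
                         index=False, float_format="%.6g")
            qc_pass = flags["qc_pass"].to_numpy()
            qc_summary = {
                "n_samples": int(cohort.n),
                "n_pass": int(qc_pass.sum()),
                "n_fail": int((~qc_pass).sum()),
            }
            logger.info("QC: %d/%d samples pass", qc_pass.sum(), cohort.n)
    for mode in config.modes:
        sig = signals[mode]
        keep = np.flatnonzero(qc_pass)
        sub = normalize.SignalMatrices(
            theta=sig.theta[keep], R=sig.R[keep], lrr=sig.lrr[keep],
            baf=sig.baf[keep], floored=sig.floored[keep],
        )
        ids = [cohort.sample_id[i] for i in keep]
        paths, calls_by_sample = hmm.call_cohort(sub, probes, ids, params)
        calls[mode] = (paths, calls_by_sample, keep)
        deletion_counts[mode] = hmm.count_locus_deletions(
            calls_by_sample, locus_idx
        )
        io.write_calls_bed(os.path.join(out, f"calls_{mode}.tsv"),
                           calls_by_sample, probes)
        logger.info("%s-mode locus deletion count: %d", mode,
                    deletion_counts[mode])

    calling_metrics = {}
    if "reference" in calls:
        paths, _, keep = calls["reference"]
        called = _called_copy_numbers(paths, locus_idx)
        truth = cohort.true_copy_number[keep]
        deleted = truth < 2
        called_del = called < 2
        calling_metrics = {
            "sensitivity": float(
                np.mean(called_del[deleted])) if deleted.any() else 1.0,
            "specificity": float(
                np.mean(~called_del[~deleted])) if (~deleted).any() else 1.0,
            "exact_accuracy": float(np.mean(called == truth)),
        }

    # association testing on QC-passing samples
    keep = np.flatnonzero(qc_pass)
    pheno = cohort.phenotype[keep]
    covars = cohort.covariates.iloc[keep].reset_index(drop=True)
    assoc_mode = "cohort" if "cohort" in signals else config.modes[0]
    lrr_locus = signals[assoc_mode].lrr[keep][:, locus_idx]
    results = []
    mixture = None
    concordance = None
    bic = {}
    if "probe_lrr" in config.association and pheno.min() != pheno.max():
        results.extend(
            assoc.probe_lrr_tests(lrr_locus, pheno, covars, locus_ids)
        )
    if "trend" in config.association and pheno.min() != pheno.max():
        if "reference" in calls:
            paths, _, keep_r = calls["reference"]
            copies = _called_copy_numbers(paths, locus_idx)
        else:
            copies = cohort.true_copy_number[keep]
        results.append(assoc.trend_test(copies, pheno, covars))
    if "mixture" in config.association:
        summary = assoc.summarize_signal(lrr_locus,
                                         config.mixture_components)
        mixture = assoc.fit_joint_mixture(
            summary, pheno, covars, K=config.mixture_components
        )
        concordance = assoc.class_concordance(
            mixture.classes, cohort.true_copy_number[keep] == 0
        )
        bic = {K: assoc.mixture_bic(summary, K) for K in (2, 3)}
    table = io.association_table(
        results, mixture,
        n_cases=int((pheno == 1).sum()), n_controls=int((pheno == 0).sum()),
    )
    table.to_csv(os.path.join(out, "association_results.tsv"), sep="\t",
                 index=False, float_format="%.6g")

    bundle = ResultsBundle(
        deletion_counts=deletion_counts,
        qc_summary=qc_summary,
        association=table,
        calling_metrics=calling_metrics,
        concordance=concordance,
        mixture_bic=bic,
        seed=seed,
        config_hash=chash,
    )
    _write_summary(os.path.join(out, "summary.tsv"), bundle)
    logger.info("pipeline done: %s", {k: v for k, v in
                                      bundle.deletion_counts.items()})
    return bundle


def _write_summary(path, bundle: ResultsBundle) -> None:
    rows = [("seed", bundle.seed), ("config_hash", bundle.config_hash)]
    for mode, n in bundle.deletion_counts.items():
        rows.append((f"deletion_count_{mode}", n))
    for k, v in bundle.qc_summary.items():
        rows.append((f"qc_{k}", v))
    for k, v in bundle.calling_metrics.items():
        rows.append((f"calling_{k}", _round6(v)))
    if bundle.concordance is not None:
        rows.append(("mixture_concordance", _round6(bundle.concordance)))
    for k, v in bundle.mixture_bic.items():
        rows.append((f"mixture_bic_K{k}", _round6(v)))
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(
        path, sep="\t", index=False
    )


def _round6(v: float) -> float:
    return float(f"{v:.6g}") if isinstance(v, float) and math.isfinite(v) \
        else v
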