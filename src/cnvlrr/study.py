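"""Canned study runs: the calling-failure contrast and recovery targets.

Each function runs one arm of the study end to end on freshly simulated
data — generator, normalization, calling and association exactly as the
pipeline wires them — and returns the headline quantity.  They are used by
the acceptance script and the acceptance test suite; the background-probe
panel is trimmed where it does not influence the quantity being measured
(locus calling and association depend on the 5 locus probes plus flanking
context, not on the full array).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import assoc, hmm, normalize
from .simulate import (
    SimulationConfig,
    concordance_fixture,
    control_fixture,
    simulate_cohort,
    trend_fixture,
    two_class_fixture,
)

__all__ = [
    "reference_called_copies",
    "control_genotype_percentages",
    "cohort_deletion_count",
    "trend_or_estimate",
    "mixture_or_estimate",
    "concordance_estimate",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, n: int) -> list:
    """Deterministic child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31))
            for child in ss.spawn(n)]


def _normalize_mode(raw, cohort, mode):
    theta, R = normalize.compute_polar(raw.X, raw.Y)
    mask = cohort.true_copy_number == 2 if mode == "reference" else None
    model = normalize.fit_cluster_model(theta, R, mode, reference_mask=mask)
    return normalize.compute_lrr_baf(theta, R, model)


def reference_called_copies(cfg: SimulationConfig):
    """Simulate, reference-normalize and Viterbi-call one cohort.

    Returns ``(called_copy_numbers, cohort)`` with the per-sample call
    taken as the median locus state, clipped to {0, 1, 2}.
    """
    cohort, raw, probes = simulate_cohort(cfg)
    sig = _normalize_mode(raw, cohort, "reference")
    locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
    paths, _ = hmm.call_cohort(sig, probes)
    states = np.vstack([p.states for p in paths])[:, locus]
    called = np.clip(np.round(np.median(states, axis=1)).astype(int), 0, 2)
    return called, cohort


def control_genotype_percentages(seed: int, n_controls: int = 759,
                                 n_background: int = 200) -> dict:
    """Percent of controls called 0- and 1-copy by the reference path."""
    cfg = dataclasses.replace(
        control_fixture(n_controls=n_controls, seed=seed),
        n_background_probes=n_background,
    )
    called, _ = reference_called_copies(cfg)
    return {
        "pct_null": 100.0 * float(np.mean(called == 0)),
        "pct_het": 100.0 * float(np.mean(called == 1)),
    }


def cohort_deletion_count(seed: int, n_background: int = 200) -> int:
    """Locus deletion calls after cohort-mode normalization (expected: 0)."""
    cfg = trend_fixture(seed=seed, n_background_probes=n_background)
    cohort, raw, probes = simulate_cohort(cfg)
    sig = _normalize_mode(raw, cohort, "cohort")
    locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
    _, calls = hmm.call_cohort(sig, probes)
    return hmm.count_locus_deletions(calls, locus)


def trend_fit(seed: int, n_background: int = 60):
    """Adjusted per-copy trend fit on reference-mode called copy numbers."""
    cfg = trend_fixture(seed=seed, n_background_probes=n_background)
    called, cohort = reference_called_copies(cfg)
    return assoc.trend_test(called, cohort.phenotype, cohort.covariates)


def trend_or_estimate(seed: int, n_background: int = 60) -> float:
    return trend_fit(seed, n_background).odds_ratio


def mixture_or_estimate(seed: int, n_background: int = 60,
                        restarts: int = 8):
    """Joint-mixture carrier-vs-null OR on the two-class fixture.

    Runs the full chain: compressed-regime simulation, cohort-mode
    normalization, PCA+LDA summary of the 5 locus probes, K=2 joint EM with
    quartile-age/gender/region/smoking adjustment.  Returns ``(or, p)``.
    """
    cfg = two_class_fixture(seed=seed, n_background_probes=n_background)
    cohort, raw, probes = simulate_cohort(cfg)
    sig = _normalize_mode(raw, cohort, "cohort")
    locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
    summary = assoc.summarize_signal(sig.lrr[:, locus], 2)
    fit = assoc.fit_joint_mixture(
        summary, cohort.phenotype, cohort.covariates, K=2, restarts=restarts
    )
    return fit.odds_ratio, fit.p_value


def concordance_estimate(seed: int, n_background: int = 60,
                         restarts: int = 8) -> float:
    """Mixture-class vs truth concordance on the concordance fixture."""
    cfg = concordance_fixture(seed=seed, n_background_probes=n_background)
    cohort, raw, probes = simulate_cohort(cfg)
    sig = _normalize_mode(raw, cohort, "cohort")
    locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
    summary = assoc.summarize_signal(sig.lrr[:, locus], 2)
    fit = assoc.fit_joint_mixture(
        summary, cohort.phenotype, cohort.covariates, K=2, restarts=restarts
    )
    return assoc.class_concordance(fit.classes,
                                   cohort.true_copy_number == 0)
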