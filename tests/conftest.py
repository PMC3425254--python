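import numpy as np
import pytest

import cnvlrr as c


@pytest.fixture(scope="session")
def calling_fixture():
    """Default-condition cohort: 1532 samples, 5 locus + 2000 background
    probes, ~53/38/9% genotype classes, default noise."""
    cfg = c.SimulationConfig(seed=1)
    cohort, raw, probes = c.simulate_cohort(cfg)
    return cfg, cohort, raw, probes


@pytest.fixture(scope="session")
def normalized(calling_fixture):
    """Cohort- and reference-mode signal matrices for the default cohort."""
    cfg, cohort, raw, probes = calling_fixture
    theta, R = c.compute_polar(raw.X, raw.Y)
    cohort_model = c.fit_cluster_model(theta, R, "cohort")
    ref_model = c.fit_cluster_model(
        theta, R, "reference", reference_mask=cohort.true_copy_number == 2
    )
    return {
        "cohort": c.compute_lrr_baf(theta, R, cohort_model),
        "reference": c.compute_lrr_baf(theta, R, ref_model),
        "cohort_model": cohort_model,
        "reference_model": ref_model,
        "theta": theta,
        "R": R,
    }


@pytest.fixture(scope="session")
def locus_indices(calling_fixture):
    _, _, _, probes = calling_fixture
    return [j for j, p in enumerate(probes) if p.is_locus_probe]


@pytest.fixture(scope="session")
def trend_cohort():
    """Trend-effect cohort (per-copy OR 0.74) with reduced background."""
    cfg = c.trend_fixture(seed=11, n_background_probes=60)
    cohort, raw, probes = c.simulate_cohort(cfg)
    theta, R = c.compute_polar(raw.X, raw.Y)
    ref_model = c.fit_cluster_model(
        theta, R, "reference", reference_mask=cohort.true_copy_number == 2
    )
    sig = c.compute_lrr_baf(theta, R, ref_model)
    cohort_model = c.fit_cluster_model(theta, R, "cohort")
    sig_cohort = c.compute_lrr_baf(theta, R, cohort_model)
    locus = [j for j, p in enumerate(probes) if p.is_locus_probe]
    return cohort, probes, locus, sig, sig_cohort


def called_copies(sig, probes, locus):
    paths, _ = c.call_cohort(sig, probes)
    states = np.vstack([p.states for p in paths])[:, locus]
    return np.clip(np.round(np.median(states, axis=1)).astype(int), 0, 2)
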