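"""Synthetic SNP-array cohorts with a common gene-deletion locus.

Generates a case-control cohort carrying a biallelic full-gene deletion at a
5-probe locus (copy number 0/1/2 shared by all locus probes), embedded in a
panel of diploid background probes, together with two-channel raw
intensities, epidemiological covariates, and a disease status drawn from a
logistic model with a per-copy (trend) or carrier (two-class) effect.

The intensity model separates two noise sources that behave very differently
at a deletion locus:

* a *differential* channel-transfer noise ``delta`` that moves signal between
  the A and B channels while conserving their sum.  Where the true
  allele-specific signal is weak (zero copies, both channels reading only
  nonspecific background) this scrambles the polar angle theta, so the
  B-allele frequency of null samples spreads out over [0, 1];
* a *common-mode* multiplicative intensity noise acting on the total signal
  R, parameterized by its log2-scale standard deviation, which is what
  per-probe LRR standard deviations measure.

A "compressed" signal regime is also provided for association fixtures: it
emulates the signal that survives a cohort-based vendor normalization at a
common deletion, where the copy-number information in R has largely been
absorbed into the genotype clusters and only a compressed, ordered residual
remains (two-copy > one-copy > null on the LRR scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbeDef",
    "DiseaseModel",
    "SimulationConfig",
    "Cohort",
    "RawIntensities",
    "default_locus_probes",
    "build_probe_panel",
    "assign_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_intensities",
    "simulate_cohort",
]

#: Genomic coordinates (1-based, chromosome 1) of the five array probes
#: covering the deletion locus.
LOCUS_PROBE_POSITIONS = (
    ("rs12068997", 110_032_359),
    ("rs4147567", 110_034_047),
    ("rs1056806", 110_034_670),
    ("rs12562055", 110_034_988),
    ("rs2239892", 110_035_809),
)

REGION_LABELS = ("R1", "R2", "R3", "R4", "R5")
SMOKING_LABELS = ("never", "former", "current")


@dataclass(frozen=True)
class ProbeDef:
    """A single array probe: identity, position and intensity scale."""

    probe_id: str
    chromosome: str
    position: int
    full_signal: float = 1.0
    is_locus_probe: bool = False

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"probe {self.probe_id}: position must be > 0")
        if self.full_signal <= 0:
            raise ValueError(f"probe {self.probe_id}: full_signal must be > 0")


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model on the latent copy-number genotype.

    ``trend`` mode uses the copy number itself as the linear predictor
    (odds ratio per additional gene copy), ``two_class`` uses an indicator
    of carrying at least one copy (carrier vs homozygous-null).
    """

    mode: str = "trend"
    log_or_effect: float = math.log(0.74)
    intercept: float = 0.0
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("trend", "two_class"):
            raise ValueError(f"unknown disease model mode: {self.mode!r}")


@dataclass
class SimulationConfig:
    n_cases: int = 773
    n_controls: int = 759
    #: P(copy number = 0, 1, 2) in the source population.
    genotype_class_freqs: tuple = (0.5296, 0.3810, 0.0894)
    #: fraction of full_signal still present at zero copies (nonspecific
    #: background); 0.095 makes the reference-normalized null LRR equal
    #: log2(0.095/1.095) = -3.53, the 0-copy HMM state mean.
    background_fraction: float = 0.095
    #: sd of the channel-transfer (differential) noise, units of full_signal.
    #: 0.04 scrambles the polar angle where allele signal is absent (null
    #: BAF spreads over [0,1]) while keeping the BAF drift of a clean
    #: diploid sample (~0.0014) below the 0.002 exclusion threshold.
    channel_noise_sd: float = 0.04
    #: log2-scale sd of the common-mode total-intensity noise.
    lrr_noise_sd: float = 0.05
    #: B-allele frequency on non-deleted haplotypes.
    b_allele_freq: float = 0.5
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    n_background_probes: int = 2000
    seed: int = 0
    #: "raw" draws intensities from the copy-number signal model;
    #: "compressed" emulates post-normalization signal at the locus whose
    #: LRR class means are already compressed (vendor cohort normalization).
    signal_regime: str = "raw"
    #: locus LRR class means (copy 0, 1, 2) in the compressed regime.
    compressed_class_means: tuple = (-0.10, 0.08, 0.17)

    def validate(self) -> None:
        freqs = np.asarray(self.genotype_class_freqs, dtype=float)
        if freqs.shape != (3,):
            raise ValueError("genotype_class_freqs must have 3 entries")
        for i, p in enumerate(freqs):
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"genotype_class_freqs[{i}] = {p} is not a probability"
                )
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"genotype_class_freqs sum to {freqs.sum()!r}, expected 1"
            )
        if self.n_cases < 0 or self.n_controls < 0 or (
            self.n_cases + self.n_controls
        ) <= 0:
            raise ValueError("sample counts must be positive")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be >= 0")
        if self.lrr_noise_sd < 0:
            raise ValueError("lrr_noise_sd must be >= 0")
        if self.background_fraction < 0:
            raise ValueError("background_fraction must be >= 0")
        if not (0.0 <= self.b_allele_freq <= 1.0):
            raise ValueError("b_allele_freq must be in [0, 1]")
        if self.signal_regime not in ("raw", "compressed"):
            raise ValueError(f"unknown signal_regime: {self.signal_regime!r}")


@dataclass
class Cohort:
    """Sampled case-control cohort with ground-truth genotypes."""

    sample_id: list
    #: locus-wide copy number per sample, in {0, 1, 2}.
    true_copy_number: np.ndarray
    #: B-allele counts per sample x locus probe (<= copy number).
    b_alleles: np.ndarray
    #: 1 = case, 0 = control.
    phenotype: np.ndarray
    #: gender / age / region / smoking per sample.
    covariates: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.sample_id)


@dataclass
class RawIntensities:
    """Two-channel (A, B) intensities, samples x probes, nonnegative."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must have the same shape")


def default_locus_probes(full_signal: float = 1.0) -> list:
    return [
        ProbeDef(pid, "1", pos, full_signal, is_locus_probe=True)
        for pid, pos in LOCUS_PROBE_POSITIONS
    ]


def build_probe_panel(n_background: int, full_signal: float = 1.0) -> list:
    """Locus probes plus diploid background probes, sorted by position.

    Background probes flank the locus on chromosome 1 at 10 kb spacing,
    leaving the locus window untouched.
    """
    probes = default_locus_probes(full_signal)
    n_up = n_background // 2
    n_down = n_background - n_up
    for i in range(n_up):
        probes.append(
            ProbeDef(f"bg_up_{i:05d}", "1", 110_020_000 - 10_000 * (n_up - i),
                     full_signal)
        )
    for i in range(n_down):
        probes.append(
            ProbeDef(f"bg_dn_{i:05d}", "1", 110_050_000 + 10_000 * i,
                     full_signal)
        )
    probes.sort(key=lambda p: (p.chromosome, p.position))
    return probes


def assign_genotypes(n: int, class_freqs, seed=None) -> np.ndarray:
    """Draw locus copy numbers {0,1,2} from the class frequencies."""
    freqs = np.asarray(class_freqs, dtype=float)
    for i, p in enumerate(freqs):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"class_freqs[{i}] = {p} is not a probability")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class_freqs sum to {freqs.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    return rng.choice(3, size=n, p=freqs / freqs.sum()).astype(np.int64)


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Gender, age, region and smoking with hospital-based-study margins."""
    gender = np.where(rng.random(n) < 0.87, "male", "female")
    age = np.clip(rng.normal(66.0, 10.0, n), 21.0, 80.0)
    region = rng.choice(REGION_LABELS, size=n)
    smoking = rng.choice(SMOKING_LABELS, size=n, p=(0.3, 0.3, 0.4))
    return pd.DataFrame(
        {"gender": gender, "age": age, "region": region, "smoking": smoking}
    )


def _covariate_term(covariates: pd.DataFrame, effects: dict) -> np.ndarray:
    """Linear predictor contribution of covariates.

    Effect keys: "age" (per year), "gender:male", "region:R2",
    "smoking:current" etc.  Unknown keys are rejected.
    """
    term = np.zeros(len(covariates))
    for key, beta in effects.items():
        if key == "age":
            term += beta * covariates["age"].to_numpy()
            continue
        if ":" not in key:
            raise ValueError(f"unknown covariate effect {key!r}")
        col, level = key.split(":", 1)
        if col not in covariates.columns:
            raise ValueError(f"unknown covariate effect {key!r}")
        term += beta * (covariates[col].to_numpy() == level)
    return term


def simulate_phenotype(
    copy_number: np.ndarray,
    covariates: pd.DataFrame,
    disease_model: DiseaseModel,
    seed=None,
) -> np.ndarray:
    """Bernoulli disease status from the logistic model on genotype."""
    if disease_model.mode == "trend":
        g = copy_number.astype(float)
    else:  # two_class, validated at construction
        g = (copy_number > 0).astype(float)
    eta = (
        disease_model.intercept
        + disease_model.log_or_effect * g
        + _covariate_term(covariates, disease_model.covariate_effects)
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    return (rng.random(len(p)) < p).astype(np.int64)


def _noiseless_channels(copy_number, b_alleles, full_signal, f):
    """Expected channel intensities for (copy, B-count) at one probe."""
    c = copy_number.astype(float)
    b = b_alleles.astype(float)
    X0 = full_signal * ((c - b) / 2.0 + f / 2.0)
    Y0 = full_signal * (b / 2.0 + f / 2.0)
    return X0, Y0


def simulate_intensities(
    cohort: Cohort,
    probes: list,
    config: SimulationConfig,
    seed=None,
) -> RawIntensities:
    """Two-channel intensities for every sample x probe.

    Noiseless channels are ``X0 = full*( (c-b)/2 + f/2 )`` and
    ``Y0 = full*( b/2 + f/2 )``; the transfer noise delta (clipped so both
    channels stay nonnegative, hence R is conserved) is added, then the
    common-mode factor ``2**g`` with g ~ N(0, lrr_noise_sd) scales both
    channels.  In the compressed regime the locus-probe totals are instead
    rescaled to ``full*(1+f)*2**L`` with L drawn around the configured
    per-class compressed LRR means.
    """
    if np.any(cohort.b_alleles > cohort.true_copy_number[:, None]):
        raise ValueError("B-allele count exceeds copy number for some sample")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = cohort.n
    m = len(probes)
    locus_idx = [j for j, p in enumerate(probes) if p.is_locus_probe]
    X = np.empty((n, m))
    Y = np.empty((n, m))
    f = config.background_fraction
    means = np.asarray(config.compressed_class_means, dtype=float)
    for j, probe in enumerate(probes):
        if probe.is_locus_probe:
            c = cohort.true_copy_number
            b = cohort.b_alleles[:, locus_idx.index(j)]
        else:
            c = np.full(n, 2, dtype=np.int64)
            b = rng.binomial(2, config.b_allele_freq, size=n)
        X0, Y0 = _noiseless_channels(c, b, probe.full_signal, f)
        delta = rng.normal(0.0, config.channel_noise_sd * probe.full_signal, n)
        delta = np.clip(delta, -X0, Y0)
        Xj = X0 + delta
        Yj = Y0 - delta
        if probe.is_locus_probe and config.signal_regime == "compressed":
            lrr = rng.normal(means[c], config.lrr_noise_sd)
            target_r = probe.full_signal * (1.0 + f) * 2.0**lrr
            r0 = Xj + Yj
            scale = target_r / r0
        else:
            scale = 2.0 ** rng.normal(0.0, config.lrr_noise_sd, n)
        X[:, j] = Xj * scale
        Y[:, j] = Yj * scale
    return RawIntensities(X=X, Y=Y)


def simulate_cohort(config: SimulationConfig, seed=None):
    """Retrospectively sampled cohort plus raw intensities and probe panel.

    A large source population is simulated under the disease model, then
    exactly ``n_cases`` cases and ``n_controls`` controls are drawn from it
    (hospital-based case-control design: the margins are fixed by design,
    the genotype distribution within each arm follows from the model).

    Returns ``(cohort, raw_intensities, probes)``; deterministic given the
    seed (``config.seed`` unless overridden).
    """
    config.validate()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    s_geno, s_cov, s_phen, s_draw, s_int = master.spawn(5)
    n_target = config.n_cases + config.n_controls
    pool = 4 * n_target + 200
    copy_number = assign_genotypes(pool, config.genotype_class_freqs, s_geno)
    covariates = simulate_covariates(pool, np.random.default_rng(s_cov))
    phenotype = simulate_phenotype(
        copy_number, covariates, config.disease_model, s_phen
    )
    rng = np.random.default_rng(s_draw)
    cases = np.flatnonzero(phenotype == 1)
    controls = np.flatnonzero(phenotype == 0)
    if len(cases) < config.n_cases or len(controls) < config.n_controls:
        raise ValueError(
            "source population too small for the requested case/control "
            f"counts (got {len(cases)} cases, {len(controls)} controls)"
        )
    take = np.concatenate(
        [
            rng.choice(cases, size=config.n_cases, replace=False),
            rng.choice(controls, size=config.n_controls, replace=False),
        ]
    )
    probes = build_probe_panel(config.n_background_probes)
    n_locus = sum(p.is_locus_probe for p in probes)
    cn = copy_number[take]
    b_alleles = rng.binomial(
        cn[:, None], config.b_allele_freq, size=(len(take), n_locus)
    )
    cohort = Cohort(
        sample_id=[f"S{i:05d}" for i in range(len(take))],
        true_copy_number=cn,
        b_alleles=b_alleles,
        phenotype=phenotype[take],
        covariates=covariates.iloc[take].reset_index(drop=True),
    )
    raw = simulate_intensities(cohort, probes, config, seed=s_int)
    return cohort, raw, probes


def control_fixture(n_controls: int = 759, seed: int = 7) -> SimulationConfig:
    """Controls-only fixture with the empirical control class frequencies.

    The disease effect is zeroed so the control genotype distribution equals
    the configured class frequencies in expectation (with a nonzero effect,
    retrospective sampling tilts the control arm away from them).
    """
    return SimulationConfig(
        n_cases=0,
        n_controls=n_controls,
        disease_model=DiseaseModel(mode="trend", log_or_effect=0.0),
        seed=seed,
    )


def trend_fixture(seed: int = 11, **overrides) -> SimulationConfig:
    """Case-control fixture with the per-copy protective trend effect."""
    cfg = SimulationConfig(
        disease_model=DiseaseModel(mode="trend",
                                   log_or_effect=math.log(0.74)),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def two_class_fixture(seed: int = 13, **overrides) -> SimulationConfig:
    """Carrier-vs-null fixture in the compressed signal regime."""
    cfg = SimulationConfig(
        disease_model=DiseaseModel(mode="two_class",
                                   log_or_effect=math.log(0.66)),
        signal_regime="compressed",
        lrr_noise_sd=0.10,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def concordance_fixture(seed: int = 17, **overrides) -> SimulationConfig:
    """Compressed-regime fixture for mixture-vs-truth concordance."""
    cfg = SimulationConfig(
        disease_model=DiseaseModel(mode="trend", log_or_effect=0.0),
        signal_regime="compressed",
        lrr_noise_sd=0.10,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
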