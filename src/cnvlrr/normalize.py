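"""Intensity normalization: theta/R, genotype cluster models, LRR and BAF.

The Log R Ratio at a probe is ``log2(R_obs / R_exp)`` where ``R_obs`` is the
observed total intensity and ``R_exp`` the total intensity expected for the
sample's genotype, derived from per-probe genotype cluster centers.  The B
allele frequency maps the polar angle theta piecewise-linearly through the
cluster centers onto the canonical genotype positions 0 / 0.5 / 1.

Two cluster-model modes are provided:

``reference``
    Clusters are fitted from a panel of known two-copy samples only, so
    ``R_exp`` reflects the true diploid intensity and deletions appear at
    strongly negative LRR (a 0-copy sample reaches ~ -3.5).

``cohort``
    Clusters are fitted from the analysis cohort itself, emulating
    cohort-based array processing.  At a locus where homozygous deletions
    are common the intensity clusters are dominated or contaminated by
    deleted samples, so the expected intensity tracks each sample's own
    (possibly deleted) intensity cloud and the LRR is compressed toward 0.
    This is modeled by clustering total intensity on the log2 scale (k <= 3
    components) and computing a posterior-weighted expected intensity with
    a fixed log2-scale softness; the weights use each component's size, so
    a majority null class drags every sample's R_exp toward the deleted
    cloud, while minority two-copy samples keep a positive residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeClusters",
    "ClusterModel",
    "SignalMatrices",
    "compute_polar",
    "fit_cluster_model",
    "compute_lrr_baf",
]

THETA_THRESHOLDS = (1.0 / 3.0, 2.0 / 3.0)
CANONICAL_BAF = (0.0, 0.5, 1.0)
LRR_FLOOR = -10.0


@dataclass
class ProbeClusters:
    """Cluster centers for one probe."""

    probe_id: str
    #: theta centers of the retained canonical clusters, increasing.
    theta_centers: np.ndarray
    #: canonical BAF positions (subset of 0, 0.5, 1) matching theta_centers.
    canonical: np.ndarray
    #: expected total intensity per retained cluster.
    r_expected: np.ndarray
    # cohort-mode intensity components (log2 medians, weights):
    comp_log2r: np.ndarray | None = None
    comp_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.theta_centers) <= 0):
            raise ValueError(
                f"probe {self.probe_id}: theta centers not increasing"
            )
        if np.any(self.r_expected <= 0):
            raise ValueError(f"probe {self.probe_id}: r_expected must be > 0")


@dataclass
class ClusterModel:
    mode: str
    probes: list = field(default_factory=list)
    #: log2-scale sd of the posterior weighting (cohort mode).
    softness: float = 1.0


def compute_polar(X: np.ndarray, Y: np.ndarray):
    """Polar transform: theta = (2/pi)*arctan(Y/X) in [0,1], R = X + Y.

    theta is 0.5 where both channels are exactly zero.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(X < 0) or np.any(Y < 0):
        raise ValueError("channel intensities must be nonnegative")
    theta = (2.0 / np.pi) * np.arctan2(Y, X)
    theta = np.where((X == 0) & (Y == 0), 0.5, theta)
    return theta, X + Y


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 30) -> np.ndarray:
    """Quantile-seeded Lloyd iterations on a 1-D array; returns centers."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array(
            [x[assign == j].mean() if np.any(assign == j) else centers[j]
             for j in range(len(centers))]
        )
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def _theta_clusters(theta_j, r_j, probe_id, min_cluster_size):
    """Bin samples at theta 1/3 and 2/3; median centers per retained bin."""
    bins = np.digitize(theta_j, THETA_THRESHOLDS)
    centers, canonical, r_exp = [], [], []
    for b in range(3):
        members = bins == b
        if members.sum() < min_cluster_size:
            continue
        centers.append(float(np.median(theta_j[members])))
        canonical.append(CANONICAL_BAF[b])
        r_exp.append(float(np.median(r_j[members])))
    if not centers:
        raise ValueError(
            f"probe {probe_id}: all genotype clusters empty or below "
            f"min_cluster_size={min_cluster_size}"
        )
    order = np.argsort(centers)
    return (
        np.asarray(centers)[order],
        np.asarray(canonical)[order],
        np.asarray(r_exp)[order],
    )


def _soft_r_expected(r, comp_log2r, comp_weight, softness):
    """Posterior-weighted expected intensity given the R components."""
    log2r = np.log2(np.maximum(r, 1e-12))
    z = (log2r[..., None] - comp_log2r) / softness
    logw = np.log(comp_weight) - 0.5 * z**2
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=-1, keepdims=True)
    return w @ (2.0**comp_log2r)


def fit_cluster_model(
    theta: np.ndarray,
    R: np.ndarray,
    mode: str,
    probe_ids=None,
    reference_mask: np.ndarray | None = None,
    min_cluster_size: int = 3,
    softness: float = 1.0,
    max_components: int = 3,
) -> ClusterModel:
    """Fit per-probe genotype cluster models.

    Parameters
    ----------
    theta, R : (samples, probes) matrices from :func:`compute_polar`.
    mode : "cohort" or "reference".
    reference_mask : boolean per-sample mask of known two-copy samples,
        required in reference mode.
    """
    if mode not in ("cohort", "reference"):
        raise ValueError(f"unknown cluster-model mode: {mode!r}")
    if mode == "reference":
        if reference_mask is None:
            raise ValueError("reference mode requires a reference_mask of "
                             "known two-copy samples")
        reference_mask = np.asarray(reference_mask, dtype=bool)
        if reference_mask.sum() == 0:
            raise ValueError("reference_mask selects no samples")
    theta = np.atleast_2d(theta)
    R = np.atleast_2d(R)
    n, m = theta.shape
    if probe_ids is None:
        probe_ids = [f"p{j}" for j in range(m)]
    model = ClusterModel(mode=mode, softness=softness)
    sel = reference_mask if mode == "reference" else np.ones(n, dtype=bool)
    for j in range(m):
        th_j, r_j = theta[sel, j], R[sel, j]
        centers, canonical, r_exp = _theta_clusters(
            th_j, r_j, probe_ids[j], min_cluster_size
        )
        pc = ProbeClusters(
            probe_id=probe_ids[j],
            theta_centers=centers,
            canonical=canonical,
            r_expected=r_exp,
        )
        if mode == "cohort":
            # intensity components over the whole cohort: the degree to
            # which each genotype cluster is contaminated by other copy
            # numbers is carried by the posterior weights.
            log2r = np.log2(np.maximum(r_j, 1e-12))
            k = min(max_components, max(1, len(np.unique(np.round(log2r, 6)))))
            comp = _kmeans_1d(log2r, k)
            assign = np.argmin(np.abs(log2r[:, None] - comp[None, :]), axis=1)
            counts = np.bincount(assign, minlength=len(comp))
            keep = np.flatnonzero(counts > 0)
            pc.comp_log2r = np.array(
                [np.median(log2r[assign == c]) for c in keep]
            )
            pc.comp_weight = counts[keep] / len(log2r)
            # report the cluster-level expected intensity at each genotype
            # cluster's median member, for inspection/export
            pc.r_expected = _soft_r_expected(
                pc.r_expected, pc.comp_log2r, pc.comp_weight, softness
            )
        model.probes.append(pc)
    return model


@dataclass
class SignalMatrices:
    """theta, R, LRR and BAF, samples x probes."""

    theta: np.ndarray
    R: np.ndarray
    lrr: np.ndarray
    baf: np.ndarray
    #: True where R was zero and the LRR floor was substituted.
    floored: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def n_probes(self) -> int:
        return self.theta.shape[1]


def compute_lrr_baf(
    theta: np.ndarray,
    R: np.ndarray,
    model: ClusterModel,
    lrr_floor: float = LRR_FLOOR,
) -> SignalMatrices:
    """LRR and BAF from theta/R under a fitted cluster model.

    Reference mode interpolates ``r_expected`` linearly in theta between
    cluster centers (constant beyond the outermost ones).  Cohort mode uses
    the posterior-weighted expected intensity of the cohort's own intensity
    components.  BAF interpolates theta through the cluster centers mapped
    to the canonical positions, in both modes.
    """
    theta = np.atleast_2d(theta)
    R = np.atleast_2d(R)
    n, m = theta.shape
    if len(model.probes) != m:
        raise ValueError(
            f"cluster model covers {len(model.probes)} probes, "
            f"signal has {m}"
        )
    lrr = np.empty((n, m))
    baf = np.empty((n, m))
    floored = np.zeros((n, m), dtype=bool)
    for j, pc in enumerate(model.probes):
        th_j, r_j = theta[:, j], R[:, j]
        if model.mode == "cohort" and pc.comp_log2r is not None:
            r_exp = _soft_r_expected(
                r_j, pc.comp_log2r, pc.comp_weight, model.softness
            )
        else:
            r_exp = np.interp(th_j, pc.theta_centers, pc.r_expected)
        if np.any(r_exp <= 0):
            raise ValueError(f"probe {pc.probe_id}: nonpositive R_exp")
        zero = r_j <= 0
        with np.errstate(divide="ignore"):
            lrr[:, j] = np.where(
                zero, lrr_floor, np.log2(np.maximum(r_j, 1e-300) / r_exp)
            )
        floored[:, j] = zero
        if len(pc.theta_centers) >= 2:
            baf[:, j] = np.interp(th_j, pc.theta_centers, pc.canonical)
        else:
            # single retained cluster: no theta scale to interpolate on
            baf[:, j] = np.clip(th_j, 0.0, 1.0)
    baf = np.clip(baf, 0.0, 1.0)
    return SignalMatrices(theta=theta, R=R, lrr=lrr, baf=baf, floored=floored)
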