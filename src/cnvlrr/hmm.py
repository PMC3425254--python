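"""Five-state copy-number HMM over ordered probes, decoded by Viterbi.

Hidden states are the copy numbers 0-4; the observations at each probe are
the LRR (Gaussian around a state-specific mean) and the BAF (a mixture of
truncated Gaussian bands at the canonical allelic-ratio positions of the
state, uniform for the 0-copy state, which carries no allelic information).
The transition prior is sticky and distance-independent: a single locus is
analyzed, not a genome-wide scan with distance-dependent transitions.

The decoder is deliberately conservative: ties prefer the state closest to
diploid, and deletion segments shorter than ``min_probes`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "HMMParams",
    "CopyNumberPath",
    "DeletionCall",
    "emission_loglik",
    "viterbi",
    "viterbi_matrix",
    "extract_deletions",
    "count_locus_deletions",
    "call_cohort",
]

#: canonical BAF band positions per copy-number state (state 0: uniform).
STATE_BAF_BANDS = {
    0: None,
    1: (0.0, 1.0),
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
    4: (0.0, 0.25, 0.5, 0.75, 1.0),
}


def _default_transitions(stay: float = 0.9996) -> np.ndarray:
    off = (1.0 - stay) / 4.0
    t = np.full((5, 5), off)
    np.fill_diagonal(t, stay)
    return t


@dataclass
class HMMParams:
    lrr_state_means: tuple = (-3.53, -0.66, 0.0, 0.40, 0.68)
    lrr_state_sds: tuple = (1.0, 0.30, 0.18, 0.22, 0.24)
    baf_band_sd: float = 0.04
    transition: np.ndarray = field(default_factory=_default_transitions)
    initial: tuple = (0.01, 0.02, 0.94, 0.02, 0.01)

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.asarray(self.lrr_state_sds) <= 0):
            raise ValueError("lrr_state_sds must be positive")
        if self.baf_band_sd <= 0:
            raise ValueError("baf_band_sd must be positive")
        if abs(sum(self.initial) - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")


@dataclass
class CopyNumberPath:
    sample_id: str
    states: np.ndarray
    log_prob: float


@dataclass(frozen=True)
class DeletionCall:
    sample_id: str
    start_index: int
    end_index: int  # inclusive probe index
    start_position: int
    end_position: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("call start after end")


def _baf_band_logdensity(baf: np.ndarray, state: int, band_sd: float):
    """Log density of the state's BAF band mixture, truncated to [0, 1]."""
    bands = STATE_BAF_BANDS[state]
    if bands is None:
        return np.zeros_like(baf)  # uniform on [0,1]
    dens = np.zeros_like(baf, dtype=float)
    w = 1.0 / len(bands)
    for p in bands:
        z = norm.cdf((1.0 - p) / band_sd) - norm.cdf((0.0 - p) / band_sd)
        dens += w * norm.pdf(baf, loc=p, scale=band_sd) / z
    return np.log(np.maximum(dens, 1e-300))


def emission_loglik(lrr, baf, state: int, params: HMMParams = None):
    """Joint log density of (LRR, BAF) under one copy-number state."""
    if params is None:
        params = HMMParams()
    if state not in STATE_BAF_BANDS:
        raise ValueError(f"invalid state {state!r}; states are 0..4")
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF must lie in [0, 1]")
    ll = norm.logpdf(
        lrr, loc=params.lrr_state_means[state],
        scale=params.lrr_state_sds[state],
    )
    return ll + _baf_band_logdensity(baf, state, params.baf_band_sd)


#: state order used to break ties: prefer diploid, then higher copy number.
_TIE_ORDER = np.array([2, 3, 1, 4, 0])
_TIE_RANK = np.argsort(_TIE_ORDER)


def _emissions(lrr_mat, baf_mat, params):
    """(samples, probes, 5) emission log-likelihood tensor."""
    return np.stack(
        [emission_loglik(lrr_mat, baf_mat, s, params) for s in range(5)],
        axis=-1,
    )


def viterbi_matrix(lrr_mat, baf_mat, params: HMMParams = None):
    """Most probable state path for each row of an LRR/BAF matrix pair.

    Returns ``(paths, log_probs)`` with ``paths`` of shape
    (samples, probes).  Ties are broken deterministically toward diploid
    (state preference 2, 3, 1, 4, 0).
    """
    if params is None:
        params = HMMParams()
    lrr_mat = np.atleast_2d(np.asarray(lrr_mat, dtype=float))
    baf_mat = np.atleast_2d(np.asarray(baf_mat, dtype=float))
    n, m = lrr_mat.shape
    if m == 0:
        raise ValueError("empty probe list")
    if not (np.all(np.isfinite(lrr_mat)) and np.all(np.isfinite(baf_mat))):
        raise ValueError("signals must be finite")
    emis = _emissions(lrr_mat, baf_mat, params)  # (n, m, 5)
    log_t = np.log(params.transition)  # (5, 5) prev -> next
    # reorder the "previous state" axis by tie preference so that argmax
    # (first maximum) resolves ties deterministically
    v = np.log(np.asarray(params.initial)) + emis[:, 0, :]  # (n, 5)
    back = np.empty((n, m, 5), dtype=np.int8)
    for p in range(1, m):
        cand = v[:, _TIE_ORDER, None] + log_t[_TIE_ORDER, :]  # (n, 5prev, 5)
        best = np.argmax(cand, axis=1)  # index into tie order
        v = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0, :]
        v = v + emis[:, p, :]
        back[:, p, :] = _TIE_ORDER[best]
    last = _TIE_ORDER[np.argmax(v[:, _TIE_ORDER], axis=1)]
    log_probs = v[np.arange(n), last]
    paths = np.empty((n, m), dtype=np.int8)
    paths[:, -1] = last
    for p in range(m - 1, 0, -1):
        paths[:, p - 1] = back[np.arange(n), p, paths[:, p]]
    return paths, log_probs


def viterbi(lrr_row, baf_row, params: HMMParams = None,
            sample_id: str = "sample") -> CopyNumberPath:
    """Viterbi decoding of a single sample."""
    paths, lp = viterbi_matrix(lrr_row, baf_row, params)
    return CopyNumberPath(sample_id=sample_id, states=paths[0],
                          log_prob=float(lp[0]))


def extract_deletions(path: CopyNumberPath, probes,
                      min_probes: int = 3) -> list:
    """Maximal runs of a constant sub-diploid state, length >= min_probes."""
    states = np.asarray(path.states)
    calls = []
    start = None
    for i in range(len(states) + 1):
        s = states[i] if i < len(states) else 99
        if start is not None and s != states[start]:
            if states[start] in (0, 1) and i - start >= min_probes:
                calls.append(
                    DeletionCall(
                        sample_id=path.sample_id,
                        start_index=start,
                        end_index=i - 1,
                        start_position=probes[start].position,
                        end_position=probes[i - 1].position,
                        copy_number=int(states[start]),
                    )
                )
            start = None
        if start is None and i < len(states) and s in (0, 1):
            start = i
    return calls


def count_locus_deletions(calls_by_sample: dict, locus_indices) -> int:
    """Number of samples with a call overlapping any locus probe."""
    locus = set(int(i) for i in locus_indices)
    count = 0
    for calls in calls_by_sample.values():
        if any(
            set(range(c.start_index, c.end_index + 1)) & locus
            for c in calls
        ):
            count += 1
    return count


def call_cohort(signals, probes, sample_ids=None,
                params: HMMParams = None, min_probes: int = 3):
    """Viterbi-call every sample; returns (paths, calls_by_sample)."""
    lrr, baf = signals.lrr, signals.baf
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(lrr.shape[0])]
    mats, lps = viterbi_matrix(lrr, baf, params)
    paths = [
        CopyNumberPath(sample_id=sid, states=mats[i], log_prob=float(lps[i]))
        for i, sid in enumerate(sample_ids)
    ]
    calls = {
        p.sample_id: extract_deletions(p, probes, min_probes) for p in paths
    }
    return paths, calls
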