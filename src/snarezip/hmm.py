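"""Hidden-Markov idealization of high-speed traces and per-transition rates.

A Gaussian-emission HMM is fit by Baum–Welch with emissions initialized
(and by default frozen) at the values measured from the extension
distributions.  Rates are derived from the Viterbi state path by dwell
counting — k_ij = (number of i->j transitions) / (total time in i) — with
rates outside the reliably measurable 1–1000 per-second band flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.hmm import GaussianHMM

from .dwell import BellFit, fit_bell
from .equilibrium import GMMResult
from .trace import Trace

__all__ = [
    "HMMModel",
    "RateMatrix",
    "fit_hmm",
    "viterbi_path",
    "rates_from_path",
    "bell_per_transition",
    "state_energies_from_rates",
]

RELIABLE_RATE_BAND_S = (1.0, 1e3)


@dataclass
class HMMModel:
    """Fitted Gaussian-emission HMM at one sampling rate."""

    means_nm: np.ndarray
    sds_nm: np.ndarray
    transmat: np.ndarray  # per-frame transition probabilities, rows sum to 1
    sampling_rate_hz: float
    log_likelihood: float
    converged: bool
    _hmm: GaussianHMM = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return len(self.means_nm)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix with eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.transmat.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        return pi / pi.sum()


def _as_levels(trace: Trace | np.ndarray) -> np.ndarray:
    if isinstance(trace, Trace):
        return np.asarray(trace.extension_nm, dtype=float)
    return np.asarray(trace, dtype=float)


def fit_hmm(
    trace: Trace | np.ndarray,
    init: GMMResult,
    fix_means: bool = True,
    sampling_rate_hz: float | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> HMMModel:
    """Baum–Welch fit with emissions initialized from a mixture fit.

    With ``fix_means`` (default) the emission means and variances stay at
    the mixture values and only the transition matrix (and start
    distribution) is learned, mirroring the use of measured extension
    distributions as priors.
    """
    if init.k < 2:
        raise ValueError("need >= 2 states for kinetics")
    x = _as_levels(trace).reshape(-1, 1)
    if sampling_rate_hz is None:
        sampling_rate_hz = (
            trace.sampling_rate_hz if isinstance(trace, Trace) else 1200.0
        )
    params = "st" if fix_means else "stmc"
    model = GaussianHMM(
        n_components=init.k,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        params=params,
        init_params="",
        random_state=seed,
    )
    model.startprob_ = np.full(init.k, 1.0 / init.k)
    # near-diagonal start: transitions are rare at 1.2 kHz
    off = 0.01 / max(init.k - 1, 1)
    model.transmat_ = np.full((init.k, init.k), off) + (0.99 - off) * np.eye(init.k)
    model.means_ = init.means_nm.reshape(-1, 1).copy()
    model.covars_ = (init.sds_nm**2).reshape(-1, 1).copy()
    model.fit(x)
    if not model.monitor_.converged:
        warnings.warn("Baum-Welch did not converge; returning last iterate",
                      stacklevel=2)
    return HMMModel(
        means_nm=model.means_.ravel().copy(),
        sds_nm=np.sqrt(model.covars_.ravel()),
        transmat=model.transmat_.copy(),
        sampling_rate_hz=float(sampling_rate_hz),
        log_likelihood=float(model.score(x)),
        converged=bool(model.monitor_.converged),
        _hmm=model,
    )


def viterbi_path(model: HMMModel, trace: Trace | np.ndarray) -> np.ndarray:
    """Most-likely state index sequence for every frame of ``trace``."""
    x = _as_levels(trace).reshape(-1, 1)
    offsets = np.abs(x - model.means_nm.reshape(1, -1)) / model.sds_nm.reshape(1, -1)
    if np.all(offsets.min(axis=1) > 5.0):
        warnings.warn(
            "trace lies > 5 sd from every emission mean; scale mismatch?",
            stacklevel=2,
        )
    return model._hmm.predict(x)


@dataclass(frozen=True)
class RateMatrix:
    """Dwell-counting rate estimates from an idealized state path."""

    k_s: np.ndarray  # k[i, j], s^-1; diagonal is zero; nan where unvisited
    counts: np.ndarray  # transition counts
    occupancy_s: np.ndarray  # total time spent in each state
    unreliable: frozenset  # (i, j) pairs outside the reliable band


def rates_from_path(path: np.ndarray, sampling_rate_hz: float) -> RateMatrix:
    """k_ij = (i->j transition count) / (total time in i).

    States never visited get NaN outgoing rates; rates outside the
    1-1000 s^-1 band measurable at 1.2 kHz are flagged unreliable.
    """
    path = np.asarray(path)
    states = int(path.max()) + 1
    counts = np.zeros((states, states))
    a, b = path[:-1], path[1:]
    np.add.at(counts, (a[a != b], b[a != b]), 1)
    occupancy = np.array(
        [np.count_nonzero(path == i) / sampling_rate_hz for i in range(states)]
    )
    k = np.full((states, states), np.nan)
    unreliable = set()
    for i in range(states):
        if occupancy[i] == 0:
            continue
        for j in range(states):
            if i == j:
                k[i, j] = 0.0
                continue
            k[i, j] = counts[i, j] / occupancy[i]
            if counts[i, j] > 0 and not (
                RELIABLE_RATE_BAND_S[0] <= k[i, j] <= RELIABLE_RATE_BAND_S[1]
            ):
                unreliable.add((i, j))
    return RateMatrix(
        k_s=k,
        counts=counts,
        occupancy_s=occupancy,
        unreliable=frozenset(unreliable),
    )


def bell_per_transition(
    rates_by_force: dict[float, RateMatrix], pair: tuple[int, int]
) -> BellFit:
    """Bell fit of one transition's rates across forces (>= 3 forces)."""
    i, j = pair
    rows = []
    for force, rm in sorted(rates_by_force.items()):
        kij = rm.k_s[i, j]
        if np.isnan(kij) or kij <= 0:
            continue
        rows.append((force, kij))
    return fit_bell(rows)


def state_energies_from_rates(
    rates: RateMatrix, pairs: list[tuple[int, int]] | None = None
) -> dict[tuple[int, int], float]:
    """Free-energy differences dG_ij = kBT ln(k_ij / k_ji), in kBT.

    Antisymmetric by construction; pairs lacking either rate are skipped.
    """
    states = rates.k_s.shape[0]
    if pairs is None:
        pairs = [(i, j) for i in range(states) for j in range(i + 1, states)]
    out: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        kij, kji = rates.k_s[i, j], rates.k_s[j, i]
        if np.isnan(kij) or np.isnan(kji) or kij <= 0 or kji <= 0:
            continue
        out[(i, j)] = math.log(kij / kji)
    return out
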