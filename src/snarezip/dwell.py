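"""Dwell-time kinetics from force-jump traces and Bell-equation landscapes.

Latencies to unzipping/rezipping after a force jump are fit by censored
exponential maximum likelihood; rates measured at several forces are fit to
the Bell equation

    kBT ln(k / k_w) = -dG + F dx

by weighted linear regression, from which the coarse-grained energy
landscape (well depths, barrier height and position) at any force follows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2

from .constants import ATTEMPT_RATE_S, KBT_PN_NM
from .ramp import detect_steps
from .trace import Trace

__all__ = [
    "DwellRecord",
    "ExponentialFit",
    "BellFit",
    "EnergyLandscape",
    "extract_latencies",
    "fit_exponential_mle",
    "fit_bell",
    "barrier_at_force",
    "build_landscape",
]

JUMP_SETTLE_S = 0.1  # settling transient excluded from latency timing


@dataclass(frozen=True)
class DwellRecord:
    """One residency in a state at constant force.

    ``censored`` marks traces that ended before the transition; for these
    ``duration_s`` is the observation-window length.
    """

    state: str
    force_pn: float
    duration_s: float
    censored: bool = False
    condition: str = ""
    #: transition occurred during the jump ramp or settling transient;
    #: excluded from rate estimation (left truncation: by memorylessness the
    #: surviving dwells are unbiased samples of the hold-force exponential)
    sub_resolution: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")


def extract_latencies(
    jump_traces: list[Trace],
    target_force_pn: float,
    direction: str = "unzip",
    min_step_nm: float = 10.0,
    force_tol_pn: float = 0.05,
    condition: str = "",
) -> list[DwellRecord]:
    """Latencies from the end of a force jump to the first detected step.

    The hold at the target force is located from the force channel (first
    frame within ``force_tol_pn`` of the target after a non-target period);
    the settling transient (0.1 s) is excluded.  Traces without a detected
    transition yield censored records spanning the observation window.
    """
    sign = +1.0 if direction == "unzip" else -1.0
    records: list[DwellRecord] = []
    for trace in jump_traces:
        at_target = np.abs(trace.force_pn - target_force_pn) <= force_tol_pn
        if not at_target.any():
            warnings.warn("trace never reaches target force; skipped", stacklevel=2)
            continue
        first = int(np.argmax(at_target))
        if first == 0:
            warnings.warn("trace starts at target force (no jump); skipped", stacklevel=2)
            continue
        t_hold = float(trace.time_s[first])
        t_zero = t_hold + JUMP_SETTLE_S
        window_end = float(trace.time_s[-1])
        events = [
            e
            for e in detect_steps(trace, min_step_nm=min_step_nm)
            if np.sign(e.step_size_nm) == sign
        ]
        if events and events[0].time_s < t_zero:
            # transition during the jump or settling transient
            records.append(
                DwellRecord(
                    state="zippered" if direction == "unzip" else "unzipped",
                    force_pn=target_force_pn,
                    duration_s=1.0 / trace.sampling_rate_hz,
                    censored=False,
                    condition=condition,
                    sub_resolution=True,
                )
            )
            continue
        if not events:
            records.append(
                DwellRecord(
                    state="zippered" if direction == "unzip" else "unzipped",
                    force_pn=target_force_pn,
                    duration_s=window_end - t_zero,
                    censored=True,
                    condition=condition,
                )
            )
            continue
        latency = max(events[0].time_s - t_zero, 1.0 / trace.sampling_rate_hz)
        records.append(
            DwellRecord(
                state="zippered" if direction == "unzip" else "unzipped",
                force_pn=target_force_pn,
                duration_s=float(latency),
                censored=False,
                condition=condition,
            )
        )
    return records


@dataclass(frozen=True)
class ExponentialFit:
    rate_s: float
    mean_s: float
    ci95_rate_s: tuple[float, float]
    n_uncensored: int
    n_censored: int
    total_time_s: float


def fit_exponential_mle(dwells: list[DwellRecord]) -> ExponentialFit:
    """Censored exponential MLE: rate = events / total observed time.

    The 95% CI is from the profile likelihood (chi-square cutoff); with no
    censoring the estimate reduces to 1 / sample mean.  Sub-resolution
    records (transitions before the hold began) are excluded: they are
    left-truncated observations, and by memorylessness the remaining dwells
    are unbiased samples of the hold-force exponential.
    """
    dwells = [r for r in dwells if not r.sub_resolution]
    d = sum(1 for r in dwells if not r.censored)
    if d == 0:
        raise ValueError("rate unidentifiable: all dwells censored")
    total_t = sum(r.duration_s for r in dwells)
    rate = d / total_t

    def profile(k: float) -> float:
        # 2*(logL(rate) - logL(k)) - chi2_{1,0.95}
        return 2.0 * (d * math.log(rate / k) - (rate - k) * total_t) - chi2.ppf(
            0.95, 1
        )

    lo = brentq(profile, rate * 1e-6, rate)
    hi = brentq(profile, rate, rate * 1e6)
    return ExponentialFit(
        rate_s=rate,
        mean_s=1.0 / rate,
        ci95_rate_s=(lo, hi),
        n_uncensored=d,
        n_censored=len(dwells) - d,
        total_time_s=total_t,
    )


@dataclass(frozen=True)
class BellFit:
    """Bell-equation fit  kBT ln(k/k_w) = -dG + F dx.

    ``delta_x_nm`` is the regression slope (signed: negative when force
    opposes the transition); ``delta_g_kbt`` the zero-force barrier height.
    ``cov`` is the 2x2 covariance of (slope nm, intercept pN nm).
    """

    delta_x_nm: float
    delta_g_kbt: float
    cov: np.ndarray = field(repr=False)
    force_range_pn: tuple[float, float]
    attempt_rate_s: float = ATTEMPT_RATE_S

    def rate_at(self, force: float) -> float:
        """Extrapolated Bell rate at ``force``, s^-1."""
        return self.attempt_rate_s * math.exp(
            -self.delta_g_kbt + force * self.delta_x_nm / KBT_PN_NM
        )

    def barrier_at(self, force: float) -> float:
        """Force-tilted barrier height dG - F dx, kBT."""
        return self.delta_g_kbt - force * self.delta_x_nm / KBT_PN_NM


def fit_bell(
    rates: list[tuple],
    attempt_rate_s: float = ATTEMPT_RATE_S,
) -> BellFit:
    """Weighted linear fit of the Bell equation to (force, rate[, CI]) rows.

    Each row is ``(force_pn, rate_s)`` or ``(force_pn, rate_s, (lo, hi))``
    with a 95% CI on the rate; weights are the inverse variances of
    ln(rate) implied by the CIs, or uniform when CIs are absent.
    """
    if len(rates) < 3:
        raise ValueError("need rates at >= 3 forces")
    f = np.array([r[0] for r in rates], dtype=float)
    if np.unique(f).size < 2:
        raise ValueError("rank-deficient design: need >= 2 distinct forces")
    k = np.array([r[1] for r in rates], dtype=float)
    y = KBT_PN_NM * np.log(k / attempt_rate_s)
    w = np.ones_like(y)
    known_var = all(len(r) > 2 and r[2] is not None for r in rates)
    if known_var:
        sd_ln = np.array(
            [(math.log(r[2][1]) - math.log(r[2][0])) / (2 * 1.959964) for r in rates]
        )
        w = 1.0 / (KBT_PN_NM * sd_ln) ** 2
    X = sm.add_constant(f)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = res.params
    if known_var:
        # weights are true inverse variances: use the unscaled (X'WX)^-1
        # rather than the residual-variance estimate (few dof per fit)
        cov = np.asarray(res.normalized_cov_params)
    else:
        cov = np.asarray(res.cov_params())
    cov = cov[::-1, ::-1]  # order (slope, intercept)
    return BellFit(
        delta_x_nm=float(slope),
        delta_g_kbt=float(-intercept / KBT_PN_NM),
        cov=cov,
        force_range_pn=(float(f.min()), float(f.max())),
        attempt_rate_s=attempt_rate_s,
    )


def barrier_at_force(rate_s: float, attempt_rate_s: float = ATTEMPT_RATE_S) -> float:
    """Barrier height (kBT) implied by a first-order rate: ln(k_w / k)."""
    if rate_s <= 0:
        raise ValueError("rate must be > 0")
    if rate_s >= attempt_rate_s:
        raise ValueError("rate at or above the attempt frequency: barrierless")
    return math.log(attempt_rate_s / rate_s)


@dataclass(frozen=True)
class EnergyLandscape:
    """Coarse-grained 1-D landscape at a given force.

    ``points`` is [(position nm, energy kBT)] for zippered well, barrier,
    unzipped well, with the zippered state at (0, 0).
    """

    force_pn: float
    points: tuple[tuple[float, float], ...]

    @property
    def barrier_kbt(self) -> float:
        return self.points[1][1]

    @property
    def unzipped_kbt(self) -> float:
        return self.points[2][1]


def build_landscape(
    unzip_fit: BellFit, rezip_fit: BellFit, force: float
) -> EnergyLandscape:
    """Assemble the landscape at ``force`` from the two Bell fits.

    The barrier sits at the unzipping transition distance; the unzipped
    well at the sum of the unzipping and rezipping distances, at energy
    dG_unzip(F) - dG_rezip(F).
    """
    lo1, hi1 = unzip_fit.force_range_pn
    lo2, hi2 = rezip_fit.force_range_pn
    if min(hi1, hi2) < max(lo1, lo2) - 2.0:
        warnings.warn("unzip and rezip fits cover disjoint force ranges", stacklevel=2)
    x_barrier = abs(unzip_fit.delta_x_nm)
    x_unzipped = x_barrier + abs(rezip_fit.delta_x_nm)
    g_barrier = unzip_fit.barrier_at(force)
    g_unzipped = g_barrier - rezip_fit.barrier_at(force)
    if g_barrier < max(0.0, g_unzipped):
        raise ValueError("inconsistent fits: barrier below a state energy")
    return EnergyLandscape(
        force_pn=force,
        points=((0.0, 0.0), (x_barrier, g_barrier), (x_unzipped, g_unzipped)),
    )
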