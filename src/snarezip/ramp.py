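"""Force-ramp analysis: transition detection, QC signature, normalization.

Steps are detected by a two-sided moving-median comparison: at each frame
boundary the median extension of the trailing window is compared with the
median of the leading window, and boundaries where the difference exceeds
``min_step`` are grouped into events.  The event force is the protocol force
at the detected change-point frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "TransitionEvent",
    "detect_steps",
    "classify_events",
    "qc_signature",
    "QCResult",
    "normalize_to_global",
    "transition_force_histogram",
]

#: Force windows (pN) of the signature events a genuine SNARE construct
#: must display over a stretch-relax cycle.
SIGNATURE_WINDOWS = {
    "unzip": (12.0, 16.0),
    "rezip": (8.0, 12.0),
    "unfold": (15.0, 18.0),
    "refold": (0.0, 2.0),
}

#: Global average unzipping force (pN) that per-bead forces are scaled to.
GLOBAL_MEAN_UNZIP_PN = 14.4


@dataclass(frozen=True)
class TransitionEvent:
    time_s: float
    force_pn: float
    direction: str  # up | down, or unzip/rezip/unfold/refold after classify
    step_size_nm: float  # signed extension change


def default_window(sampling_rate_hz: float) -> int:
    """Detector window in frames: 11 at 100 Hz, 61 at 1.2 kHz."""
    return 61 if sampling_rate_hz >= 600 else 11


def detect_steps(
    trace: Trace,
    min_step_nm: float = 10.0,
    window: int | None = None,
) -> list[TransitionEvent]:
    """Detect abrupt extension steps of at least ``min_step_nm``.

    Returns events sorted by time.  Candidate boundaries closer than one
    window are merged into the single strongest boundary.
    """
    if window is None:
        window = default_window(trace.sampling_rate_hz)
    n = len(trace)
    if n <= 2 * window:
        raise ValueError("trace must be longer than twice the window")
    ext = pd.Series(trace.extension_nm)
    med_trail = ext.rolling(window).median().to_numpy()
    med_lead = ext[::-1].rolling(window).median().to_numpy()[::-1]
    # diff[i]: lead window starting at i vs trail window ending at i-1
    diff = np.full(n, 0.0)
    valid = slice(window, n - window + 1)
    diff[valid] = med_lead[valid] - med_trail[window - 1 : n - window]

    candidates = np.nonzero(np.abs(diff) >= min_step_nm)[0]
    events: list[TransitionEvent] = []
    if candidates.size:
        groups = np.split(candidates, np.nonzero(np.diff(candidates) > window)[0] + 1)
        for grp in groups:
            i = grp[np.argmax(np.abs(diff[grp]))]
            events.append(
                TransitionEvent(
                    time_s=float(trace.time_s[i]),
                    force_pn=float(trace.force_pn[i]),
                    direction="up" if diff[i] > 0 else "down",
                    step_size_nm=float(diff[i]),
                )
            )
    return sorted(events, key=lambda e: e.time_s)


def classify_events(
    events: list[TransitionEvent], large_step_nm: float = 10.0
) -> list[TransitionEvent]:
    """Label detected steps by signature class.

    Large upward steps are SNARE unzipping, small upward steps SNAP-25
    unfolding; the mirror classes apply to downward steps.
    """
    out = []
    for e in events:
        if e.direction not in ("up", "down"):
            out.append(e)
            continue
        big = abs(e.step_size_nm) >= large_step_nm
        if e.direction == "up":
            label = "unzip" if big else "unfold"
        else:
            label = "rezip" if big else "refold"
        out.append(TransitionEvent(e.time_s, e.force_pn, label, e.step_size_nm))
    return out


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...]


def qc_signature(events: list[TransitionEvent]) -> QCResult:
    """Verify the construct's signature events against their force windows.

    Pass iff each class (unzip, rezip, unfold, refold) occurs at least once
    inside its window; any event of a signature class outside its window is
    also a failure.
    """
    reasons: list[str] = []
    by_class: dict[str, list[TransitionEvent]] = {k: [] for k in SIGNATURE_WINDOWS}
    for e in events:
        if e.direction in by_class:
            by_class[e.direction].append(e)
    for cls, (lo, hi) in SIGNATURE_WINDOWS.items():
        evs = by_class[cls]
        if not evs:
            reasons.append(f"missing {cls} event")
            continue
        for e in evs:
            if not lo <= e.force_pn <= hi:
                reasons.append(
                    f"{cls} at {e.force_pn:.1f} pN outside {lo:g}-{hi:g}"
                )
    return QCResult(passed=not reasons, reasons=tuple(reasons))


def normalize_to_global(
    per_bead_unzip_forces: dict[str, np.ndarray],
    global_mean_pn: float = GLOBAL_MEAN_UNZIP_PN,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """Rescale per-bead unzipping forces to a common global mean.

    Each bead's scale factor is ``global_mean / mean(bead forces)``; after
    rescaling every bead's mean (and hence the pooled mean) equals
    ``global_mean_pn`` exactly.  Beads without events are excluded with a
    warning.  Idempotent.
    """
    scales: dict[str, float] = {}
    rescaled: dict[str, np.ndarray] = {}
    for bead, forces in per_bead_unzip_forces.items():
        forces = np.asarray(forces, dtype=float)
        if forces.size == 0:
            warnings.warn(f"bead {bead!r} has no unzip events; excluded", stacklevel=2)
            continue
        if forces.size < 3:
            warnings.warn(
                f"bead {bead!r} has fewer than 3 unzip events; scale is noisy",
                stacklevel=2,
            )
        scale = global_mean_pn / forces.mean()
        scales[bead] = scale
        rescaled[bead] = forces * scale
    return scales, rescaled


def transition_force_histogram(
    forces: np.ndarray | list[float] | list[TransitionEvent],
    bin_width_pn: float = 0.5,
) -> dict:
    """Histogram + summary of transition forces (summary from unbinned data)."""
    if len(forces) and isinstance(forces[0], TransitionEvent):
        forces = [e.force_pn for e in forces]
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        raise ValueError("need at least one event")
    lo = np.floor(forces.min() / bin_width_pn) * bin_width_pn
    hi = np.ceil(forces.max() / bin_width_pn) * bin_width_pn + bin_width_pn
    edges = np.arange(lo, hi + 0.5 * bin_width_pn, bin_width_pn)
    counts, edges = np.histogram(forces, bins=edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "mean_pn": float(forces.mean()),
        "sd_pn": float(forces.std(ddof=1)) if forces.size > 1 else None,
        "n": int(forces.size),
    }
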