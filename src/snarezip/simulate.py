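"""Kinetic Monte-Carlo simulation of bead traces.

State paths are generated by exact exponential waiting times during
constant-force holds and by time-discretized thinning (1 ms steps) during
ramps.  The observed extension is the construct-model extension of the
current state at the instantaneous force plus camera-frame Gaussian noise
(optionally Ornstein–Uhlenbeck correlated, emulating bead relaxation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KBT_PN_NM
from .kinetics import KineticScheme
from .polymer import ConstructSpec, invert_wlc, state_extension
from .trace import Trace

__all__ = ["ProtocolSegment", "ForceProtocol", "NoiseModel", "simulate"]

RAMP_STEP_S = 1e-3  # thinning step during ramps; accuracy/speed trade-off


@dataclass(frozen=True)
class ProtocolSegment:
    mode: str  # "hold" | "ramp"
    start_force_pn: float
    rate_pn_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.mode not in ("hold", "ramp"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.duration_s < 0:
            raise ValueError("segment duration must be >= 0")

    def force_at(self, t: float | np.ndarray) -> float | np.ndarray:
        if self.mode == "hold":
            return self.start_force_pn + 0.0 * np.asarray(t)
        return self.start_force_pn + self.rate_pn_s * np.asarray(t)

    @property
    def end_force_pn(self) -> float:
        return float(self.force_at(self.duration_s))


@dataclass
class ForceProtocol:
    """Ordered hold/ramp segments; forces must stay within [0, 20] pN."""

    segments: list[ProtocolSegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol must contain at least one segment")
        for seg in self.segments:
            for f in (seg.start_force_pn, seg.end_force_pn):
                if not 0.0 <= f <= 20.0:
                    raise ValueError(f"protocol force {f:.2f} pN outside [0, 20]")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def force_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        t0 = 0.0
        last = self.segments[-1]
        for seg in self.segments:
            sel = (t >= t0) & (t < t0 + seg.duration_s)
            out[sel] = seg.force_at(t[sel] - t0)
            t0 += seg.duration_s
        out[t >= t0 - 1e-12] = last.force_at(last.duration_s)
        return out

    # -- convenience builders ---------------------------------------------
    @classmethod
    def hold(cls, force: float, duration: float) -> "ForceProtocol":
        return cls([ProtocolSegment("hold", force, 0.0, duration)])

    @classmethod
    def jump(
        cls,
        f_start: float,
        f_target: float,
        hold_before_s: float,
        hold_after_s: float,
        slew_pn_s: float = 80.0,
    ) -> "ForceProtocol":
        """Force-jump protocol: hold, fast ramp (>=50 pN/s), hold at target."""
        if slew_pn_s < 50.0:
            raise ValueError("jump slew rate must be >= 50 pN/s")
        ramp_t = abs(f_target - f_start) / slew_pn_s
        if ramp_t > 0.1:
            raise ValueError("jump must reach target within 0.1 s")
        rate = math.copysign(slew_pn_s, f_target - f_start)
        return cls(
            [
                ProtocolSegment("hold", f_start, 0.0, hold_before_s),
                ProtocolSegment("ramp", f_start, rate, ramp_t),
                ProtocolSegment("hold", f_target, 0.0, hold_after_s),
            ]
        )

    @classmethod
    def ramp_cycle(
        cls, f_min: float, f_max: float, rate_pn_s: float = 1.0
    ) -> "ForceProtocol":
        """Symmetric stretch-relax cycle at +/- ``rate_pn_s``."""
        t_up = (f_max - f_min) / rate_pn_s
        return cls(
            [
                ProtocolSegment("ramp", f_min, rate_pn_s, t_up),
                ProtocolSegment("ramp", f_max, -rate_pn_s, t_up),
            ]
        )


@dataclass(frozen=True)
class NoiseModel:
    """Per-frame Gaussian measurement noise, optionally OU-correlated."""

    sigma_nm: float
    correlation_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_nm < 0:
            raise ValueError("sigma must be >= 0")

    def sample(self, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_nm == 0.0 or n == 0:
            return np.zeros(n)
        white = rng.standard_normal(n)
        if not self.correlation_time_s:
            return self.sigma_nm * white
        from scipy.signal import lfilter

        a = math.exp(-dt / self.correlation_time_s)
        innov = self.sigma_nm * math.sqrt(1.0 - a * a) * white
        innov[0] = self.sigma_nm * white[0]
        return lfilter([1.0], [1.0, -a], innov)


# per-spec cache of state-extension lookup grids
_GRID_F = np.linspace(0.0, 20.0, 2001)


def _extension_grid(spec: ConstructSpec, state: str) -> np.ndarray:
    cache = spec.__dict__.setdefault("_ext_grid_cache", {})
    if state not in cache:
        handle = spec.handle_segment()
        st = spec.state(state)
        coil = spec.coil_segment(st.unfolded_residues) if st.unfolded_residues else None
        vals = np.empty_like(_GRID_F)
        for i, f in enumerate(_GRID_F):
            x = invert_wlc(f, handle) + st.folded_axial_nm
            if coil is not None:
                x += invert_wlc(f, coil)
            vals[i] = x
        cache[state] = vals
    return cache[state]


def _gen_path(
    scheme: KineticScheme,
    protocol: ForceProtocol,
    initial_state: str,
    rng: np.random.Generator,
) -> list[tuple[float, str, str]]:
    """Transition events (time, from, to) over one protocol execution."""
    events: list[tuple[float, str, str]] = []
    state = initial_state
    t0 = 0.0
    for seg in protocol.segments:
        t_in = 0.0  # time within segment
        while t_in < seg.duration_s:
            if seg.mode == "hold":
                force = seg.start_force_pn
                rates = scheme.out_rates(state, force)
                total = sum(rates.values())
                if total == 0.0:
                    break
                wait = rng.exponential(1.0 / total)
                if t_in + wait >= seg.duration_s:
                    break
                t_in += wait
            else:  # ramp: thinning on a 1 ms grid, vectorized over steps
                n_steps = max(1, int(math.ceil((seg.duration_s - t_in) / RAMP_STEP_S)))
                edges_t = t_in + RAMP_STEP_S * np.arange(n_steps + 1)
                edges_t[-1] = seg.duration_s
                mid_f = np.asarray(seg.force_at(0.5 * (edges_t[:-1] + edges_t[1:])))
                dts = np.diff(edges_t)
                total_k = np.zeros(n_steps)
                for (s, dst), bell in scheme.edges.items():
                    if s != state:
                        continue
                    lo, hi = scheme.gates.get((s, dst), (0.0, math.inf))
                    active = (mid_f >= lo) & (mid_f <= hi)
                    total_k += active * bell.k_ref_s * np.exp(
                        (mid_f - bell.f_ref_pn) * bell.delta_x_nm / KBT_PN_NM
                    )
                haz = np.cumsum(total_k * dts)
                u = rng.random()
                idx = int(np.searchsorted(haz, -math.log(u)))
                if idx >= n_steps:
                    break
                t_in = float(edges_t[idx] + 0.5 * dts[idx])
                force = float(seg.force_at(t_in))
                rates = scheme.out_rates(state, force)
                total = sum(rates.values())
                if total == 0.0:
                    break
            # choose destination proportionally to instantaneous rates
            dsts = list(rates)
            probs = np.array([rates[d] for d in dsts]) / total
            dst = dsts[rng.choice(len(dsts), p=probs)]
            events.append((t0 + t_in, state, dst))
            state = dst
        t0 += seg.duration_s
    return events


def simulate(
    scheme: KineticScheme,
    protocol: ForceProtocol,
    spec: ConstructSpec,
    noise: NoiseModel,
    sampling_rate_hz: float,
    seed: int,
    initial_state: str | None = None,
    stop_after_first_transition_s: float | None = None,
    state_levels_nm: dict[str, float] | None = None,
) -> Trace:
    """Simulate one bead trace under ``protocol``.

    Identical seeds give identical traces.  If
    ``stop_after_first_transition_s`` is set, the trace is truncated that
    many seconds after the first transition (serial-measurement protocols
    move on once the event of interest has occurred).  ``state_levels_nm``
    optionally overrides the construct-model state extensions with fixed
    offsets (nm) added to the fully zippered baseline — used to emulate
    measured peak positions instead of the model's calculated ones.
    """
    rng = np.random.default_rng(seed)
    state0 = initial_state if initial_state is not None else scheme.states[0]
    if state0 not in scheme.states:
        raise ValueError(f"unknown initial state {state0!r}")

    events = _gen_path(scheme, protocol, state0, rng)

    if events:
        dwells = np.diff([e[0] for e in events])
        if dwells.size and dwells.min() < 0.1 / sampling_rate_hz:
            warnings.warn(
                "dwells shorter than a tenth of a frame occurred; "
                "missed-event regime (exit rates exceed 10x the sampling rate)",
                stacklevel=2,
            )

    t_end = protocol.duration_s
    if stop_after_first_transition_s is not None and events:
        t_end = min(t_end, events[0][0] + stop_after_first_transition_s)
        events = [e for e in events if e[0] <= t_end]

    n = max(1, int(math.floor(t_end * sampling_rate_hz)))
    time = np.arange(n) / sampling_rate_hz
    force = protocol.force_at(time)

    ev_times = np.array([e[0] for e in events])
    state_names = [state0] + [e[2] for e in events]
    idx = np.searchsorted(ev_times, time, side="right")
    states = np.array(state_names, dtype=object)[idx]

    ext = np.empty(n)
    base_grid = _extension_grid(spec, "FULLY_ZIPPERED")
    for name in set(state_names):
        sel = states == name
        if state_levels_nm is not None:
            ext[sel] = np.interp(force[sel], _GRID_F, base_grid) + state_levels_nm[name]
        else:
            ext[sel] = np.interp(force[sel], _GRID_F, _extension_grid(spec, name))
    ext += noise.sample(n, 1.0 / sampling_rate_hz, rng)

    return Trace(
        time_s=time,
        force_pn=force,
        extension_nm=ext,
        sampling_rate_hz=sampling_rate_hz,
        state=states.astype(str),
        events=events,
        meta={"seed": seed, "initial_state": state0},
    )
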