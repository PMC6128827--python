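"""The Trace container: sampled (time, force, extension) series.

Traces are the universal currency of the pipeline — produced by the
simulator, written/read as tab-separated text with a JSON metadata sidecar,
and consumed by every analysis stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trace", "read_trace", "write_trace"]


@dataclass
class Trace:
    """Sampled bead trajectory.

    ``state`` is the per-frame conformational state (string labels), present
    for simulated traces; ``events`` records true transition times for
    simulated data (time_s, from_state, to_state).
    """

    time_s: np.ndarray
    force_pn: np.ndarray
    extension_nm: np.ndarray
    sampling_rate_hz: float
    state: np.ndarray | None = None
    events: list[tuple[float, str, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if len(self.force_pn) != n or len(self.extension_nm) != n:
            raise ValueError("trace arrays must have equal length")
        if self.state is not None and len(self.state) != n:
            raise ValueError("state column length mismatch")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz


def write_trace(path: str | Path, trace: Trace) -> None:
    """Write a trace as TSV plus a ``.meta.json`` sidecar."""
    path = Path(path)
    cols = ["time_s", "force_pN", "extension_nm"]
    data = [trace.time_s, trace.force_pn, trace.extension_nm]
    fmt = ["%.9g", "%.9g", "%.9g"]
    if trace.state is not None:
        cols.append("state")
        data.append(trace.state)
        fmt.append("%s")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        rows = zip(*[np.asarray(c) for c in data])
        for row in rows:
            fh.write(
                "\t".join(
                    f % v for f, v in zip(fmt, row)
                )
                + "\n"
            )
    meta = dict(trace.meta)
    meta["sampling_rate_hz"] = trace.sampling_rate_hz
    if trace.events:
        meta["events"] = [[t, a, b] for t, a, b in trace.events]
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1) + "\n"
    )


def read_trace(path: str | Path) -> Trace:
    """Read a TSV trace, validating the header and time monotonicity."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    required = ["time_s", "force_pN", "extension_nm"]
    if header[: len(required)] != required:
        raise ValueError(f"{path}: malformed header {header!r}")
    has_state = "state" in header
    usecols = (0, 1, 2)
    arr = np.loadtxt(path, skiprows=1, usecols=usecols, ndmin=2)
    state = None
    if has_state:
        state = np.loadtxt(
            path, skiprows=1, usecols=(header.index("state"),), dtype=str, ndmin=1
        )
    t = arr[:, 0]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-monotonic time at line {bad[0] + 3}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    events: list[tuple[float, str, str]] = []
    rate = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rate = meta.pop("sampling_rate_hz", None)
        events = [tuple(e) for e in meta.pop("events", [])]
    if rate is None:
        dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
        rate = 1.0 / dt
    return Trace(
        time_s=t,
        force_pn=arr[:, 1],
        extension_nm=arr[:, 2],
        sampling_rate_hz=float(rate),
        state=state,
        events=events,
        meta=meta,
    )
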