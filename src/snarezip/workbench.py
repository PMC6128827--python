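"""Experiment orchestration: seeded fixture trees and summary reports.

``make_fixtures`` writes a deterministic tree of simulated experiments —
force-ramp cycles, force-jump dwell sets, and 0.2 pN equilibrium scans per
condition — and ``report`` assembles the per-stage outputs found in an
experiment directory into one machine-readable summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from .conditions import CONDITIONS, MEASURED_LEVELS_NM, rupture_scheme, zipper_scheme
from .polymer import ConstructSpec
from .simulate import ForceProtocol, NoiseModel, ProtocolSegment, simulate
from .trace import write_trace

__all__ = ["ExperimentConfig", "make_fixtures", "report"]

log = logging.getLogger("snarezip")

#: Default per-frame noise, nm: resolvable intermediates at 1.2 kHz, merged
#: (relative to the 13 nm spacing) at 100 Hz tracking.
SIGMA_1200HZ_NM = 2.5
SIGMA_100HZ_NM = 1.0


class ExperimentConfig(BaseModel):
    """Declarative description of one simulated experiment set."""

    conditions: list[str] = Field(default_factory=lambda: ["none", "WT"])
    seed: int = 1
    ramp_cycles: int = 3
    jump_forces_pn: list[float] = Field(default_factory=lambda: [14.0, 14.4, 14.8])
    dwells_per_force: int = 5
    scan_forces_pn: list[float] = Field(
        default_factory=lambda: [round(f, 1) for f in np.arange(13.0, 15.01, 0.5)]
    )
    scan_seconds: float = 2.0
    jump_window_s: float = 60.0

    @classmethod
    def smoke(cls, seed: int = 1) -> "ExperimentConfig":
        """Small deterministic tree, completes well under a minute."""
        return cls(seed=seed)

    @classmethod
    def study(cls, seed: int = 1) -> "ExperimentConfig":
        """Study-scale tree: >= 19 dwells per force, > 15 s per grid force."""
        return cls(
            seed=seed,
            ramp_cycles=10,
            dwells_per_force=19,
            scan_seconds=16.0,
            scan_forces_pn=[round(f, 1) for f in np.arange(12.0, 16.01, 0.2)],
            jump_window_s=120.0,
        )


def make_fixtures(
    config: ExperimentConfig, out_dir: str | Path, force: bool = False
) -> Path:
    """Write the simulated experiment tree; byte-identical for equal seeds."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    spec = ConstructSpec()
    rng = np.random.default_rng(config.seed)
    for label in config.conditions:
        condition = CONDITIONS[label]
        base = out / label
        log.info("generating condition %s", label)

        ramp_dir = base / "ramp"
        ramp_dir.mkdir(parents=True, exist_ok=True)
        for i in range(config.ramp_cycles):
            # alternate low-peak cycles (unzip/rezip signatures) with
            # high-peak cycles (SNAP-25 unfold, then refold near 0 force)
            if i % 2 == 0:
                protocol = ForceProtocol.ramp_cycle(1.0, 14.5)
            else:
                protocol = ForceProtocol(
                    ForceProtocol.ramp_cycle(0.5, 17.0).segments
                    + [ProtocolSegment("hold", 0.5, 0.0, 4.0)]
                )
            seed = int(rng.integers(2**31))
            trace = simulate(
                rupture_scheme(condition),
                protocol,
                spec,
                NoiseModel(SIGMA_100HZ_NM),
                sampling_rate_hz=100.0,
                seed=seed,
            )
            trace.meta.update(condition=label, protocol="ramp_cycle")
            write_trace(ramp_dir / f"cycle_{i:03d}.tsv", trace)

        jump_dir = base / "jump"
        jump_dir.mkdir(parents=True, exist_ok=True)
        for f_target in config.jump_forces_pn:
            protocol = ForceProtocol.jump(10.0, f_target, 1.0, config.jump_window_s)
            for i in range(config.dwells_per_force):
                seed = int(rng.integers(2**31))
                trace = simulate(
                    rupture_scheme(condition, include_snap25=False),
                    protocol,
                    spec,
                    NoiseModel(SIGMA_100HZ_NM),
                    sampling_rate_hz=100.0,
                    seed=seed,
                    stop_after_first_transition_s=2.0,
                )
                trace.meta.update(
                    condition=label, protocol="jump", target_force_pn=f_target
                )
                write_trace(jump_dir / f"jump_{f_target:.1f}pN_{i:03d}.tsv", trace)

        scan_dir = base / "scan"
        scan_dir.mkdir(parents=True, exist_ok=True)
        for f_hold in config.scan_forces_pn:
            seed = int(rng.integers(2**31))
            trace = simulate(
                zipper_scheme(condition),
                ForceProtocol.hold(f_hold, config.scan_seconds),
                spec,
                NoiseModel(SIGMA_1200HZ_NM),
                sampling_rate_hz=1200.0,
                seed=seed,
                state_levels_nm=MEASURED_LEVELS_NM,
            )
            trace.meta.update(condition=label, protocol="scan", force_pn=f_hold)
            write_trace(scan_dir / f"scan_{f_hold:.1f}pN.tsv", trace)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "conditions": config.conditions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out


STAGE_FILES = {
    "ramp_events": "ramp_events.tsv",
    "dwell_fits": "dwell_fits.json",
    "bell_fits": "bell_fits.json",
    "populations": "populations.tsv",
    "hmm_rates": "hmm_rates.tsv",
}


def report(experiment_dir: str | Path) -> dict:
    """Assemble per-stage outputs under ``experiment_dir`` into a summary.

    Missing stage outputs are reported as explicit gaps rather than errors.
    """
    exp = Path(experiment_dir)
    summary: dict = {"experiment": str(exp), "stages": {}, "gaps": []}
    manifest = exp / "manifest.json"
    if manifest.exists():
        summary["manifest"] = json.loads(manifest.read_text())
    for cond_dir in sorted(d for d in exp.iterdir() if d.is_dir()):
        stages = {}
        for stage, fname in STAGE_FILES.items():
            path = cond_dir / fname
            if not path.exists():
                summary["gaps"].append(f"{cond_dir.name}: missing {stage}")
                continue
            if fname.endswith(".json"):
                stages[stage] = json.loads(path.read_text())
            else:
                stages[stage] = {"path": str(path), "rows": _count_rows(path)}
        summary["stages"][cond_dir.name] = stages
    return summary


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)
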