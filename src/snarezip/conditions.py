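"""Named experimental conditions and their pinned kinetic parameter sets.

The complexin (Cpx) truncation series is encoded as per-condition free
energies of the three zippered conformations (fully zippered, linker-open,
half-zippered) quoted at the 14 pN working force, plus the height of the
main unzipping barrier.  The pinned values encode the measured phenomenology:

* ``none``  — populations ~0.55/0.20/0.25 at 14 pN, unzipping barrier 15 kBT.
* ``WT``    — full-length Cpx: zippered state stabilized by 4.3 kBT (barrier
  19.3 kBT), half-zippered state nearly abolished, linker-open state
  promoted more than three-fold at 14 pN.
* ``NAC``   — N-terminal + accessory + central helices: indistinguishable
  from WT (the C-terminal domain has no effect in this assay).
* ``AC``    — accessory + central helices: stabilization without linker
  clamping; linker-open population drops below the no-Cpx level.
* ``C``     — central helix only: partial suppression of the half-zippered
  state, no linker-open promotion.

The unzipped state is unaffected by Cpx in every condition (barrier and
unzipped-state energy shift together, leaving rezipping rates unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinetics import BellParameters, KineticScheme, scheme_from_landscape

__all__ = [
    "Condition",
    "CONDITIONS",
    "MEASURED_LEVELS_NM",
    "ZIPPER_STATES",
    "zipper_scheme",
    "rupture_scheme",
]

#: Measured extension offsets of the zippered intermediates relative to the
#: fully zippered state (Gaussian peak positions at 14 pN), nm.
MEASURED_LEVELS_NM = {
    "FULLY_ZIPPERED": 0.0,
    "LINKER_OPEN": 5.3,
    "HALF_ZIPPERED": 13.0,
    "UNZIPPED": 28.5,
}

ZIPPER_STATES = ("FULLY_ZIPPERED", "LINKER_OPEN", "HALF_ZIPPERED")

# transition-state positions along the extension coordinate, nm
_X_BARRIER_FZ_LO = 2.6
_X_BARRIER_LO_HZ = 9.0
# barrier heights at 14 pN relative to the fully zippered state, kBT
_B_FZ_LO = 9.7
_B_LO_HZ = 11.4

# main rupture transition (zippered collection <-> unzipped)
_X_UNZIP_BARRIER = 7.0  # nm from the zippered well
_X_UNZIPPED = 25.0  # nm from the zippered well
_G_REZIP_BARRIER = 31.5  # kBT above the unzipped state at 14 pN (Cpx-blind)

# SNAP-25 dissociation / rebinding
_SNAP25_OFF_BELL = BellParameters(k_ref_s=0.5, f_ref_pn=16.5, delta_x_nm=2.0)
_SNAP25_REBIND_BELL = BellParameters(k_ref_s=1.0, f_ref_pn=0.0, delta_x_nm=0.0)
_SNAP25_REBIND_MAX_FORCE = 2.0  # pN; refolding only below this force


@dataclass(frozen=True)
class Condition:
    """One Cpx condition with its pinned kinetic parameters (14 pN basis)."""

    label: str
    cpx_um: float
    g_linker_open_kbt: float
    g_half_zippered_kbt: float
    unzip_barrier_kbt: float
    kinetic_overrides: dict = field(default_factory=dict)


CONDITIONS: dict[str, Condition] = {
    "none": Condition("none", 0.0, 1.0, 0.8, 15.0),
    "WT": Condition("WT", 5.0, -0.9, 3.7, 19.3),
    "NAC": Condition("NAC", 5.0, -0.9, 3.7, 19.3),
    "AC": Condition("AC", 5.0, 1.9, 3.7, 19.3),
    "C": Condition("C", 5.0, 1.4, 2.2, 18.5),
}


def zipper_scheme(condition: Condition | str = "none") -> KineticScheme:
    """Three-state exchange among the zippered conformations (12-16 pN)."""
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    energies = {
        "FULLY_ZIPPERED": (0.0, MEASURED_LEVELS_NM["FULLY_ZIPPERED"]),
        "LINKER_OPEN": (
            condition.g_linker_open_kbt,
            MEASURED_LEVELS_NM["LINKER_OPEN"],
        ),
        "HALF_ZIPPERED": (
            condition.g_half_zippered_kbt,
            MEASURED_LEVELS_NM["HALF_ZIPPERED"],
        ),
    }
    barriers = {
        ("FULLY_ZIPPERED", "LINKER_OPEN"): (_X_BARRIER_FZ_LO, _B_FZ_LO),
        ("LINKER_OPEN", "HALF_ZIPPERED"): (_X_BARRIER_LO_HZ, _B_LO_HZ),
    }
    return scheme_from_landscape(energies, barriers, reference_force_pn=14.0)


def rupture_scheme(
    condition: Condition | str = "none", include_snap25: bool = True
) -> KineticScheme:
    """Coarse two-state rupture scheme (zippered collection <-> unzipped).

    The unzipping barrier height is condition-dependent; the rezipping
    barrier measured from the unzipped state is not (Cpx leaves the unzipped
    state and the rezipping kinetics untouched).  Optionally extended with
    SNAP-25 dissociation above ~15 pN and rebinding below 2 pN.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    b = condition.unzip_barrier_kbt
    energies = {
        "FULLY_ZIPPERED": (0.0, 0.0),
        "UNZIPPED": (b - _G_REZIP_BARRIER, _X_UNZIPPED),
    }
    barriers = {("FULLY_ZIPPERED", "UNZIPPED"): (_X_UNZIP_BARRIER, b)}
    scheme = scheme_from_landscape(energies, barriers, reference_force_pn=14.0)
    if include_snap25:
        scheme.states.append("SNAP25_OFF")
        scheme.edges[("UNZIPPED", "SNAP25_OFF")] = _SNAP25_OFF_BELL
        scheme.edges[("SNAP25_OFF", "UNZIPPED")] = _SNAP25_REBIND_BELL
        scheme.gates[("SNAP25_OFF", "UNZIPPED")] = (0.0, _SNAP25_REBIND_MAX_FORCE)
    return scheme
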