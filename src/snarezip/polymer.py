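"""Extension model for the DNA–SNARE pulling construct.

The tethered construct is two 510-bp dsDNA handles in series with a single
SNARE four-helix bundle (syntaxin-1A, SNAP-25b, synaptobrevin-2) whose
N-termini are disulfide-crosslinked and whose C-termini carry the handles.
Each conformational state of the complex leaves a defined number of residues
as random coil in the tether path; the remaining folded structure contributes
a fixed axial length.  The end-to-end extension at force F is

    x(F) = x_dsDNA(F; 1020 bp) + x_coil(F; n_unfolded residues) + d_folded

with both polymer terms given by the Marko–Siggia worm-like-chain
interpolation (plus an enthalpic stretch term for dsDNA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import KBT_PN_NM

__all__ = [
    "PolymerSegment",
    "ConformationState",
    "ConstructSpec",
    "STATE_ORDER",
    "invert_wlc",
    "wlc_force",
    "state_extension",
    "state_delta",
    "layer_span_residues",
]

#: Canonical ordering of the conformational states by degree of unfolding.
STATE_ORDER = (
    "FULLY_ZIPPERED",
    "LINKER_OPEN",
    "HALF_ZIPPERED",
    "UNZIPPED",
    "SNAP25_OFF",
)


@dataclass(frozen=True)
class PolymerSegment:
    """One serial element of the tether.

    kind
        ``dsDNA-WLC`` (extensible WLC), ``polypeptide-WLC`` (inextensible
        WLC) or ``folded-axial`` (force-independent rigid length).
    size
        Base pairs, residues, or nm for ``folded-axial``.
    """

    kind: str
    size: float
    persistence_length_nm: float = 0.0
    contour_per_unit_nm: float = 0.0
    stretch_modulus_pn: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("dsDNA-WLC", "polypeptide-WLC", "folded-axial"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "folded-axial":
            if self.size < 0:
                raise ValueError("folded-axial length must be >= 0")
        else:
            if self.persistence_length_nm <= 0:
                raise ValueError("persistence length must be > 0")
            if self.contour_per_unit_nm <= 0:
                raise ValueError("contour per unit must be > 0")

    @property
    def contour_length_nm(self) -> float:
        if self.kind == "folded-axial":
            return self.size
        return self.size * self.contour_per_unit_nm


def _marko_siggia_force(rel_ext: float, persistence_nm: float) -> float:
    """Entropic WLC force at relative extension ``rel_ext`` in [0, 1)."""
    return (KBT_PN_NM / persistence_nm) * (
        0.25 / (1.0 - rel_ext) ** 2 - 0.25 + rel_ext
    )


def invert_wlc(force: float, segment: PolymerSegment) -> float:
    """Extension (nm) of ``segment`` at ``force`` (pN).

    Solves the Marko–Siggia interpolation by bracketed root finding; for
    dsDNA the relative extension is augmented by the enthalpic term F/K.
    Strictly increasing in force; 0 at zero force.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    if segment.kind == "folded-axial":
        return segment.size
    if force == 0.0:
        return 0.0
    p = segment.persistence_length_nm
    f = float(force)
    # rel extension solving MS(l) = F, bracketed in [0, 1)
    lo, hi = 0.0, 1.0 - 1e-12
    if _marko_siggia_force(hi, p) < f:  # pragma: no cover - unreachable at lab forces
        raise ValueError("force beyond numerical WLC range")
    rel = brentq(lambda l: _marko_siggia_force(l, p) - f, lo, hi, xtol=1e-12)
    if segment.kind == "dsDNA-WLC" and segment.stretch_modulus_pn:
        rel = rel + f / segment.stretch_modulus_pn
    return rel * segment.contour_length_nm


def wlc_force(extension: float, segment: PolymerSegment) -> float:
    """Force (pN) at which ``segment`` has the given extension (nm).

    Inverse of :func:`invert_wlc`; solved by bracketed root finding on the
    force axis so that the enthalpic dsDNA term is handled implicitly.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if extension == 0.0:
        return 0.0
    return brentq(
        lambda f: invert_wlc(f, segment) - extension, 1e-9, 1e3, xtol=1e-12
    )


@dataclass(frozen=True)
class ConformationState:
    """A named conformation of the SNARE complex in the tether.

    unfolded_residues
        Residues in the tether path (synaptobrevin + syntaxin between the
        N-terminal crosslink and the C-terminal handle attachments) that are
        random coil in this state.
    folded_axial_nm
        Axial projection of the remaining folded structure, nm.
    """

    name: str
    unfolded_residues: int
    folded_axial_nm: float

    def __post_init__(self) -> None:
        if self.name not in STATE_ORDER:
            raise ValueError(f"unknown state {self.name!r}")
        if self.unfolded_residues < 0:
            raise ValueError("unfolded_residues must be >= 0")


def default_layer_map() -> pd.DataFrame:
    """Leucine-zipper layer → residue table for the four SNARE helices.

    Layers -7…+8 spaced ~3.5 residues apart around the zero (ionic) layer
    (synaptobrevin R56, syntaxin Q226, SNAP-25 Q53/Q174).  Shipped as a
    3-column table so it can be edited without touching code.
    """
    path = resources.files("snarezip.data") / "layer_map.tsv"
    return pd.read_csv(path, sep="\t")


def _load_construct_config() -> dict:
    path = resources.files("snarezip.data") / "construct.json"
    return json.loads(path.read_text())


@dataclass
class ConstructSpec:
    """Geometry and polymer parameters of the pulling construct."""

    handle_bp: int = 510
    n_handles: int = 2
    chains: dict = field(
        default_factory=lambda: {
            "syx": (191, 268),
            "snap25": (2, 206),
            "syb": (2, 97),
        }
    )
    handle_attachment: dict = field(
        default_factory=lambda: {"syx": 266, "syb": 97}
    )
    crosslink: dict = field(default_factory=lambda: {"syx": 202, "syb": 32})
    layer_map: pd.DataFrame = field(default_factory=default_layer_map)
    # polymer parameters
    dsdna_persistence_nm: float = 45.0
    dsdna_contour_per_bp_nm: float = 0.338
    dsdna_stretch_modulus_pn: float = 1200.0
    peptide_persistence_nm: float = 0.6
    peptide_contour_per_res_nm: float = 0.365
    helix_rise_per_res_nm: float = 0.15
    #: Calibrated axial lengths of the folded remainder, per state (nm).
    folded_axial_nm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.folded_axial_nm:
            self.folded_axial_nm = _load_construct_config()["folded_axial_nm"]
        for chain, res in self.handle_attachment.items():
            lo, hi = self.chains[chain]
            if not lo <= res <= hi:
                raise ValueError(f"attachment {chain}:{res} outside chain range")
        for chain, res in self.crosslink.items():
            lo, hi = self.chains[chain]
            if not lo <= res <= hi:
                raise ValueError(f"crosslink {chain}:{res} outside chain range")
        for chain, grp in self.layer_map.groupby("chain"):
            grp = grp.sort_values("layer")
            if not grp["residue"].is_monotonic_increasing:
                raise ValueError(f"layer map not monotonic for chain {chain}")

    # -- segment builders -------------------------------------------------
    def handle_segment(self) -> PolymerSegment:
        """Both dsDNA handles, treated as one serial WLC."""
        return PolymerSegment(
            kind="dsDNA-WLC",
            size=self.handle_bp * self.n_handles,
            persistence_length_nm=self.dsdna_persistence_nm,
            contour_per_unit_nm=self.dsdna_contour_per_bp_nm,
            stretch_modulus_pn=self.dsdna_stretch_modulus_pn,
        )

    def coil_segment(self, n_residues: int) -> PolymerSegment:
        return PolymerSegment(
            kind="polypeptide-WLC",
            size=n_residues,
            persistence_length_nm=self.peptide_persistence_nm,
            contour_per_unit_nm=self.peptide_contour_per_res_nm,
        )

    def layer_residue(self, chain: str, layer: int) -> int:
        rows = self.layer_map[
            (self.layer_map["chain"] == chain) & (self.layer_map["layer"] == layer)
        ]
        if rows.empty:
            raise KeyError(f"layer {layer} not in map for chain {chain}")
        return int(rows["residue"].iloc[0])

    # -- state definitions -------------------------------------------------
    def unfolded_residue_count(self, state_name: str) -> int:
        """Residues of the tether path that are coil in ``state_name``.

        Counts residues strictly between the last folded residue and the
        handle attachment (C-terminal side) or the N-terminal crosslink.
        """
        syb_lo = self.crosslink["syb"]
        syb_hi = self.handle_attachment["syb"]
        syx_lo = self.crosslink["syx"]
        syx_hi = self.handle_attachment["syx"]
        linker_start = {  # first residue of the C-terminal linker domain
            "syb": self.layer_residue("syb", 8) + 1,
            "syx": self.layer_residue("syx", 8) + 2,
        }
        if state_name == "FULLY_ZIPPERED":
            return 0
        if state_name == "LINKER_OPEN":
            return (syb_hi - linker_start["syb"]) + (syx_hi - linker_start["syx"])
        if state_name == "HALF_ZIPPERED":
            return (syb_hi - 1 - self.layer_residue("syb", 2)) + (
                syx_hi - 1 - self.layer_residue("syx", 4)
            )
        if state_name == "UNZIPPED":
            return (syb_hi - 1 - syb_lo) + (syx_hi - 1 - self.layer_residue("syx", 0))
        if state_name == "SNAP25_OFF":
            return (syb_hi - 1 - syb_lo) + (syx_hi - 1 - syx_lo)
        raise ValueError(f"unknown state {state_name!r}")

    def state(self, name: str) -> ConformationState:
        return ConformationState(
            name=name,
            unfolded_residues=self.unfolded_residue_count(name),
            folded_axial_nm=self.folded_axial_nm[name],
        )

    def states(self) -> dict[str, ConformationState]:
        return {name: self.state(name) for name in STATE_ORDER}


def state_extension(
    force: float, state: ConformationState | str, spec: ConstructSpec
) -> float:
    """Total construct extension (nm) at ``force`` for one conformation."""
    if isinstance(state, str):
        state = spec.state(state)
    x = invert_wlc(force, spec.handle_segment())
    if state.unfolded_residues:
        x += invert_wlc(force, spec.coil_segment(state.unfolded_residues))
    return x + state.folded_axial_nm


def state_delta(
    force: float, state: ConformationState | str, spec: ConstructSpec
) -> float:
    """Extension relative to the fully zippered state at the same force."""
    return state_extension(force, state, spec) - state_extension(
        force, "FULLY_ZIPPERED", spec
    )


def layer_span_residues(
    chain: str, from_layer: int, to_layer: int, spec: ConstructSpec
) -> int:
    """Residues spanned between two layers of one helix (symmetric)."""
    a = spec.layer_residue(chain, from_layer)
    b = spec.layer_residue(chain, to_layer)
    return abs(b - a)
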