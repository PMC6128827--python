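"""Force-dependent rate model shared by the simulator and the fitting stages.

Every transition obeys the Bell equation

    k(F) = k_w exp[(-dG + F dx) / kBT]  =  k_ref exp[(F - F_ref) dx / kBT]

with kBT = 4.11 pN nm and attempt frequency k_w = 1e6 s^-1.  A
:class:`KineticScheme` is a directed graph of such transitions among named
conformational states; :func:`scheme_from_landscape` builds one from state
free energies and barrier positions so that detailed balance holds exactly
at every force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import ATTEMPT_RATE_S, KBT_PN_NM

__all__ = [
    "BellParameters",
    "KineticScheme",
    "rate_at_force",
    "scheme_from_landscape",
]


@dataclass(frozen=True)
class BellParameters:
    """Bell-equation parameterization of one transition.

    ``delta_x_nm`` is signed: positive if force accelerates the transition
    (unzipping-like), negative if force opposes it (zippering-like).
    """

    k_ref_s: float
    f_ref_pn: float
    delta_x_nm: float

    def __post_init__(self) -> None:
        if self.k_ref_s <= 0:
            raise ValueError("k_ref must be > 0")

    @classmethod
    def from_barrier(
        cls,
        barrier_kbt: float,
        delta_x_nm: float,
        attempt_rate_s: float = ATTEMPT_RATE_S,
    ) -> "BellParameters":
        """From zero-force barrier height (kBT) and transition distance."""
        return cls(
            k_ref_s=attempt_rate_s * math.exp(-barrier_kbt),
            f_ref_pn=0.0,
            delta_x_nm=delta_x_nm,
        )

    def barrier_kbt(self, force: float, attempt_rate_s: float = ATTEMPT_RATE_S) -> float:
        """Force-tilted barrier height implied by k(F) and the attempt rate."""
        return math.log(attempt_rate_s / rate_at_force(self, force))


def rate_at_force(edge: BellParameters, force: float) -> float:
    """Bell rate k(F) = k_ref exp[(F - F_ref) dx / kBT], s^-1."""
    if force < 0:
        raise ValueError("force must be >= 0")
    return edge.k_ref_s * math.exp(
        (force - edge.f_ref_pn) * edge.delta_x_nm / KBT_PN_NM
    )


@dataclass
class KineticScheme:
    """Directed rate graph among conformational states.

    ``gates`` optionally restricts an edge to a force window (f_min, f_max);
    outside the window its rate is zero (e.g. SNAP-25 rebinding only below
    2 pN).
    """

    states: list[str]
    edges: dict[tuple[str, str], BellParameters]
    gates: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (src, dst) in self.edges:
            if src not in self.states or dst not in self.states:
                raise ValueError(f"edge {(src, dst)} references unknown state")

    def rate(self, src: str, dst: str, force: float) -> float:
        edge = self.edges.get((src, dst))
        if edge is None:
            return 0.0
        lo, hi = self.gates.get((src, dst), (0.0, math.inf))
        if not lo <= force <= hi:
            return 0.0
        return rate_at_force(edge, force)

    def out_rates(self, src: str, force: float) -> dict[str, float]:
        return {
            dst: self.rate(src, dst, force)
            for (s, dst) in self.edges
            if s == src and self.rate(src, dst, force) > 0.0
        }

    def total_exit_rate(self, src: str, force: float) -> float:
        return sum(self.out_rates(src, force).values())

    def is_absorbing(self, state: str, force: float) -> bool:
        return self.total_exit_rate(state, force) == 0.0


def scheme_from_landscape(
    state_energies: dict[str, tuple[float, float]],
    barriers: dict[tuple[str, str], tuple[float, float]],
    attempt_rate_s: float = ATTEMPT_RATE_S,
    reference_force_pn: float = 0.0,
) -> KineticScheme:
    """Build a scheme from a 1-D free-energy landscape.

    Parameters
    ----------
    state_energies
        state -> (G in kBT at ``reference_force_pn``, extension coordinate
        x in nm).
    barriers
        undirected edge (i, j) -> (barrier position nm, barrier height kBT
        at ``reference_force_pn``).  Both directed rates are generated with
        k_ij(F) = k_w exp[-(B - G_i - (F - F_ref)(x_b - x_i)/kBT) ...], which
        makes k_ij / k_ji equal the Boltzmann factor of the force-tilted
        state-energy difference at every force (exact detailed balance).
    reference_force_pn
        Force at which the energies and barrier heights are quoted.  A
        landscape is usually sketched at the working force (e.g. 14 pN),
        where the barrier tops both wells; at other forces the tilt can put
        a well above the barrier.
    """
    edges: dict[tuple[str, str], BellParameters] = {}
    for (i, j), (x_b, height) in barriers.items():
        for endpoint in (i, j):
            if endpoint not in state_energies:
                raise ValueError(f"barrier {(i, j)} references unknown state")
        g_i, x_i = state_energies[i]
        g_j, x_j = state_energies[j]
        if height < max(g_i, g_j):
            raise ValueError(f"barrier {(i, j)} lower than an endpoint energy")
        edges[(i, j)] = BellParameters(
            k_ref_s=attempt_rate_s * math.exp(-(height - g_i)),
            f_ref_pn=reference_force_pn,
            delta_x_nm=x_b - x_i,
        )
        edges[(j, i)] = BellParameters(
            k_ref_s=attempt_rate_s * math.exp(-(height - g_j)),
            f_ref_pn=reference_force_pn,
            delta_x_nm=x_b - x_j,
        )
    return KineticScheme(states=list(state_energies), edges=edges)
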