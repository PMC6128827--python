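"""Equilibrium populations of zippered intermediates from high-speed traces.

Extension samples collected at each force on a 0.2 pN grid are fit with a
Gaussian mixture; components are assigned to the fully zippered,
linker-open and half-zippered states by proximity to the model state
levels, giving a force-dependent population table.  The table is fit to a
three-state Boltzmann equilibrium model

    p_i(F) = exp(-(G_i - F x_i)/kBT) / sum_j exp(-(G_j - F x_j)/kBT)

with (G_0, x_0) = (0, 0) for the fully zippered reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.mixture import GaussianMixture

from .constants import KBT_PN_NM

__all__ = [
    "GMMResult",
    "EquilibriumModel",
    "fit_gmm",
    "fit_fixed_level_mixture",
    "population_scan",
    "fit_three_state",
    "three_state_populations",
    "fold_change",
]

ZIPPER_STATES = ("FULLY_ZIPPERED", "LINKER_OPEN", "HALF_ZIPPERED")
ASSIGN_TOL_NM = 2.5  # component-to-state assignment tolerance
MIN_SCAN_SECONDS = 15.0


@dataclass(frozen=True)
class GMMResult:
    means_nm: np.ndarray
    sds_nm: np.ndarray
    weights: np.ndarray
    k: int
    log_likelihood: float


def fit_gmm(
    extensions_nm: np.ndarray,
    k: int,
    init_means: np.ndarray | None = None,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
) -> GMMResult:
    """EM fit of a k-component Gaussian mixture, components sorted by mean.

    Best of ``n_init`` seeded restarts (single run when ``init_means`` is
    given, since the EM start is then deterministic).  ``tol`` is the EM
    stopping tolerance on the per-sample average log-likelihood.
    """
    x = np.asarray(extensions_nm, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2 * k:
        raise ValueError("too few samples for the requested components")
    kwargs: dict = {}
    if init_means is not None:
        kwargs["means_init"] = np.asarray(init_means, dtype=float).reshape(-1, 1)
        n_init = 1
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        tol=tol,
        max_iter=500,
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-6,
        **kwargs,
    ).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    if np.any(sds < 1e-3 * (x.max() - x.min() + 1e-12)):
        raise RuntimeError("degenerate mixture component (sd collapsed)")
    order = np.argsort(means)
    return GMMResult(
        means_nm=means[order],
        sds_nm=sds[order],
        weights=gm.weights_[order],
        k=k,
        log_likelihood=float(gm.score(x) * x.shape[0]),
    )


def components_for_force(force_pn: float) -> int:
    """Mixture order per force: 2 below the 13 pN threshold, 3 at/above."""
    return 2 if force_pn < 13.0 else 3


def fit_fixed_level_mixture(
    extensions_nm: np.ndarray,
    levels_nm: np.ndarray,
    sigma_init_nm: float = 2.5,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> GMMResult:
    """Mixture fit with component means pinned to known state levels.

    Only the component weights and one shared noise width are estimated by
    EM.  With partially overlapping components (state spacing ~2 sigma) the
    fully free mixture is weakly identified and its weights are biased;
    pinning the means to the known extension levels — the same use of
    measured priors as in the HMM stage — makes the weights consistent
    estimates of the state occupancies.
    """
    x = np.asarray(extensions_nm, dtype=float)
    levels = np.asarray(levels_nm, dtype=float)
    k = len(levels)
    w = np.full(k, 1.0 / k)
    sigma = float(sigma_init_nm)
    sq = (x[None, :] - levels[:, None]) ** 2
    prev = -np.inf
    for _ in range(max_iter):
        log_dens = -0.5 * sq / sigma**2 - math.log(sigma)
        log_r = np.log(w[:, None] + 1e-300) + log_dens
        norm = np.logaddexp.reduce(log_r, axis=0)
        ll = float(norm.sum())
        r = np.exp(log_r - norm[None, :])
        w = r.mean(axis=1)
        sigma = math.sqrt(float((r * sq).sum() / x.size))
        if abs(ll - prev) < tol * x.size:
            break
        prev = ll
    return GMMResult(
        means_nm=levels.copy(),
        sds_nm=np.full(k, sigma),
        weights=w,
        k=k,
        log_likelihood=ll,
    )


def population_scan(
    samples_by_force: dict[float, np.ndarray],
    state_levels_nm: dict[str, float],
    sampling_rate_hz: float = 1200.0,
    condition: str = "",
    k_by_force: dict[float, int] | None = None,
    assign_tol_nm: float = ASSIGN_TOL_NM,
    seed: int = 0,
    fix_levels: bool = True,
) -> pd.DataFrame:
    """Per-force mixture fits assigned to the three zippered states.

    ``samples_by_force`` maps grid force (pN) to extension samples relative
    to the fully zippered level.  By default component means are pinned to
    the model state levels (:func:`fit_fixed_level_mixture`); with
    ``fix_levels=False`` a free Gaussian mixture is fit and components are
    matched to the nearest state level within ``assign_tol_nm``.  Unmatched
    weight (e.g. an unzipped component) is excluded and the three state
    populations are renormalized to 1.  Rows with less than 15 s of data
    are flagged.
    """
    rows = []
    for force in sorted(samples_by_force):
        x = np.asarray(samples_by_force[force], dtype=float)
        k = (k_by_force or {}).get(force, components_for_force(force))
        init = np.array(
            [state_levels_nm[s] for s in ZIPPER_STATES[:k]], dtype=float
        )
        if fix_levels:
            gmm = fit_fixed_level_mixture(x, init)
        else:
            gmm = fit_gmm(x, k=k, init_means=init, seed=seed)
        pops = {s: 0.0 for s in ZIPPER_STATES}
        for mean, w in zip(gmm.means_nm, gmm.weights):
            dists = {s: abs(mean - state_levels_nm[s]) for s in ZIPPER_STATES}
            best = min(dists, key=dists.get)
            if dists[best] <= assign_tol_nm:
                pops[best] += w
        total = sum(pops.values())
        if total == 0:
            warnings.warn(
                f"no component assigned at {force} pN; row skipped", stacklevel=2
            )
            continue
        seconds = x.size / sampling_rate_hz
        rows.append(
            {
                "force_pn": force,
                "p_fully_zippered": pops["FULLY_ZIPPERED"] / total,
                "p_linker_open": pops["LINKER_OPEN"] / total,
                "p_half_zippered": pops["HALF_ZIPPERED"] / total,
                "n_frames": x.size,
                "low_confidence": seconds < MIN_SCAN_SECONDS,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["condition"] = condition
    return table


@dataclass(frozen=True)
class EquilibriumModel:
    """Three-state equilibrium parameters relative to fully zippered.

    Energies in kBT at zero force; extension coordinates in nm.
    """

    g_kbt: dict[str, float]
    x_nm: dict[str, float]
    residual: float = 0.0

    def populations(self, force_pn: float) -> dict[str, float]:
        # G_i is in kBT; the force tilt F x_i (pN nm) is converted to kBT
        w = {
            s: math.exp(-(self.g_kbt[s] - force_pn * self.x_nm[s] / KBT_PN_NM))
            for s in self.g_kbt
        }
        z = sum(w.values())
        return {s: v / z for s, v in w.items()}


def three_state_populations(
    model: EquilibriumModel, forces: np.ndarray
) -> pd.DataFrame:
    rows = []
    for f in np.atleast_1d(forces):
        p = model.populations(float(f))
        rows.append(
            {
                "force_pn": float(f),
                "p_fully_zippered": p["FULLY_ZIPPERED"],
                "p_linker_open": p["LINKER_OPEN"],
                "p_half_zippered": p["HALF_ZIPPERED"],
            }
        )
    return pd.DataFrame(rows)


_P_COLS = {
    "FULLY_ZIPPERED": "p_fully_zippered",
    "LINKER_OPEN": "p_linker_open",
    "HALF_ZIPPERED": "p_half_zippered",
}


def fit_three_state(
    table: pd.DataFrame,
    fix_x_nm: dict[str, float] | None = None,
) -> EquilibriumModel:
    """Fit the Boltzmann three-state model to a population table.

    The loss is the multinomial negative log-likelihood using the per-row
    frame counts (falling back to equal counts when absent).  Initialized
    from per-state linear fits of ln(p_i / p_0) against force, which is the
    exact inverse on noiseless model-generated tables.
    """
    f = table["force_pn"].to_numpy(dtype=float)
    if np.unique(f).size < 2:
        raise ValueError("non-identifiable: populations observed at < 2 forces")
    p_obs = np.column_stack(
        [table[_P_COLS[s]].to_numpy(dtype=float) for s in ZIPPER_STATES]
    )
    n = (
        table["n_frames"].to_numpy(dtype=float)
        if "n_frames" in table
        else np.full(len(table), 1000.0)
    )
    if np.allclose(p_obs.std(axis=0), 0.0):
        raise ValueError("non-identifiable: populations constant in force")

    # linearized init: ln(p_i/p_0) = (-G_i + F x_i)/kBT
    init = {}
    eps = 1e-12
    for j, s in enumerate(ZIPPER_STATES[1:], start=1):
        y = np.log((p_obs[:, j] + eps) / (p_obs[:, 0] + eps))
        slope, intercept = np.polyfit(f, y, 1)
        init[s] = (-intercept, slope * KBT_PN_NM)

    free_states = [s for s in ZIPPER_STATES[1:]]

    def unpack(theta: np.ndarray) -> EquilibriumModel:
        g = {"FULLY_ZIPPERED": 0.0}
        x = {"FULLY_ZIPPERED": 0.0}
        i = 0
        for s in free_states:
            g[s] = theta[i]
            i += 1
            if fix_x_nm and s in fix_x_nm:
                x[s] = fix_x_nm[s]
            else:
                x[s] = theta[i]
                i += 1
        return EquilibriumModel(g_kbt=g, x_nm=x)

    def pack_init() -> np.ndarray:
        theta = []
        for s in free_states:
            theta.append(init[s][0])
            if not (fix_x_nm and s in fix_x_nm):
                theta.append(init[s][1])
        return np.array(theta)

    def nll(theta: np.ndarray) -> float:
        model = unpack(theta)
        total = 0.0
        for fi, pi, ni in zip(f, p_obs, n):
            pm = model.populations(float(fi))
            pvec = np.array([pm[s] for s in ZIPPER_STATES])
            total -= ni * float(np.sum(pi * np.log(pvec + 1e-300)))
        return total

    res = minimize(nll, pack_init(), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    model = unpack(res.x)
    pred = three_state_populations(model, f)
    resid = float(
        np.sqrt(
            np.mean(
                (
                    pred[list(_P_COLS.values())].to_numpy() - p_obs
                )
                ** 2
            )
        )
    )
    return EquilibriumModel(g_kbt=model.g_kbt, x_nm=model.x_nm, residual=resid)


def fold_change(
    table_cond: pd.DataFrame,
    table_ref: pd.DataFrame,
    force_pn: float,
    state: str,
) -> float:
    """Population ratio p_state(cond) / p_state(ref) at one grid force."""
    col = _P_COLS[state]

    def row(table: pd.DataFrame) -> float:
        sel = np.isclose(table["force_pn"], force_pn, atol=1e-6)
        if not sel.any():
            raise KeyError(f"force {force_pn} pN not in table")
        return float(table.loc[sel, col].iloc[0])

    ref = row(table_ref)
    if ref == 0.0:
        raise ZeroDivisionError("reference population is zero; ratio undefined")
    return row(table_cond) / ref
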