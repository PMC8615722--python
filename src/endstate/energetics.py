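"""Molecular-mechanics and implicit-solvent energy terms for single frames.

All energies are kcal/mol, distances Å.  Pair terms use Lennard-Jones 12-6
with Lorentz–Berthelot-style combination (rmin = rmin_half_i + rmin_half_j,
eps = sqrt(eps_i * eps_j)) and vacuum Coulomb with no cutoff.  The polar
solvation term is a generalized-Born sum with OBC-II effective radii
(alpha=1.0, beta=0.8, gamma=4.85, no radius offset so an isolated atom's
effective radius equals its intrinsic one); the non-polar term is
gamma * SASA + beta with numerical Shrake–Rupley surface areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import (
    COULOMB_CONSTANT,
    DEFAULT_BETA,
    DEFAULT_EPS_SOLVENT,
    DEFAULT_GAMMA,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
)
from .io import ToySystem

__all__ = [
    "FrameEnergies",
    "pair_vdw",
    "pair_coulomb",
    "effective_born_radii",
    "gb_energy",
    "gb_energy_per_atom",
    "sasa",
    "sasa_per_atom",
    "nonpolar_energy",
    "gas_phase_interaction",
    "frame_energies",
]

# OBC-II coefficients for the tanh rescaling of effective radii
_OBC_ALPHA, _OBC_BETA, _OBC_GAMMA = 1.0, 0.8, 4.85
# uniform HCT descreening scale factor
_SCREEN = 0.8


def _as_indices(mask, n: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if len(mask) != n:
            raise ValueError("boolean mask length mismatch")
        return np.nonzero(mask)[0]
    return mask.astype(int)


def _check_disjoint(a: np.ndarray, b: np.ndarray) -> None:
    if np.intersect1d(a, b).size:
        raise ValueError("atom masks must be disjoint")


# ---------------------------------------------------------------------------
# pairwise gas-phase terms
# ---------------------------------------------------------------------------


def _cross_vdw_matrix(system: ToySystem, frame: int, ia, ib) -> np.ndarray:
    r = cdist(system.coords[frame, ia], system.coords[frame, ib])
    if np.any(r == 0.0):
        raise ValueError("coincident atoms across masks (LJ singularity)")
    rmin = system.rmin_half[ia][:, None] + system.rmin_half[ib][None, :]
    eps = np.sqrt(system.epsilon[ia][:, None] * system.epsilon[ib][None, :])
    x = (rmin / r) ** 6
    return eps * (x * x - 2.0 * x)


def _cross_coulomb_matrix(system: ToySystem, frame: int, ia, ib) -> np.ndarray:
    r = cdist(system.coords[frame, ia], system.coords[frame, ib])
    if np.any(r == 0.0):
        raise ValueError("coincident atoms across masks (Coulomb singularity)")
    qq = system.charges[ia][:, None] * system.charges[ib][None, :]
    return COULOMB_CONSTANT * qq / r


def pair_vdw(system: ToySystem, frame: int, mask_a, mask_b) -> float:
    """Lennard-Jones 12-6 sum over all cross pairs, no cutoff."""
    ia = _as_indices(mask_a, system.n_atoms)
    ib = _as_indices(mask_b, system.n_atoms)
    _check_disjoint(ia, ib)
    return float(_cross_vdw_matrix(system, frame, ia, ib).sum())


def pair_coulomb(system: ToySystem, frame: int, mask_a, mask_b) -> float:
    """Vacuum Coulomb sum over all cross pairs, no cutoff."""
    ia = _as_indices(mask_a, system.n_atoms)
    ib = _as_indices(mask_b, system.n_atoms)
    _check_disjoint(ia, ib)
    return float(_cross_coulomb_matrix(system, frame, ia, ib).sum())


def gas_phase_interaction(system: ToySystem, frame: int) -> float:
    """vdW + Coulomb interaction energy across the receptor/ligand partition."""
    a = system.receptor_mask
    b = system.ligand_mask
    return pair_vdw(system, frame, a, b) + pair_coulomb(system, frame, a, b)


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------


def effective_born_radii(system: ToySystem, frame: int, mask) -> np.ndarray:
    """OBC-II effective radii from HCT pairwise descreening (Å)."""
    idx = _as_indices(mask, system.n_atoms)
    rho = system.born_radius[idx]
    if np.any(rho <= 0):
        raise ValueError("born_radius must be > 0")
    pos = system.coords[frame, idx]
    n = len(idx)
    if n == 1:
        integral = np.zeros(1)
    else:
        r = cdist(pos, pos)
        sk = _SCREEN * rho[None, :]  # scaled radius of the descreening atom j
        rho_i = rho[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = r + sk
            low = np.maximum(rho_i, np.abs(r - sk))
            h = 0.5 * (
                1.0 / low
                - 1.0 / u
                + 0.25 * (r - sk * sk / r) * (1.0 / (u * u) - 1.0 / (low * low))
                + 0.5 * np.log(low / u) / r
            )
            # atom i fully inside the scaled sphere of j
            buried = rho_i < (sk - r)
            h = np.where(buried, h + 2.0 * (1.0 / rho_i - 1.0 / low), h)
            # atom j fully inside i: no descreening
            h = np.where(rho_i >= u, 0.0, h)
        np.fill_diagonal(h, 0.0)
        integral = h.sum(axis=1)
    psi = integral * rho
    arg = _OBC_ALPHA * psi - _OBC_BETA * psi**2 + _OBC_GAMMA * psi**3
    inv_reff = 1.0 / rho - np.tanh(arg) / rho
    return 1.0 / inv_reff


def _gb_pair_matrix(
    system: ToySystem, frame: int, idx: np.ndarray, eps_solvent: float
) -> np.ndarray:
    reff = effective_born_radii(system, frame, idx)
    pos = system.coords[frame, idx]
    r2 = cdist(pos, pos) ** 2
    rr = reff[:, None] * reff[None, :]
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    qq = system.charges[idx][:, None] * system.charges[idx][None, :]
    pref = -0.5 * COULOMB_CONSTANT * (1.0 - 1.0 / eps_solvent)
    return pref * qq / f


def gb_energy(
    system: ToySystem,
    frame: int,
    mask=None,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
) -> float:
    """Generalized-Born polar solvation energy of the masked atoms.

    Includes the i = j self terms; ``eps_solvent = 1`` gives exactly zero.
    """
    if eps_solvent == 1.0:
        return 0.0
    idx = _as_indices(
        mask if mask is not None else np.ones(system.n_atoms, bool), system.n_atoms
    )
    e = _gb_pair_matrix(system, frame, idx, eps_solvent)
    # off-diagonal pairs appear twice in the matrix; energy counts them once
    return float(np.diag(e).sum() + (e.sum() - np.diag(e).sum()) / 2.0)


def gb_energy_per_atom(
    system: ToySystem,
    frame: int,
    mask=None,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom GB split (self full, cross terms half to each partner).

    Returns ``(atom_indices, contributions)``; contributions sum to
    :func:`gb_energy` exactly.
    """
    idx = _as_indices(
        mask if mask is not None else np.ones(system.n_atoms, bool), system.n_atoms
    )
    if eps_solvent == 1.0:
        return idx, np.zeros(len(idx))
    e = _gb_pair_matrix(system, frame, idx, eps_solvent)
    # atom i: full self term plus half of every unordered cross pair
    contrib = 0.5 * e.sum(axis=1) + 0.5 * np.diag(e)
    return idx, contrib


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (2.0 * i + 1.0) / n
    rad = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i
    return np.column_stack([rad * np.cos(theta), rad * np.sin(theta), z])


def sasa_per_atom(
    system: ToySystem,
    frame: int,
    mask=None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrake–Rupley per-atom SASA (Å²) using lj_rmin_half + probe radii."""
    if probe < 0:
        raise ValueError("probe must be >= 0")
    if n_points < 12:
        raise ValueError("n_points must be >= 12")
    idx = _as_indices(
        mask if mask is not None else np.ones(system.n_atoms, bool), system.n_atoms
    )
    pos = system.coords[frame, idx]
    radii = system.rmin_half[idx] + probe
    sphere = _fibonacci_sphere(n_points)
    pair_d = cdist(pos, pos)
    areas = np.empty(len(idx))
    for k in range(len(idx)):
        nbr = np.nonzero(
            (pair_d[k] < radii[k] + radii) & (np.arange(len(idx)) != k)
        )[0]
        pts = pos[k] + radii[k] * sphere
        if len(nbr):
            d = cdist(pts, pos[nbr])
            exposed = np.all(d >= radii[nbr][None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas[k] = 4.0 * np.pi * radii[k] ** 2 * frac
    return idx, areas


def sasa(
    system: ToySystem,
    frame: int,
    mask=None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_SASA_POINTS,
) -> float:
    """Total solvent-accessible surface area of the masked atoms (Å²)."""
    _, areas = sasa_per_atom(system, frame, mask, probe, n_points)
    return float(areas.sum())


def nonpolar_energy(
    area: float, gamma: float = DEFAULT_GAMMA, beta: float = DEFAULT_BETA
) -> float:
    """Empirical non-polar solvation term gamma * SASA + beta."""
    if area < 0:
        raise ValueError("area must be >= 0")
    return gamma * area + beta


# ---------------------------------------------------------------------------
# assembled frame energies with per-residue decomposition
# ---------------------------------------------------------------------------


@dataclass
class FrameEnergies:
    """The four energy terms of one atom group in one frame, with a
    per-residue additive decomposition (pair terms split half to each
    partner residue; GB self terms to the owning residue)."""

    e_vdw: float
    e_ele: float
    g_gb: float
    g_np: float
    per_residue: pd.DataFrame  # index (chain, resi); columns vdw, ele, gb, np


def frame_energies(
    system: ToySystem,
    frame: int,
    mask=None,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
    probe: float = DEFAULT_PROBE_RADIUS,
    sasa_points: int = DEFAULT_SASA_POINTS,
    gamma: float = DEFAULT_GAMMA,
    beta: float = DEFAULT_BETA,
) -> FrameEnergies:
    """Internal vdW/Coulomb plus GB and non-polar terms of one atom group."""
    idx = _as_indices(
        mask if mask is not None else np.ones(system.n_atoms, bool), system.n_atoms
    )
    pos = system.coords[frame, idx]
    r = cdist(pos, pos)
    iu = np.triu_indices(len(idx), k=1)
    if np.any(r[iu] == 0.0):
        raise ValueError("coincident atoms within mask")

    rmin = system.rmin_half[idx][:, None] + system.rmin_half[idx][None, :]
    eps = np.sqrt(system.epsilon[idx][:, None] * system.epsilon[idx][None, :])
    qq = system.charges[idx][:, None] * system.charges[idx][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (rmin / r) ** 6
        vdw_m = eps * (x * x - 2.0 * x)
        ele_m = COULOMB_CONSTANT * qq / r
    np.fill_diagonal(vdw_m, 0.0)
    np.fill_diagonal(ele_m, 0.0)

    e_vdw = float(vdw_m[iu].sum())
    e_ele = float(ele_m[iu].sum())
    # half/half split: the full (double-counted) matrix halved per atom
    vdw_atom = 0.5 * vdw_m.sum(axis=1)
    ele_atom = 0.5 * ele_m.sum(axis=1)

    _, gb_atom = gb_energy_per_atom(system, frame, idx, eps_solvent)
    _, areas = sasa_per_atom(system, frame, idx, probe, sasa_points)
    np_atom = gamma * areas
    g_np = float(np_atom.sum()) + beta
    g_gb = float(gb_atom.sum())

    keys = pd.MultiIndex.from_arrays(
        [system.chain_ids[idx], system.residue_ids[idx]], names=["chain", "resi"]
    )
    per_res = (
        pd.DataFrame(
            {"vdw": vdw_atom, "ele": ele_atom, "gb": gb_atom, "np": np_atom},
            index=keys,
        )
        .groupby(level=["chain", "resi"], sort=False)
        .sum()
    )
    return FrameEnergies(
        e_vdw=e_vdw, e_ele=e_ele, g_gb=g_gb, g_np=g_np, per_residue=per_res
    )
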