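"""Synthetic inputs with known ground truth.

Three generators cover everything the analysis pipeline consumes:

* :func:`gen_energy_series` — stationary Gaussian / AR(1) interaction-energy
  series with optional regime changes and injected two-sided outliers;
* :func:`gen_toy_complex` — a multi-chain protein ring bound to a short
  single-stranded RNA-like chain, with designed contacts (hydrogen bond,
  salt bridge, alkyl–ring) realized in an exact, seed-chosen subset of
  frames;
* :func:`gen_fep_samples` — exact Boltzmann samples of a harmonic
  mutation toy, one window per coupling value.

All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .constants import KB, DEFAULT_TEMPERATURE
from .fep import FepDataset
from .io import EnergySeries, ToySystem
from .selections import parse_selection

__all__ = [
    "SeriesSpec",
    "ContactSpec",
    "ComplexSpec",
    "gen_energy_series",
    "gen_toy_complex",
    "gen_fep_samples",
]


# ---------------------------------------------------------------------------
# energy series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for a synthetic interaction-energy series."""

    n_points: int
    dt: float = 1.0
    mean: float = 0.0
    sigma: float = 1.0
    autocorrelation_time: float = 0.0
    regime_changes: tuple[tuple[int, float, float], ...] = ()
    outlier_fraction: float = 0.0
    outlier_scale: float = 8.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.autocorrelation_time < 0:
            raise ValueError("autocorrelation_time must be >= 0")
        for start, _, sig in self.regime_changes:
            if not (0 < start < self.n_points):
                raise ValueError(f"regime start {start} outside (0, n_points)")
            if sig < 0:
                raise ValueError("regime sigma must be >= 0")


def _segments(spec: SeriesSpec) -> list[tuple[int, int, float, float]]:
    changes = sorted(spec.regime_changes)
    bounds = [0] + [c[0] for c in changes] + [spec.n_points]
    means = [spec.mean] + [c[1] for c in changes]
    sigmas = [spec.sigma] + [c[2] for c in changes]
    return [
        (bounds[i], bounds[i + 1], means[i], sigmas[i]) for i in range(len(means))
    ]


def gen_energy_series(spec: SeriesSpec) -> EnergySeries:
    """Generate a stationary Gaussian or AR(1) series per the spec."""
    rng = np.random.default_rng(spec.seed)
    phi = (
        float(np.exp(-spec.dt / spec.autocorrelation_time))
        if spec.autocorrelation_time > 0
        else 0.0
    )
    values = np.empty(spec.n_points)
    for start, stop, mean, sigma in _segments(spec):
        m = stop - start
        eps = rng.standard_normal(m)
        # innovations scaled so the stationary SD equals sigma
        driv = eps * (sigma * np.sqrt(1.0 - phi * phi))
        driv[0] = eps[0] * sigma
        values[start:stop] = mean + lfilter([1.0], [1.0, -phi], driv)

    n_out = int(round(spec.outlier_fraction * spec.n_points))
    if n_out > 0:
        idx = rng.choice(spec.n_points, size=n_out, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        extra = rng.uniform(0.0, 1.0, size=n_out)
        seg_of = np.empty(spec.n_points, dtype=int)
        segs = _segments(spec)
        for k, (start, stop, _, _) in enumerate(segs):
            seg_of[start:stop] = k
        for j, i in enumerate(idx):
            _, _, mean, sigma = segs[seg_of[i]]
            values[i] = mean + signs[j] * sigma * spec.outlier_scale * (1.0 + extra[j])

    times = np.arange(spec.n_points) * spec.dt
    return EnergySeries(times, values, spec.label)


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

# residue templates: name -> (element, offset xyz, charge, rmin_half, epsilon, born)
_PROTEIN_TEMPLATE = {
    "N": ("N", (0.00, 0.00, 0.00), -0.40, 1.824, 0.1700, 1.55),
    "H": ("H", (-0.60, 0.85, 0.00), 0.31, 0.600, 0.0157, 1.20),
    "CA": ("C", (1.45, 0.00, 0.00), 0.03, 1.908, 0.1094, 1.70),
    "C": ("C", (2.15, 1.25, 0.00), 0.55, 1.908, 0.0860, 1.70),
    "O": ("O", (2.10, 2.45, 0.00), -0.55, 1.661, 0.2100, 1.50),
    "CB": ("C", (1.95, -0.95, 1.05), -0.05, 1.908, 0.1094, 1.70),
    "CG": ("C", (2.65, -2.05, 1.55), -0.05, 1.908, 0.1094, 1.70),
    "NZ": ("N", (3.35, -3.15, 2.10), 0.51, 1.824, 0.1700, 1.55),
    "OH": ("O", (1.25, -1.15, 2.55), -0.55, 1.721, 0.2104, 1.50),
    "HH": ("H", (1.30, -1.60, 3.45), 0.40, 0.300, 0.0000, 1.10),
}

_RNA_TEMPLATE = {
    "P": ("P", (0.00, 0.00, 0.00), 1.17, 2.100, 0.2000, 1.85),
    "OP1": ("O", (-0.75, 1.20, 0.10), -0.78, 1.661, 0.2100, 1.50),
    "OP2": ("O", (-0.75, -1.20, 0.10), -0.78, 1.661, 0.2100, 1.50),
    "O5'": ("O", (1.35, 0.05, 0.60), -0.50, 1.683, 0.1700, 1.50),
    "C1'": ("C", (2.55, 0.60, 1.20), 0.10, 1.908, 0.1094, 1.70),
    "N9": ("N", (3.75, 0.00, 1.55), -0.20, 1.824, 0.1700, 1.55),
    "C8": ("C", (4.90, 0.70, 1.85), 0.20, 1.908, 0.0860, 1.70),
    "N7": ("N", (6.00, 0.05, 2.15), -0.50, 1.824, 0.1700, 1.55),
    "C5": ("C", (5.60, -1.25, 2.10), 0.05, 1.908, 0.0860, 1.70),
    "C4": ("C", (4.20, -1.30, 1.75), 0.30, 1.908, 0.0860, 1.70),
}

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQ"
_RNA_CHAIN = "R"
_MIN_HEAVY_SEPARATION = 0.7  # Å, hard-sphere overlap threshold


@dataclass(frozen=True)
class ContactSpec:
    """One designed receptor–ligand contact.

    ``kind`` is one of ``hbond`` (protein selector = donor heavy atom, RNA
    selector = acceptor atom), ``salt_bridge`` (minimum atom-pair distance
    between the two groups) or ``ch_pi`` (centroid–centroid distance).
    """

    kind: str
    protein: str
    rna: str
    target_distance: float
    on_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "salt_bridge", "ch_pi"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")
        if not (0.0 <= self.on_fraction <= 1.0):
            raise ValueError("on_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a hexamer-like protein ring bound to a short ssRNA toy."""

    n_protein_chains: int = 6
    residues_per_chain: int = 3
    n_rna_nucleotides: int = 4
    contact_pairs: tuple[ContactSpec, ...] = ()
    n_frames: int = 10
    jitter_sigma: float = 0.03
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not (1 <= self.n_protein_chains <= len(_CHAIN_IDS)):
            raise ValueError("n_protein_chains out of range")
        if self.residues_per_chain < 1 or self.n_rna_nucleotides < 1:
            raise ValueError("need at least one residue per chain")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def _base_geometry(spec: ComplexSpec):
    names, elements, chains, resids, resns = [], [], [], [], []
    charges, rmin, eps, born, group = [], [], [], [], []
    coords = []

    def emit(template, resn, chain, resi, origin, grp):
        for name, (el, off, q, rm, ep, b) in template.items():
            names.append(name)
            elements.append(el)
            chains.append(chain)
            resids.append(resi)
            resns.append(resn)
            charges.append(q)
            rmin.append(rm)
            eps.append(ep)
            born.append(b)
            group.append(grp)
            coords.append(np.asarray(origin) + np.asarray(off))

    n_res_total = spec.n_protein_chains * spec.residues_per_chain
    ring_radius = max(14.0, n_res_total * 3.8 * 1.3 / (2.0 * np.pi))
    for c in range(spec.n_protein_chains):
        theta = 2.0 * np.pi * c / spec.n_protein_chains
        center = ring_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        for r in range(spec.residues_per_chain):
            origin = center + (r - (spec.residues_per_chain - 1) / 2.0) * 3.8 * tangent
            emit(_PROTEIN_TEMPLATE, "AMI", _CHAIN_IDS[c], r + 1, origin, "receptor")

    x0 = -(spec.n_rna_nucleotides - 1) * 3.0
    for n in range(spec.n_rna_nucleotides):
        origin = np.array([x0 + n * 6.0, 0.0, 9.0])
        emit(_RNA_TEMPLATE, "NUC", _RNA_CHAIN, n + 1, origin, "ligand")

    return (
        np.asarray(names, dtype=object),
        np.asarray(elements, dtype=object),
        np.asarray(chains, dtype=object),
        np.asarray(resids, dtype=int),
        np.asarray(resns, dtype=object),
        np.asarray(charges, dtype=float),
        np.asarray(rmin, dtype=float),
        np.asarray(eps, dtype=float),
        np.asarray(born, dtype=float),
        np.asarray(group, dtype=object),
        np.asarray(coords, dtype=float),
    )


def _residue_atoms(system: ToySystem, chain: str, resi: int) -> np.ndarray:
    return np.nonzero(
        (system.chain_ids == chain) & (system.residue_ids == resi)
    )[0]


def _donor_hydrogen(system: ToySystem, donor_idx: int) -> int:
    chain = system.chain_ids[donor_idx]
    resi = system.residue_ids[donor_idx]
    res_atoms = _residue_atoms(system, chain, resi)
    hyds = [i for i in res_atoms if system.elements[i] == "H"]
    if not hyds:
        raise ValueError(f"donor {chain}:{resi} has no hydrogen atom")
    pos = system.coords[0]
    d = [np.linalg.norm(pos[i] - pos[donor_idx]) for i in hyds]
    return hyds[int(np.argmin(d))]


def _elevated(v: np.ndarray) -> np.ndarray:
    """Unit approach direction tilted to >= 45° elevation so a realized
    contact pulls the ligand residue above, not through, the protein ring."""
    horizontal = float(np.hypot(v[0], v[1]))
    out = np.array([v[0], v[1], max(v[2], horizontal)])
    return out / np.linalg.norm(out)


def _orient_residue(
    coords: np.ndarray, res_atoms: np.ndarray, anchor: np.ndarray, u: np.ndarray
) -> None:
    """Rotate a residue rigidly about ``anchor`` so its centroid lies along
    ``+u`` — the residue's tail then points away from the protein."""
    from scipy.spatial.transform import Rotation

    tail = coords[res_atoms].mean(axis=0) - anchor
    norm = np.linalg.norm(tail)
    if norm < 1e-6:
        return
    rot, _ = Rotation.align_vectors(u[None, :], (tail / norm)[None, :])
    coords[res_atoms] = anchor + rot.apply(coords[res_atoms] - anchor)


def _realize_contact(
    coords: np.ndarray,
    contact: ContactSpec,
    idx_protein: np.ndarray,
    idx_rna: np.ndarray,
    res_atoms: np.ndarray,
    h_idx: int | None,
    distance: float,
) -> None:
    """Rigidly move the ligand residue so the contact geometry is exact."""
    if contact.kind == "hbond":
        donor = coords[idx_protein[0]]
        hydrogen = coords[h_idx]
        u = hydrogen - donor
        u = u / np.linalg.norm(u)
        _orient_residue(coords, res_atoms, coords[idx_rna[0]], u)
        delta = (donor + distance * u) - coords[idx_rna[0]]
        coords[res_atoms] += delta
    elif contact.kind == "ch_pi":
        ca = coords[idx_protein].mean(axis=0)
        cb = coords[idx_rna].mean(axis=0)
        u = _elevated(cb - ca)
        _orient_residue(coords, res_atoms, cb, u)
        cb = coords[idx_rna].mean(axis=0)
        coords[res_atoms] += (ca + distance * u) - cb
    else:  # salt_bridge: minimum cross-pair distance, solved along the
        # approach axis (the min-pair identity may switch as the residue
        # moves, so a scalar root-find beats iterating on the closest pair)
        from scipy.optimize import brentq

        a_pos = coords[idx_protein]
        ca = a_pos.mean(axis=0)
        u = _elevated(coords[idx_rna].mean(axis=0) - ca)
        _orient_residue(coords, res_atoms, coords[idx_rna].mean(axis=0), u)
        # slide the ligand group's centroid along the ray ca + t*u: at t -> 0
        # the groups touch, at large t they separate, so a root is bracketed
        shift0 = ca - coords[idx_rna].mean(axis=0)
        base_b = coords[idx_rna] + shift0
        base_res = coords[res_atoms] + shift0

        def min_dist(t: float) -> float:
            moved = base_b + t * u
            return float(
                np.linalg.norm(a_pos[:, None, :] - moved[None, :, :], axis=-1).min()
            )

        if min_dist(0.0) >= distance:
            raise ValueError(
                f"infeasible geometry: salt-bridge target {distance} Å is "
                "smaller than the contact groups' own extent"
            )
        hi = distance + 1.0
        while min_dist(hi) < distance:
            hi += 1.0
        t_star = brentq(lambda t: min_dist(t) - distance, 0.0, hi, xtol=1e-12)
        coords[res_atoms] = base_res + t_star * u


def gen_toy_complex(spec: ComplexSpec) -> ToySystem:
    """Build a toy protein–RNA complex realizing each contact in exactly
    ``round(on_fraction * n_frames)`` seed-chosen frames."""
    (names, elements, chains, resids, resns,
     charges, rmin, eps, born, group, base) = _base_geometry(spec)

    scaffold = ToySystem(
        names=names, elements=elements, chain_ids=chains, residue_ids=resids,
        residue_names=resns, charges=charges, rmin_half=rmin, epsilon=eps,
        born_radius=born, group=group, coords=base[None, :, :],
        temperature=spec.temperature,
    )

    # resolve selectors once against the scaffold
    resolved = []
    touched: set[tuple[str, int]] = set()
    for contact in spec.contact_pairs:
        idx_p = parse_selection(scaffold, contact.protein)
        idx_r = parse_selection(scaffold, contact.rna)
        if np.any(scaffold.group[idx_p] != "receptor"):
            raise ValueError(f"{contact.protein!r} must select receptor atoms")
        if np.any(scaffold.group[idx_r] != "ligand"):
            raise ValueError(f"{contact.rna!r} must select ligand atoms")
        res_key = (str(scaffold.chain_ids[idx_r[0]]), int(scaffold.residue_ids[idx_r[0]]))
        if res_key in touched:
            raise ValueError(
                f"contacts must target distinct ligand residues; {res_key} reused"
            )
        touched.add(res_key)
        h_idx = None
        if contact.kind == "hbond":
            if len(idx_p) != 1 or len(idx_r) != 1:
                raise ValueError("hbond selectors must resolve to single atoms")
            h_idx = _donor_hydrogen(scaffold, int(idx_p[0]))
        res_atoms = _residue_atoms(scaffold, *res_key)
        resolved.append((contact, idx_p, idx_r, res_atoms, h_idx))

    # frame membership, one independent stream per contact
    on_sets = []
    for k, contact in enumerate(spec.contact_pairs):
        n_on = int(round(contact.on_fraction * spec.n_frames))
        rng_k = np.random.default_rng([spec.seed, 7919, k])
        on = np.zeros(spec.n_frames, dtype=bool)
        if n_on > 0:
            on[rng_k.choice(spec.n_frames, size=n_on, replace=False)] = True
        on_sets.append(on)

    rng = np.random.default_rng([spec.seed, 104729])
    frames = np.empty((spec.n_frames, len(names), 3))
    for f in range(spec.n_frames):
        coords = base.copy()
        if spec.jitter_sigma > 0:
            coords += rng.normal(0.0, spec.jitter_sigma, size=coords.shape)
        for (contact, idx_p, idx_r, res_atoms, h_idx), on in zip(resolved, on_sets):
            d = contact.target_distance if on[f] else contact.target_distance + 6.0
            _realize_contact(coords, contact, idx_p, idx_r, res_atoms, h_idx, d)
        frames[f] = coords

    system = ToySystem(
        names=names, elements=elements, chain_ids=chains, residue_ids=resids,
        residue_names=resns, charges=charges, rmin_half=rmin, epsilon=eps,
        born_radius=born, group=group, coords=frames,
        temperature=spec.temperature,
    )

    # hard-sphere feasibility on the first frame
    rec = system.coords[0][system.receptor_mask]
    lig = system.coords[0][system.ligand_mask]
    dmin = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=-1).min()
    if dmin < _MIN_HEAVY_SEPARATION:
        raise ValueError(
            f"infeasible geometry: cross-partition atoms overlap (min {dmin:.2f} Å)"
        )
    return system


# ---------------------------------------------------------------------------
# FEP samples
# ---------------------------------------------------------------------------


def gen_fep_samples(
    k_wt: float,
    k_mut: float,
    lambdas: np.ndarray | None = None,
    n_per_window: int = 1000,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> FepDataset:
    """Exact Boltzmann samples of the harmonic mutation toy.

    The mixed potential is ``V_lam(x) = (1-lam)·½k_wt·x² + lam·½k_mut·x²``,
    a Gaussian with variance ``kT / k_lam``; each of the first ``m-1``
    schedule points gets ``n_per_window`` samples with both ``V_lam`` and
    ``V_{lam+dlam}`` recorded.
    """
    if k_wt <= 0 or k_mut <= 0:
        raise ValueError("force constants must be > 0")
    if lambdas is None:
        lambdas = np.linspace(0.0, 1.0, 11)
    lambdas = np.asarray(lambdas, dtype=float)
    kt = KB * temperature
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(len(lambdas) - 1):
        lam, lam_next = lambdas[i], lambdas[i + 1]
        k_lam = (1.0 - lam) * k_wt + lam * k_mut
        k_next = (1.0 - lam_next) * k_wt + lam_next * k_mut
        x = rng.normal(0.0, np.sqrt(kt / k_lam), size=n_per_window)
        windows.append((0.5 * k_lam * x * x, 0.5 * k_next * x * x))
    return FepDataset(
        lambdas=lambdas,
        windows=windows,
        temperature=temperature,
        n_per_window=n_per_window,
    )
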