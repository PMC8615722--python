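"""Trajectory-level geometric analyses.

Coordinate RMSD/RMSF with Kabsch superposition, hydrogen-bond occupancy
against a distance + angle criterion, group-distance series and histograms,
and lowest-energy frame selection.  Selectors use the compact
``chain:resi:atoms`` expressions of :mod:`endstate.selections`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io import ToySystem
from .selections import parse_selection

__all__ = [
    "HBondCriterion",
    "HBondResult",
    "DistanceSpec",
    "DistanceResult",
    "rmsd_series",
    "rmsf_coords",
    "hbond_occupancy",
    "distance_series",
    "lowest_energy_frame",
]

DEFAULT_HBOND_DISTANCE = 3.5  # Å, donor-acceptor heavy-atom cutoff
DEFAULT_HBOND_ANGLE = 135.0  # degrees, donor-H-acceptor minimum


@dataclass(frozen=True)
class HBondCriterion:
    donor: str  # selector, single heavy atom
    acceptor: str  # selector, single heavy atom
    hydrogen: str | None = None  # selector; auto-detected when omitted
    max_distance: float = DEFAULT_HBOND_DISTANCE
    min_angle: float = DEFAULT_HBOND_ANGLE

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if not (0.0 <= self.min_angle <= 180.0):
            raise ValueError("min_angle must be in [0, 180]")


@dataclass
class HBondResult:
    occupancy: float  # percent of frames satisfying the criterion
    mean_distance: float  # Å, averaged over ALL frames
    mean_angle: float  # degrees, averaged over ALL frames
    distances: np.ndarray
    angles: np.ndarray


@dataclass(frozen=True)
class DistanceSpec:
    group_a: str
    group_b: str
    mode: str = "min_atom_pair"  # or "centroid"

    def __post_init__(self) -> None:
        if self.mode not in ("min_atom_pair", "centroid"):
            raise ValueError(f"unknown distance mode {self.mode!r}")


@dataclass
class DistanceResult:
    series: np.ndarray  # Å, one value per frame
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.series.mean())


# ---------------------------------------------------------------------------
# superposition diagnostics
# ---------------------------------------------------------------------------


def _check_mask_geometry(ref: np.ndarray) -> None:
    if len(ref) < 3:
        raise ValueError("superposition mask needs at least 3 atoms")
    centered = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) superposition mask")


def _superpose(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``ref`` (Kabsch)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsd_series(
    system: ToySystem, reference: int = 0, mask=None
) -> np.ndarray:
    """Per-frame RMSD (Å) of the masked atoms after optimal superposition
    onto the reference frame."""
    idx = _mask_indices(system, mask)
    ref = system.coords[reference, idx]
    _check_mask_geometry(ref)
    out = np.empty(system.n_frames)
    for f in range(system.n_frames):
        fitted = _superpose(system.coords[f, idx], ref)
        out[f] = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return out


def rmsf_coords(system: ToySystem, mask=None) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean structure after per-frame alignment."""
    if system.n_frames < 2:
        raise ValueError("need at least 2 frames for RMSF")
    idx = _mask_indices(system, mask)
    ref = system.coords[0, idx]
    _check_mask_geometry(ref)
    aligned = np.stack(
        [_superpose(system.coords[f, idx], ref) for f in range(system.n_frames)]
    )
    mean = aligned.mean(axis=0)
    aligned = np.stack([_superpose(a, mean) for a in aligned])
    mean = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


def _mask_indices(system: ToySystem, mask) -> np.ndarray:
    if mask is None:
        return np.arange(system.n_atoms)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return np.nonzero(mask)[0]
    return mask.astype(int)


# ---------------------------------------------------------------------------
# hydrogen bonds and distances
# ---------------------------------------------------------------------------


def _single_atom(system: ToySystem, expr: str) -> int:
    idx = parse_selection(system, expr)
    if len(idx) != 1:
        raise ValueError(f"selector {expr!r} must resolve to exactly one atom")
    return int(idx[0])


def _auto_hydrogen(system: ToySystem, donor: int) -> int:
    chain = system.chain_ids[donor]
    resi = system.residue_ids[donor]
    same_res = np.nonzero(
        (system.chain_ids == chain)
        & (system.residue_ids == resi)
        & (system.elements == "H")
    )[0]
    if len(same_res) == 0:
        raise ValueError(
            f"donor {chain}:{resi}:{system.names[donor]} has no hydrogen"
        )
    d = np.linalg.norm(
        system.coords[0, same_res] - system.coords[0, donor], axis=1
    )
    return int(same_res[np.argmin(d)])


def hbond_occupancy(system: ToySystem, criterion: HBondCriterion) -> HBondResult:
    """Occupancy (%), plus all-frame mean donor–acceptor distance and
    donor–H···acceptor angle, of one hydrogen-bond criterion."""
    donor = _single_atom(system, criterion.donor)
    acceptor = _single_atom(system, criterion.acceptor)
    hydrogen = (
        _single_atom(system, criterion.hydrogen)
        if criterion.hydrogen is not None
        else _auto_hydrogen(system, donor)
    )
    dpos = system.coords[:, donor]
    apos = system.coords[:, acceptor]
    hpos = system.coords[:, hydrogen]
    distances = np.linalg.norm(apos - dpos, axis=1)
    v1 = dpos - hpos
    v2 = apos - hpos
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    satisfied = (distances <= criterion.max_distance) & (
        angles >= criterion.min_angle
    )
    return HBondResult(
        occupancy=100.0 * float(satisfied.mean()),
        mean_distance=float(distances.mean()),
        mean_angle=float(angles.mean()),
        distances=distances,
        angles=angles,
    )


def distance_series(
    system: ToySystem, spec: DistanceSpec, bin_width: float = 0.2
) -> DistanceResult:
    """Per-frame group distance plus a fixed-width histogram."""
    ia = parse_selection(system, spec.group_a)
    ib = parse_selection(system, spec.group_b)
    series = np.empty(system.n_frames)
    for f in range(system.n_frames):
        a = system.coords[f, ia]
        b = system.coords[f, ib]
        if spec.mode == "centroid":
            series[f] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        else:
            series[f] = np.linalg.norm(
                a[:, None, :] - b[None, :, :], axis=-1
            ).min()
    lo = np.floor(series.min() / bin_width) * bin_width
    hi = np.ceil(series.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(series, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    return DistanceResult(series=series, bin_edges=edges, counts=counts)


def lowest_energy_frame(dh_series) -> int:
    """Index of the minimum of a per-frame energy series; ties go earliest."""
    arr = np.asarray(dh_series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty energy series")
    return int(np.argmin(arr))
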