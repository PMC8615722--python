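"""Free-energy perturbation over a coupling-parameter schedule.

The relative free energy is accumulated as a sum of per-window exponential
averages, ``dG_lam = -kT ln < exp(-(V_{lam+dlam} - V_lam)/kT) >_lam``, over a
strictly increasing schedule from 0 to 1.  A Beutler-form softcore mixing
rule is provided for pair potentials whose end-state parameters differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import COULOMB_CONSTANT, KB

__all__ = [
    "FepDataset",
    "FepResult",
    "PairParams",
    "window_dg",
    "total_ddg",
    "softcore_pair",
]

SOFTCORE_ALPHA = 0.5


@dataclass
class FepDataset:
    """Per-window samples of the mixed potential and its forward perturbation."""

    lambdas: np.ndarray
    windows: list[tuple[np.ndarray, np.ndarray]]
    temperature: float
    n_per_window: int

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.lambdas) < 2:
            raise ValueError("schedule needs at least two lambda values")
        if not np.all(np.diff(self.lambdas) > 0):
            raise ValueError("lambda schedule must be strictly increasing")
        if not (self.lambdas[0] == 0.0 and self.lambdas[-1] == 1.0):
            raise ValueError("lambda schedule must start at 0 and end at 1")
        if len(self.windows) != len(self.lambdas) - 1:
            raise ValueError(
                f"expected {len(self.lambdas) - 1} sampled windows, "
                f"got {len(self.windows)}"
            )
        for v, v_next in self.windows:
            if len(v) != self.n_per_window or len(v_next) != self.n_per_window:
                raise ValueError("all windows must hold n_per_window samples")


@dataclass
class FepResult:
    per_window_dg: np.ndarray
    per_window_sd: np.ndarray
    total: float

    def __post_init__(self) -> None:
        if abs(self.total - float(np.sum(self.per_window_dg))) > 1e-9:
            raise ValueError("total must equal the sum of per-window values")


def window_dg(
    samples_v_lam: np.ndarray,
    samples_v_next: np.ndarray,
    temperature: float,
) -> float:
    """Exponential-average free energy of one window (kcal/mol)."""
    v0 = np.asarray(samples_v_lam, dtype=float)
    v1 = np.asarray(samples_v_next, dtype=float)
    if v0.shape != v1.shape or v0.ndim != 1:
        raise ValueError("window samples must be 1-D arrays of equal length")
    if len(v0) < 10:
        raise ValueError("need at least 10 samples per window")
    dv = v1 - v0
    if not np.all(np.isfinite(dv)):
        raise ValueError("non-finite perturbation energies")
    kt = KB * temperature
    return float(-kt * (logsumexp(-dv / kt) - np.log(len(dv))))


def total_ddg(dataset: FepDataset) -> FepResult:
    """Sum window free energies over the schedule."""
    dgs = np.array(
        [
            window_dg(v, v_next, dataset.temperature)
            for v, v_next in dataset.windows
        ]
    )
    sds = np.array([float(np.std(v_next - v)) for v, v_next in dataset.windows])
    return FepResult(per_window_dg=dgs, per_window_sd=sds, total=float(dgs.sum()))


# ---------------------------------------------------------------------------
# softcore pair mixing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairParams:
    """End-state nonbonded parameters of one atom pair.

    ``epsilon`` (kcal/mol) and ``rmin`` (Å) define the Lennard-Jones well;
    ``q_prod`` is the product of the two partial charges (e²).
    """

    epsilon: float
    rmin: float
    q_prod: float


def _lj(p: PairParams, r: float) -> float:
    if p.epsilon == 0.0:
        return 0.0
    x = (p.rmin / r) ** 6
    return p.epsilon * (x * x - 2.0 * x)


def _lj_soft(p: PairParams, lam_off: float, r: float) -> float:
    """Beutler softcore LJ: exact LJ at lam_off=0, finite at r=0 otherwise."""
    if p.epsilon == 0.0:
        return 0.0
    sigma6 = p.rmin**6 / 2.0  # sigma^6 with rmin = 2^(1/6) sigma
    denom = SOFTCORE_ALPHA * lam_off + r**6 / sigma6
    return 4.0 * p.epsilon * (1.0 / denom**2 - 1.0 / denom)


def softcore_pair(wt: PairParams, mut: PairParams, lam: float, r: float) -> float:
    """Mixed pair energy at coupling ``lam``.

    Identical end-state parameters mix linearly (equivalently, are left
    unchanged); differing parameters use softcore LJ with the electrostatic
    term evaluated on the softened distance, so the value stays finite at
    r = 0 for interior ``lam`` while reproducing each end state exactly at
    ``lam`` = 0 and 1.
    """
    if r < 0:
        raise ValueError("r must be >= 0")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must be in [0, 1]")
    if wt == mut:
        if r == 0.0:
            raise ValueError("coincident atoms with unmodified pair potential")
        return _lj(wt, r) + COULOMB_CONSTANT * wt.q_prod / r

    lj = (1.0 - lam) * _lj_soft(wt, lam, r) + lam * _lj_soft(mut, 1.0 - lam, r)
    q_prod = (1.0 - lam) * wt.q_prod + lam * mut.q_prod
    sigma6 = max(wt.rmin, mut.rmin, 1.0) ** 6 / 2.0
    r_soft = (SOFTCORE_ALPHA * lam * (1.0 - lam) * sigma6 + r**6) ** (1.0 / 6.0)
    if r_soft == 0.0:
        raise ValueError("coincident atoms at an endpoint state")
    return lj + COULOMB_CONSTANT * q_prod / r_soft
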