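"""Single-trajectory end-state binding enthalpy.

Every frame of the complex trajectory is reused for the unbound receptor and
ligand, so each term of the enthalpy is a difference
``E(complex) - E(receptor) - E(ligand)`` evaluated on the same coordinates;
the gas-phase differences then reduce exactly to the cross-partition pair
sums and internal bonded terms cancel by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_BETA,
    DEFAULT_EPS_SOLVENT,
    DEFAULT_GAMMA,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
)
from .energetics import frame_energies
from .io import ToySystem

__all__ = ["EnthalpySummary", "enthalpy_series", "per_residue_decomposition", "key_residues"]

TERMS = ("vdw", "ele", "gb", "np")


@dataclass
class EnthalpySummary:
    """Aggregated binding enthalpy over a frame window."""

    mean_dh: float
    sem_dh: float
    term_means: dict[str, float]
    per_residue_means: pd.DataFrame
    n_frames: int


def _resolve_frames(system: ToySystem, frames) -> list[int]:
    if frames is None:
        out = list(range(system.n_frames))
    else:
        out = [int(f) for f in frames]
    if not out:
        raise ValueError("empty frame window")
    return out


def enthalpy_series(
    system: ToySystem,
    frames: Iterable[int] | None = None,
    eps_solvent: float = DEFAULT_EPS_SOLVENT,
    probe: float = DEFAULT_PROBE_RADIUS,
    sasa_points: int = DEFAULT_SASA_POINTS,
    gamma: float = DEFAULT_GAMMA,
    beta: float = DEFAULT_BETA,
) -> tuple[pd.DataFrame, EnthalpySummary]:
    """Per-frame binding enthalpy terms plus their aggregation.

    Returns a frame table with columns ``frame, vdw, ele, gb, np, dh`` and an
    :class:`EnthalpySummary` whose per-residue means carry the term splits
    (``vdw``, ``ele``, ``gb``, ``np``, ``ele_plus_gb``, ``total``).
    """
    frame_list = _resolve_frames(system, frames)
    kwargs = dict(
        eps_solvent=eps_solvent,
        probe=probe,
        sasa_points=sasa_points,
        gamma=gamma,
        beta=beta,
    )
    rows = []
    per_res_acc: pd.DataFrame | None = None
    rec = system.receptor_mask
    lig = system.ligand_mask
    for f in frame_list:
        fe_c = frame_energies(system, f, None, **kwargs)
        fe_r = frame_energies(system, f, rec, **kwargs)
        fe_l = frame_energies(system, f, lig, **kwargs)
        d = {
            "vdw": fe_c.e_vdw - fe_r.e_vdw - fe_l.e_vdw,
            "ele": fe_c.e_ele - fe_r.e_ele - fe_l.e_ele,
            "gb": fe_c.g_gb - fe_r.g_gb - fe_l.g_gb,
            "np": fe_c.g_np - fe_r.g_np - fe_l.g_np,
        }
        rows.append({"frame": f, **d, "dh": sum(d.values())})
        sub = pd.concat([fe_r.per_residue, fe_l.per_residue])
        delta = fe_c.per_residue.sub(sub.reindex(fe_c.per_residue.index))
        per_res_acc = delta if per_res_acc is None else per_res_acc + delta

    table = pd.DataFrame(rows)
    per_res = per_res_acc / len(frame_list)
    per_res["ele_plus_gb"] = per_res["ele"] + per_res["gb"]
    per_res["total"] = per_res[list(TERMS)].sum(axis=1)

    dh = table["dh"].to_numpy()
    sem = float(np.std(dh, ddof=1) / np.sqrt(len(dh))) if len(dh) > 1 else 0.0
    summary = EnthalpySummary(
        mean_dh=float(dh.mean()),
        sem_dh=sem,
        term_means={t: float(table[t].mean()) for t in TERMS},
        per_residue_means=per_res,
        n_frames=len(frame_list),
    )
    return table, summary


def per_residue_decomposition(
    system: ToySystem,
    frames: Iterable[int] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Mean per-residue binding contribution, split by energy term."""
    _, summary = enthalpy_series(system, frames, **kwargs)
    return summary.per_residue_means


def key_residues(per_residue_means: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Residues whose mean total contribution is at least as favorable as
    ``threshold`` (a negative number), sorted most favorable first."""
    if threshold >= 0:
        raise ValueError("threshold must be negative (favorable contributions)")
    hits = per_residue_means[per_residue_means["total"] <= threshold]
    return hits.sort_values("total")
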