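"""Domain types and on-disk representations.

Coordinate models travel as multi-model PDB text (one ``MODEL``/``ENDMDL``
block per frame).  Per-atom parameters (partial charge, Lennard-Jones
parameters, intrinsic Born radius, receptor/ligand group) travel as a
delimited text table keyed by ``(chain, resi, atom)``.  Interaction-energy
time series are two-column delimited text.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "AtomRecord",
    "ToySystem",
    "EnergySeries",
    "ResultTable",
    "PARAM_COLUMNS",
    "read_models",
    "write_models",
    "read_energy_series",
    "write_energy_series",
]

PARAM_COLUMNS = [
    "chain",
    "resi",
    "resn",
    "atom",
    "charge",
    "rmin_half",
    "epsilon",
    "born_radius",
    "group",
]

GROUPS = ("receptor", "ligand")


@dataclass(frozen=True)
class AtomRecord:
    """A single atom with coordinates (first frame) and nonbonded parameters."""

    atom_id: int
    name: str
    element: str
    chain_id: str
    residue_name: str
    residue_index: int
    coords: np.ndarray
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    born_radius: float
    group: str

    def __post_init__(self) -> None:
        if self.born_radius <= 0:
            raise ValueError(f"atom {self.name}: born_radius must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.group not in GROUPS:
            raise ValueError(f"atom {self.name}: group must be one of {GROUPS}")


@dataclass
class ToySystem:
    """A receptor/ligand complex with per-atom parameters and coordinate frames.

    Attributes
    ----------
    names, elements, chain_ids, residue_names : arrays of str, length n_atoms
    residue_ids : int array, 1-based per chain
    charges, rmin_half, epsilon, born_radius : float arrays (e, Å, kcal/mol, Å)
    group : str array, each entry ``"receptor"`` or ``"ligand"``
    coords : float array of shape (n_frames, n_atoms, 3), Å
    temperature : analysis temperature, K
    """

    names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    charges: np.ndarray
    rmin_half: np.ndarray
    epsilon: np.ndarray
    born_radius: np.ndarray
    group: np.ndarray
    coords: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in (
            "elements",
            "chain_ids",
            "residue_ids",
            "residue_names",
            "charges",
            "rmin_half",
            "epsilon",
            "born_radius",
            "group",
        ):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr}: expected length {n}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n, 3):
            raise ValueError(
                f"coords must have shape (n_frames, {n}, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("at least one coordinate frame is required")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.born_radius <= 0):
            raise ValueError("born_radius must be > 0 for every atom")
        if np.any(self.epsilon < 0):
            raise ValueError("lj epsilon must be >= 0 for every atom")
        bad = set(np.unique(self.group)) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        keys = list(zip(self.chain_ids, self.residue_ids, self.names))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue, atom name) keys are not unique")

    # -- convenience ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def receptor_mask(self) -> np.ndarray:
        return self.group == "receptor"

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.group == "ligand"

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, residue_index) keys in atom order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.residue_ids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def atom_records(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                atom_id=i + 1,
                name=str(self.names[i]),
                element=str(self.elements[i]),
                chain_id=str(self.chain_ids[i]),
                residue_name=str(self.residue_names[i]),
                residue_index=int(self.residue_ids[i]),
                coords=self.coords[0, i].copy(),
                charge=float(self.charges[i]),
                lj_rmin_half=float(self.rmin_half[i]),
                lj_epsilon=float(self.epsilon[i]),
                born_radius=float(self.born_radius[i]),
                group=str(self.group[i]),
            )
            for i in range(self.n_atoms)
        ]

    def parameter_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": self.chain_ids,
                "resi": self.residue_ids,
                "resn": self.residue_names,
                "atom": self.names,
                "charge": self.charges,
                "rmin_half": self.rmin_half,
                "epsilon": self.epsilon,
                "born_radius": self.born_radius,
                "group": self.group,
            }
        )


@dataclass
class EnergySeries:
    """A time-stamped energy series (ps, kcal/mol)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in energy series")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, start: int, stop: int) -> "EnergySeries":
        return EnergySeries(self.times[start:stop], self.values[start:stop], self.label)


@dataclass
class ResultTable:
    """Long-format result rows keyed by (system, trajectory, quantity).

    Quantities follow the summary-table convention: ``dH``, ``minus_TdS`` and
    ``dG`` rows per trajectory, with ``dG = dH + minus_TdS``.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["system", "trajectory", "quantity", "value", "stderr"]
        )
    )

    def add(
        self,
        system: str,
        trajectory: str,
        quantity: str,
        value: float,
        stderr: float = float("nan"),
    ) -> None:
        self.frame.loc[len(self.frame)] = [system, trajectory, quantity, value, stderr]

    def validate_consistency(self, tol: float = 0.05) -> None:
        """Check dG = dH + minus_TdS within ``tol`` after 0.1 rounding."""
        pivot = self.frame.pivot_table(
            index=["system", "trajectory"], columns="quantity", values="value"
        )
        needed = {"dH", "minus_TdS", "dG"}
        if not needed.issubset(pivot.columns):
            return
        resid = (
            pivot["dG"].round(1) - (pivot["dH"].round(1) + pivot["minus_TdS"].round(1))
        ).abs()
        bad = resid[resid > tol]
        if len(bad):
            raise ValueError(f"inconsistent dG rows: {bad.to_dict()}")

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_param_table(params_text: str) -> pd.DataFrame:
    table = pd.read_csv(_io.StringIO(params_text))
    missing = set(PARAM_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parameter table is missing columns: {sorted(missing)}")
    return table


def read_models(pdb_text: str, params_text: str) -> ToySystem:
    """Build a :class:`ToySystem` from multi-model PDB text + a parameter table.

    Every PDB atom must have a matching parameter row keyed by
    ``(chain, resi, atom)``; frames follow ``MODEL`` record order and the
    receptor/ligand partition is taken from the table's ``group`` column.
    """
    pdb_file = _pdb.PDBFile.read(_io.StringIO(pdb_text))
    try:
        stack = pdb_file.get_structure(model=None, altloc="all")
    except Exception as err:  # biotite raises its own error types
        raise ValueError(f"malformed multi-model PDB: {err}") from err
    if np.any(stack.altloc_id != " "):
        raise ValueError("alternate locations are not supported")
    if np.any(stack.ins_code != ""):
        raise ValueError("insertion codes are not supported")

    table = _read_param_table(params_text)
    lookup = {
        (str(row.chain), int(row.resi), str(row.atom)): row
        for row in table.itertuples(index=False)
    }
    n = stack.array_length()
    charges = np.empty(n)
    rmin_half = np.empty(n)
    epsilon = np.empty(n)
    born = np.empty(n)
    group = np.empty(n, dtype=object)
    resn = np.empty(n, dtype=object)
    for i in range(n):
        key = (str(stack.chain_id[i]), int(stack.res_id[i]), str(stack.atom_name[i]))
        row = lookup.get(key)
        if row is None:
            raise ValueError(
                "no parameter row for atom "
                f"chain={key[0]} residue={key[1]} name={key[2]}"
            )
        charges[i] = row.charge
        rmin_half[i] = row.rmin_half
        epsilon[i] = row.epsilon
        born[i] = row.born_radius
        group[i] = str(row.group)
        resn[i] = str(row.resn)
    return ToySystem(
        names=stack.atom_name.astype(object),
        elements=stack.element.astype(object),
        chain_ids=stack.chain_id.astype(object),
        residue_ids=stack.res_id.astype(int),
        residue_names=np.asarray(resn, dtype=object),
        charges=charges,
        rmin_half=rmin_half,
        epsilon=epsilon,
        born_radius=born,
        group=np.asarray(group, dtype=object),
        coords=stack.coord.astype(float),
    )


def write_models(system: ToySystem) -> tuple[str, str]:
    """Serialize a system to (multi-model PDB text, parameter-table CSV text)."""
    arrays = []
    for f in range(system.n_frames):
        arr = struc.AtomArray(system.n_atoms)
        arr.coord = system.coords[f]
        arr.chain_id = np.asarray(system.chain_ids, dtype="U4")
        arr.res_id = np.asarray(system.residue_ids, dtype=int)
        arr.res_name = np.asarray(system.residue_names, dtype="U5")
        arr.atom_name = np.asarray(system.names, dtype="U6")
        arr.element = np.asarray(system.elements, dtype="U2")
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    buf = _io.StringIO()
    pdb_file.write(buf)
    params = system.parameter_table().to_csv(index=False, float_format="%.6f")
    return buf.getvalue(), params


def read_energy_series(csv_text: str, label: str = "") -> EnergySeries:
    """Parse a two-column (time, energy) delimited text; header optional."""
    first = csv_text.lstrip().splitlines()[0] if csv_text.strip() else ""
    has_header = any(c.isalpha() for c in first.replace("e", "").replace("E", ""))
    table = pd.read_csv(
        _io.StringIO(csv_text),
        header=0 if has_header else None,
        sep=None,
        engine="python",
    )
    if table.shape[1] < 2:
        raise ValueError("expected two columns (time, energy)")
    times = pd.to_numeric(table.iloc[:, 0], errors="coerce").to_numpy()
    values = pd.to_numeric(table.iloc[:, 1], errors="coerce").to_numpy()
    finite = np.isfinite(times) & np.isfinite(values)
    if not np.all(finite):
        raise ValueError("non-finite rows in energy series")
    if len(times) < 2:
        raise ValueError("energy series needs at least 2 rows")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing (duplicate or reversed)")
    return EnergySeries(times, values, label)


def write_energy_series(series: EnergySeries) -> str:
    """Serialize with a fixed numeric format so write→read→write is stable."""
    lines = ["time,energy"]
    lines += [f"{t:.6f},{v:.6f}" for t, v in zip(series.times, series.values)]
    return "\n".join(lines) + "\n"


def write_fep_dataset(dataset, directory) -> None:
    """Write a FEP dataset as one CSV per sampled window plus a schedule file."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "schedule.json").write_text(
        json.dumps(
            {
                "lambdas": [float(x) for x in dataset.lambdas],
                "temperature": dataset.temperature,
                "n_per_window": dataset.n_per_window,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    for i, (v, v_next) in enumerate(dataset.windows):
        lines = ["v_lambda,v_lambda_next"]
        lines += [f"{a:.8f},{b:.8f}" for a, b in zip(v, v_next)]
        (directory / f"window_{i:02d}.csv").write_text("\n".join(lines) + "\n")


def read_fep_dataset(directory):
    """Read a FEP dataset directory written by :func:`write_fep_dataset`."""
    import json
    from pathlib import Path

    from .fep import FepDataset

    directory = Path(directory)
    schedule = json.loads((directory / "schedule.json").read_text())
    lambdas = np.asarray(schedule["lambdas"], dtype=float)
    windows = []
    for i in range(len(lambdas) - 1):
        path = directory / f"window_{i:02d}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing FEP window file {path}")
        table = pd.read_csv(path)
        windows.append(
            (table["v_lambda"].to_numpy(), table["v_lambda_next"].to_numpy())
        )
    return FepDataset(
        lambdas=lambdas,
        windows=windows,
        temperature=float(schedule["temperature"]),
        n_per_window=int(schedule["n_per_window"]),
    )
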