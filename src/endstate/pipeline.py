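"""Pipeline orchestration: config model, full run, and demo fixtures.

A run takes one or more systems (toy complex + per-trajectory energy
series), applies the window-selection → outlier-filter → interaction-entropy
chain to each series, computes the end-state enthalpy from the complex
frames, and emits summary, per-residue, hydrogen-bond and distance tables
plus a manifest recording every default applied.  Output is deterministic
for a given config + seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .constants import (
    DEFAULT_BETA,
    DEFAULT_EPS_SOLVENT,
    DEFAULT_GAMMA,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
    DEFAULT_TEMPERATURE,
)
from .entropy import (
    binding_free_energy,
    block_bootstrap_sd,
    filter_outliers,
    ie_entropy,
    round_half_away,
    scan_windows,
    selected_slice,
    system_average,
    average_and_ddg,
)
from .io import (
    read_energy_series,
    read_models,
    write_energy_series,
    write_fep_dataset,
    write_models,
)
from .mmgbsa import enthalpy_series
from .structure import DistanceSpec, HBondCriterion, distance_series, hbond_occupancy

__all__ = ["RunConfig", "run_pipeline", "make_fixtures"]


class GbSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eps_solvent: float = DEFAULT_EPS_SOLVENT


class SasaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    probe: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_SASA_POINTS
    gamma: float = DEFAULT_GAMMA
    beta: float = DEFAULT_BETA


class TrajectoryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    series: str
    label: str = ""


class SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    pdb: str
    params: str
    trajectories: list[TrajectoryConfig]


class PairConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wild: str
    mutant: str


class HBondConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    donor: str
    acceptor: str
    hydrogen: str | None = None
    max_distance: float = 3.5
    min_angle: float = 135.0


class DistanceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    group_a: str
    group_b: str
    mode: str = "min_atom_pair"


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    systems: list[SystemConfig]
    pairs: list[PairConfig] = Field(default_factory=list)
    hbonds: list[HBondConfig] = Field(default_factory=list)
    distances: list[DistanceConfig] = Field(default_factory=list)
    temperature: float = DEFAULT_TEMPERATURE
    window_ns: float = 10.0
    k_sigma: float = 3.0
    seed: int = 0
    gb: GbSettings = Field(default_factory=GbSettings)
    sasa: SasaSettings = Field(default_factory=SasaSettings)
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text))


def _analyze_series(series, config: RunConfig):
    window_ps = config.window_ns * 1000.0
    scan = scan_windows(series, window_ps)
    window = selected_slice(series, scan)
    kept, n_drop = filter_outliers(window, config.k_sigma)
    ie = ie_entropy(kept, config.temperature, n_discarded=n_drop)
    ie_sd = block_bootstrap_sd(kept, config.temperature, seed=config.seed)
    return ie, ie_sd


def run_pipeline(config: RunConfig, base_dir: Path | str = ".") -> dict:
    """Execute the full analysis and write all report tables.

    Returns a dict with the summary table, per-pair differences and the
    manifest.  All paths in the config resolve relative to ``base_dir``.
    """
    base = Path(base_dir)
    out = base / config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    summary_rows = []
    dg_by_system: dict[str, list[float]] = {}
    for sys_cfg in config.systems:
        try:
            pdb_text = (base / sys_cfg.pdb).read_text()
            params_text = (base / sys_cfg.params).read_text()
        except OSError as err:
            raise OSError(f"stage=load system={sys_cfg.name}: {err}") from err
        system = read_models(pdb_text, params_text)
        system.temperature = config.temperature

        _, summary = enthalpy_series(
            system,
            eps_solvent=config.gb.eps_solvent,
            probe=config.sasa.probe,
            sasa_points=config.sasa.n_points,
            gamma=config.sasa.gamma,
            beta=config.sasa.beta,
        )
        per_res = summary.per_residue_means.reset_index()
        per_res.insert(2, "resn", [
            str(system.residue_names[
                np.nonzero((system.chain_ids == c) & (system.residue_ids == r))[0][0]
            ])
            for c, r in zip(per_res["chain"], per_res["resi"])
        ])
        per_res.to_csv(
            out / f"per_residue_{sys_cfg.name}.tsv",
            sep="\t", index=False, float_format="%.6f",
        )

        dgs = []
        for k, traj in enumerate(sys_cfg.trajectories, start=1):
            label = traj.label or f"No. {k}"
            try:
                series_text = (base / traj.series).read_text()
            except OSError as err:
                raise OSError(
                    f"stage=series system={sys_cfg.name} trajectory={label}: {err}"
                ) from err
            series = read_energy_series(series_text, label=label)
            ie, ie_sd = _analyze_series(series, config)
            result = binding_free_energy(summary, ie)
            dgs.append(result.dg)
            summary_rows.append(
                {
                    "system": sys_cfg.name,
                    "trajectory": label,
                    "dH": result.dh,
                    "dH_sem": summary.sem_dh,
                    "minus_TdS": result.minus_t_delta_s,
                    "minus_TdS_sd": ie_sd,
                    "dG": result.dg,
                    "window_start_ps": ie.window[0],
                    "window_end_ps": ie.window[1],
                    "n_used": ie.n_used,
                    "n_discarded": ie.n_discarded,
                }
            )
        dg_by_system[sys_cfg.name] = dgs

        if config.hbonds:
            hb_rows = []
            for h in config.hbonds:
                try:
                    res = hbond_occupancy(
                        system,
                        HBondCriterion(
                            donor=h.donor,
                            acceptor=h.acceptor,
                            hydrogen=h.hydrogen,
                            max_distance=h.max_distance,
                            min_angle=h.min_angle,
                        ),
                    )
                except ValueError:
                    continue  # selector not present in this system
                hb_rows.append(
                    {
                        "donor": h.donor,
                        "acceptor": h.acceptor,
                        "occupancy_pct": res.occupancy,
                        "mean_distance_A": res.mean_distance,
                        "mean_angle_deg": res.mean_angle,
                    }
                )
            pd.DataFrame(hb_rows).to_csv(
                out / f"hbonds_{sys_cfg.name}.tsv",
                sep="\t", index=False, float_format="%.4f",
            )

        if config.distances:
            d_rows = []
            for d in config.distances:
                try:
                    res = distance_series(
                        system, DistanceSpec(d.group_a, d.group_b, d.mode)
                    )
                except ValueError:
                    continue
                d_rows.append(
                    {
                        "group_a": d.group_a,
                        "group_b": d.group_b,
                        "mode": d.mode,
                        "mean_distance_A": res.mean,
                    }
                )
            pd.DataFrame(d_rows).to_csv(
                out / f"distances_{sys_cfg.name}.tsv",
                sep="\t", index=False, float_format="%.4f",
            )

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.6f")

    # rounded report table plus per-system averages
    report_rows = []
    for row in summary_rows:
        report_rows.append(
            {
                "system": row["system"],
                "trajectory": row["trajectory"],
                "dH": round_half_away(row["dH"], 1),
                "minus_TdS": round_half_away(row["minus_TdS"], 1),
                "dG": round_half_away(row["dG"], 1),
            }
        )
    for name, dgs in dg_by_system.items():
        report_rows.append(
            {
                "system": name,
                "trajectory": "Ave",
                "dH": "",
                "minus_TdS": "",
                "dG": system_average(dgs),
            }
        )
    pd.DataFrame(report_rows).to_csv(out / "report.tsv", sep="\t", index=False)

    pair_rows = []
    for pair in config.pairs:
        if pair.wild not in dg_by_system or pair.mutant not in dg_by_system:
            raise ValueError(f"pair references unknown system: {pair}")
        avg = average_and_ddg(dg_by_system[pair.wild], dg_by_system[pair.mutant])
        pair_rows.append(
            {
                "wild": pair.wild,
                "mutant": pair.mutant,
                "wild_avg_dG": avg.wild_average,
                "mutant_avg_dG": avg.mutant_average,
                "ddG": avg.ddg,
            }
        )
    pd.DataFrame(pair_rows).to_csv(out / "ddg.tsv", sep="\t", index=False)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "versions": {
            "endstate": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {
        "summary": summary,
        "pairs": pd.DataFrame(pair_rows),
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# demo fixtures
# ---------------------------------------------------------------------------

_FIXTURE_README = """\
Demo dataset generated by `endstate simulate`.

Contents
--------
wt.pdb / wt.params.csv      toy complex, wild-type-like contact set
mut.pdb / mut.params.csv    same scaffold with tighter contacts
{name}_traj{k}.csv          gas-phase interaction-energy series (3 per system)
fep/                        harmonic-toy FEP samples (k 1 -> 2 kcal/mol/A^2)
config.yaml                 ready-to-run pipeline configuration

Expected outcome of `endstate report --config config.yaml`
----------------------------------------------------------
- results/summary.tsv: one row per (system, trajectory) with dH, -TdS, dG
- results/report.tsv: 0.1-rounded table with per-system "Ave" rows
- results/ddg.tsv: mutant-minus-wild difference of the system averages
- results/manifest.json: every input, default and version used
"""


def make_fixtures(out_dir: Path | str, seed: int = 0) -> Path:
    """Write a complete worked example dataset; returns the directory."""
    from .synth import ComplexSpec, ContactSpec, SeriesSpec, gen_energy_series, gen_fep_samples, gen_toy_complex

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    specs = {
        "wt": ComplexSpec(
            n_protein_chains=6,
            residues_per_chain=2,
            n_rna_nucleotides=3,
            contact_pairs=(
                ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, on_fraction=0.9),
                ContactSpec("salt_bridge", "B:1:charged_group", "R:2:phosphate", 3.7, on_fraction=0.8),
                ContactSpec("ch_pi", "C:1:alkyl", "R:3:ring", 5.6, on_fraction=0.7),
            ),
            n_frames=12,
            jitter_sigma=0.03,
            seed=seed,
        ),
        "mut": ComplexSpec(
            n_protein_chains=6,
            residues_per_chain=2,
            n_rna_nucleotides=3,
            contact_pairs=(
                ContactSpec("hbond", "A:1:OH", "R:1:OP2", 2.7, on_fraction=1.0),
                ContactSpec("salt_bridge", "B:1:charged_group", "R:2:phosphate", 3.5, on_fraction=0.9),
                ContactSpec("ch_pi", "C:1:alkyl", "R:3:ring", 5.0, on_fraction=0.9),
            ),
            n_frames=12,
            jitter_sigma=0.03,
            seed=seed + 1,
        ),
    }
    means = {"wt": -60.0, "mut": -63.0}
    sigmas = [1.2, 1.5, 1.0]

    systems_cfg = []
    for name, spec in specs.items():
        system = gen_toy_complex(spec)
        pdb_text, params_text = write_models(system)
        (out / f"{name}.pdb").write_text(pdb_text)
        (out / f"{name}.params.csv").write_text(params_text)
        trajs = []
        for k, sigma in enumerate(sigmas, start=1):
            series = gen_energy_series(
                SeriesSpec(
                    n_points=4000,
                    dt=1.0,
                    mean=means[name],
                    sigma=sigma,
                    autocorrelation_time=2.0,
                    outlier_fraction=0.002,
                    outlier_scale=8.0,
                    seed=seed * 100 + k + (0 if name == "wt" else 50),
                    label=f"{name}-{k}",
                )
            )
            fname = f"{name}_traj{k}.csv"
            (out / fname).write_text(write_energy_series(series))
            trajs.append({"series": fname})
        systems_cfg.append(
            {
                "name": name,
                "pdb": f"{name}.pdb",
                "params": f"{name}.params.csv",
                "trajectories": trajs,
            }
        )

    write_fep_dataset(
        gen_fep_samples(1.0, 2.0, n_per_window=2000, seed=seed), out / "fep"
    )

    config = {
        "systems": systems_cfg,
        "pairs": [{"wild": "wt", "mutant": "mut"}],
        "hbonds": [
            {"donor": "A:1:OH", "acceptor": "R:1:OP2", "max_distance": 3.5, "min_angle": 135.0}
        ],
        "distances": [
            {"group_a": "B:1:charged_group", "group_b": "R:2:phosphate", "mode": "min_atom_pair"},
            {"group_a": "C:1:alkyl", "group_b": "R:3:ring", "mode": "centroid"},
        ],
        "temperature": 300.0,
        "window_ns": 1.0,
        "k_sigma": 3.0,
        "seed": seed,
        "sasa": {"n_points": 120},
        "output_dir": "results",
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    (out / "README.txt").write_text(_FIXTURE_README)
    return out
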