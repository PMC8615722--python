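"""Interaction-entropy estimation from gas-phase interaction-energy series.

Workflow: scan fixed-length time windows for the one with the smallest
energy fluctuation, discard points more than k standard deviations from the
window mean (single pass), then estimate the entropic term as
``kT · ln <exp(dE/kT)>`` over the mean-centered fluctuations.  The estimate
is non-negative by Jensen's inequality and invariant under constant shifts
of the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB, DEFAULT_TEMPERATURE
from .io import EnergySeries

__all__ = [
    "WindowScan",
    "IeResult",
    "BindingResult",
    "AverageDdg",
    "scan_windows",
    "select_window",
    "filter_outliers",
    "ie_entropy",
    "binding_free_energy",
    "average_and_ddg",
    "round_half_away",
]

MIN_IE_POINTS = 100


@dataclass
class WindowScan:
    """Energy-fluctuation (RMSF) of every admissible fixed-length window."""

    window_length: float  # ps
    starts: np.ndarray  # window start times, ps
    start_indices: np.ndarray
    end_indices: np.ndarray  # exclusive
    rmsf_values: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        if np.any(self.rmsf_values < 0):
            raise ValueError("rmsf_values must be >= 0")


@dataclass
class IeResult:
    minus_t_delta_s: float  # kcal/mol, >= 0
    n_used: int
    n_discarded: int
    window: tuple[float, float]  # (start_time, end_time), ps
    convergence_trace: np.ndarray  # running estimate on growing prefixes

    def __post_init__(self) -> None:
        if self.minus_t_delta_s < 0:
            raise ValueError("minus_t_delta_s must be >= 0")


def scan_windows(series: EnergySeries, window_length: float) -> WindowScan:
    """RMSF of the energy over every window ``[t, t + window_length)``.

    RMSF is the square root of the mean squared deviation from the window
    mean.  Errors out when no full window fits in the series.
    """
    t = series.times
    v = series.values
    n = len(t)
    step = float(np.median(np.diff(t)))
    ends = np.searchsorted(t, t + window_length, side="left")
    # the window must fit inside the sampled span (one trailing sample
    # interval of slack so the final full window of a uniform series counts)
    valid = (t + window_length) <= t[-1] + step * (1.0 + 1e-9)
    valid &= (ends - np.arange(n)) >= 2
    starts_idx = np.nonzero(valid)[0]
    if len(starts_idx) == 0:
        raise ValueError("window_length longer than the series span")
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])
    i = starts_idx
    j = ends[starts_idx]
    m = (j - i).astype(float)
    mean = (c1[j] - c1[i]) / m
    var = (c2[j] - c2[i]) / m - mean * mean
    rmsf = np.sqrt(np.maximum(var, 0.0))
    return WindowScan(
        window_length=window_length,
        starts=t[starts_idx],
        start_indices=starts_idx,
        end_indices=j,
        rmsf_values=rmsf,
    )


def select_window(scan: WindowScan) -> tuple[float, float]:
    """Start/end times of the minimum-RMSF window; ties go to the earliest."""
    if len(scan.rmsf_values) == 0:
        raise ValueError("empty window scan")
    k = int(np.argmin(scan.rmsf_values))  # first occurrence on ties
    return float(scan.starts[k]), float(scan.starts[k] + scan.window_length)


def selected_slice(series: EnergySeries, scan: WindowScan) -> EnergySeries:
    """The sub-series of the minimum-RMSF window."""
    k = int(np.argmin(scan.rmsf_values))
    return series.slice(int(scan.start_indices[k]), int(scan.end_indices[k]))


def filter_outliers(
    series: EnergySeries, k_sigma: float = 3.0
) -> tuple[EnergySeries, int]:
    """Single-pass discard of points more than ``k_sigma`` SDs from the mean.

    Mean and SD are those of the input window itself; a zero-SD (constant)
    window keeps every point.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be > 0")
    v = series.values
    mean = v.mean()
    sd = v.std()
    if sd == 0.0:
        return series, 0
    keep = np.abs(v - mean) <= k_sigma * sd
    n_drop = int((~keep).sum())
    if n_drop == len(v):
        raise ValueError("outlier filter discarded every point")
    return EnergySeries(series.times[keep], series.values[keep], series.label), n_drop


def ie_entropy(
    series: EnergySeries,
    temperature: float = DEFAULT_TEMPERATURE,
    n_discarded: int = 0,
) -> IeResult:
    """Entropic term ``kT · ln <exp(dE/kT)>`` of a (filtered) energy window.

    ``dE`` is the series centered on its own mean, so the result is
    shift-invariant and non-negative.  The convergence trace holds the
    estimate on every growing prefix.
    """
    v = series.values
    if len(v) < MIN_IE_POINTS:
        raise ValueError(f"need at least {MIN_IE_POINTS} points, got {len(v)}")
    kt = KB * temperature
    de = v - v.mean()
    sd = de.std()
    if sd > 0 and abs(de.mean()) > 1e-9 * sd:
        raise AssertionError("centering failed")  # pragma: no cover
    b = de / kt
    # log of the running mean of exp(b), overflow-safe
    log_cum = np.logaddexp.accumulate(b)
    trace = kt * (log_cum - np.log(np.arange(1, len(b) + 1)))
    estimate = max(0.0, float(kt * (logsumexp(b) - math.log(len(b)))))
    return IeResult(
        minus_t_delta_s=estimate,
        n_used=len(v),
        n_discarded=n_discarded,
        window=(float(series.times[0]), float(series.times[-1])),
        convergence_trace=trace,
    )


def block_bootstrap_sd(
    series: EnergySeries,
    temperature: float = DEFAULT_TEMPERATURE,
    n_blocks: int = 50,
    n_resamples: int = 200,
    seed: int = 0,
) -> float:
    """Block-bootstrap SD of the entropy estimate (reported uncertainty)."""
    v = series.values
    blocks = np.array_split(np.arange(len(v)), n_blocks)
    blocks = [b for b in blocks if len(b)]
    rng = np.random.default_rng(seed)
    kt = KB * temperature
    out = np.empty(n_resamples)
    for r in range(n_resamples):
        pick = rng.integers(0, len(blocks), size=len(blocks))
        sample = np.concatenate([v[blocks[p]] for p in pick])
        de = sample - sample.mean()
        out[r] = kt * (logsumexp(de / kt) - math.log(len(de)))
    return float(out.std())


# ---------------------------------------------------------------------------
# assembly into binding free energies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingResult:
    dh: float
    minus_t_delta_s: float
    dg: float


@dataclass(frozen=True)
class AverageDdg:
    wild_average: float
    mutant_average: float
    ddg: float  # mutant - wild


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table-reporting convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def binding_free_energy(dh, ie) -> BindingResult:
    """Combine enthalpy and entropic terms into the binding free energy.

    Accepts plain numbers or the :class:`~endstate.mmgbsa.EnthalpySummary` /
    :class:`IeResult` objects produced upstream.
    """
    dh_val = float(getattr(dh, "mean_dh", dh))
    ts_val = float(getattr(ie, "minus_t_delta_s", ie))
    return BindingResult(dh=dh_val, minus_t_delta_s=ts_val, dg=dh_val + ts_val)


def system_average(per_trajectory_dg: "list[float]") -> float:
    """Unweighted trajectory mean, rounded to 0.1 for reporting."""
    if not per_trajectory_dg:
        raise ValueError("need at least one trajectory")
    return round_half_away(float(np.mean(per_trajectory_dg)), 1)


def average_and_ddg(
    wild_dgs: "list[float]", mutant_dgs: "list[float]"
) -> AverageDdg:
    """System averages and their mutant-minus-wild difference (0.1 rounding)."""
    wild = system_average(wild_dgs)
    mut = system_average(mutant_dgs)
    return AverageDdg(
        wild_average=wild,
        mutant_average=mut,
        ddg=round_half_away(mut - wild, 1),
    )
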