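"""Automated extraction of growth parameters from OD600 curves.

For every well the pipeline computes the two classical growth parameters:

* the saturated density K, the mean of the three consecutive
  background-corrected reads that include the maximum read; and
* the exponential growth rate r (h^-1), obtained in four steps:
  (1) extract the exponential period of the curve, (2) take the natural-log
  slope of every pair of neighbouring reads inside it, (3) remove outlier
  slopes with box-plot (Tukey) fences, and (4) average the maximal surviving
  slope with its nearest surviving neighbours on each side.

Step 1 guards against spurious reads in the lag phase (which would otherwise
contribute the largest log-slope of the whole curve); step 3 guards against
single-read detector spikes inside the exponential phase. Curves that are
still rising when the run ends carry an unreliable K and are flagged
``incomplete`` so that :func:`refine_dataset` can drop them; flat curves are
kept with r = 0, since zero growth is itself information about the medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .plate_io import PlateIOError, PlateLayout, PlateRun, make_growth_table

QC_ZERO_GROWTH = "zero_growth"
QC_INCOMPLETE = "incomplete"
QC_EDGE_MAX = "edge_max"
QC_TOO_FEW_SLOPES = "too_few_slopes"


@dataclass
class GrowthCurve:
    """One well's background-corrected OD600 time series.

    Corrected readings may be slightly negative (read noise around an empty
    well); they are only floored when logs are taken.
    """

    curve_id: str
    times: np.ndarray
    od: np.ndarray
    well_id: str = ""
    combination_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise PlateIOError(f"curve {self.curve_id!r}: times/od length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise PlateIOError(f"curve {self.curve_id!r}: times not strictly increasing")


@dataclass
class ExtractionConfig:
    """Tunable constants of the extraction pipeline.

    noise_floor
        OD below which a corrected read is considered indistinguishable from
        background (default 0.01 OD).
    sat_fraction
        The exponential window ends where the curve first reaches this
        fraction of K (default 0.9).
    plateau_slope_tol, plateau_window
        A curve is incomplete (still rising) when the least-squares ln-OD
        slope over the final ``plateau_window`` reads exceeds
        ``plateau_slope_tol`` (h^-1) while the curve ever rose above the
        noise floor.
    outlier_rule
        ``"tukey"`` (default): drop slopes outside [Q1 - k IQR, Q3 + k IQR];
        ``"below_q1"``: drop slopes strictly below Q1 (compatibility mode);
        ``"none"``: no filtering (the step-3 ablation variant).
    slope_method, slope_window
        How step 2 estimates per-read log-slopes: ``"regression"`` (default,
        least-squares line over ``slope_window`` nearest reads),
        ``"gradient"`` (central differences) or ``"pairwise"`` (forward
        differences). All agree exactly on exact exponentials; the wider
        stencil suppresses read noise at low OD.
    """

    noise_floor: float = 0.01
    sat_fraction: float = 0.9
    plateau_slope_tol: float = 0.02
    plateau_window: int = 9
    outlier_rule: str = "tukey"
    tukey_k: float = 1.5
    slope_method: str = "regression"
    slope_window: int = 7
    min_window_points: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.sat_fraction < 1:
            raise PlateIOError("sat_fraction must be in (0, 1)")
        if self.noise_floor <= 0:
            raise PlateIOError("noise_floor must be positive")
        if self.outlier_rule not in ("tukey", "below_q1", "none"):
            raise PlateIOError(f"unknown outlier_rule {self.outlier_rule!r}")


@dataclass
class GrowthParameters:
    """(r, K) plus QC flags for one curve."""

    curve_id: str
    r: float
    K: float
    window: tuple[int, int]
    n_slopes_used: int
    qc_flags: set[str] = field(default_factory=set)
    combination_id: str = ""

    @property
    def flags_str(self) -> str:
        return "|".join(sorted(self.qc_flags))


def subtract_background(run: PlateRun, layout: PlateLayout) -> list[GrowthCurve]:
    """Subtract the per-timepoint mean of the background wells from samples.

    The optical background of the microplate and the medium is estimated at
    every timepoint as the mean OD600 of the wells filled with medium only,
    and subtracted from each sample well's raw reads.
    """
    bg_wells = [w for w in layout.background_wells if w in run.wells]
    if not bg_wells:
        raise PlateIOError(f"run {run.run_id!r}: no background wells present")
    bg = np.mean([run.wells[w] for w in bg_wells], axis=0)
    curves = []
    for well in layout.sample_wells:
        if well not in run.wells:
            continue
        od = run.wells[well]
        curves.append(
            GrowthCurve(
                curve_id=f"{run.run_id}:{well}",
                times=run.well_times(well),
                od=od - bg[: len(od)],
                well_id=well,
                combination_id=layout.combinations[well],
            )
        )
    return curves


def saturated_density(curve: GrowthCurve) -> tuple[float, bool]:
    """K = mean of the three consecutive reads that include the maximum.

    Returns ``(K, edge_max)``; ``edge_max`` is set when the maximum sits at
    the first or last read, in which case the three reads are anchored at
    that edge (an early warning that the curve may not have saturated).
    """
    od = curve.od
    if len(od) < 3:
        raise PlateIOError(f"curve {curve.curve_id!r}: need >= 3 reads for K")
    m = int(np.argmax(od))
    if m == 0:
        return float(np.mean(od[:3])), True
    if m == len(od) - 1:
        return float(np.mean(od[-3:])), True
    return float(np.mean(od[m - 1 : m + 2])), False


def exponential_window(
    curve: GrowthCurve,
    cfg: ExtractionConfig | None = None,
    K: float | None = None,
) -> tuple[int, int, set[str]]:
    """Step 1: locate the exponential period as a half-open index range.

    The window ends at the first read reaching ``sat_fraction * K`` and
    starts just after the last read below the noise floor before that point,
    i.e. it is the contiguous above-floor run that leads into saturation.
    Anchoring the start at the *last* crossing (rather than the first)
    excludes isolated lag-phase spikes that briefly exceed the floor.
    """
    cfg = cfg or ExtractionConfig()
    od = curve.od
    flags: set[str] = set()
    if K is None:
        K = saturated_density(curve)[0]
    above = od >= cfg.noise_floor
    if not above.any():
        return 0, 0, {QC_ZERO_GROWTH}
    sat = np.nonzero(od >= cfg.sat_fraction * K)[0]
    end = int(sat[0]) if len(sat) else len(od)
    below_before = np.nonzero(~above[:end])[0]
    start = int(below_before[-1]) + 1 if len(below_before) else 0
    if end - start < cfg.min_window_points:
        flags.add(QC_TOO_FEW_SLOPES)
        start, end = _longest_rising_run(od, cfg.noise_floor)
        if end - start < 2:
            flags.add(QC_ZERO_GROWTH)
            return 0, 0, flags
    return start, end, flags


def _longest_rising_run(od: np.ndarray, floor: float) -> tuple[int, int]:
    """Fallback window: longest non-decreasing run with all reads >= floor."""
    best = (0, 0)
    i = 0
    n = len(od)
    while i < n:
        if od[i] < floor:
            i += 1
            continue
        j = i
        while j + 1 < n and od[j + 1] >= floor and od[j + 1] >= od[j]:
            j += 1
        if j + 1 - i > best[1] - best[0]:
            best = (i, j + 1)
        i = j + 1
    return best


def log_slopes(
    curve: GrowthCurve,
    window: tuple[int, int],
    method: str = "gradient",
    slope_window: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: logarithmic slope between neighbouring records in the window.

    ``method="gradient"`` (default) takes the numerical gradient of ln(OD)
    with respect to time — a central difference over each read's two
    neighbours on interior points, one-sided at the window edges — yielding
    one slope per read. ``method="pairwise"`` returns the end - start - 1
    forward differences between consecutive reads instead. On an exact
    exponential the two are identical; on noisy data the central stencil
    halves the read-noise contribution to each slope.

    Returns ``(slopes, positions)`` where ``positions[i]`` is the read index
    the slope is attached to (the left read of the pair for ``pairwise``).
    Non-positive reads inside the window are dropped with a warning.
    """
    start, end = window
    idx = np.arange(start, end)
    if len(idx) < 2:
        return np.array([]), np.array([], dtype=int)
    od = curve.od[idx]
    pos = od > 0
    if not pos.all():
        warnings.warn(
            f"curve {curve.curve_id!r}: dropping {int((~pos).sum())} non-positive "
            "reads inside the exponential window",
            stacklevel=2,
        )
        idx = idx[pos]
        od = od[pos]
    if len(idx) < 2:
        return np.array([]), np.array([], dtype=int)
    t = curve.times[idx]
    y = np.log(od)
    if method == "gradient":
        return np.gradient(y, t), idx
    if method == "pairwise":
        return np.diff(y) / np.diff(t), idx[:-1]
    if method == "regression":
        return _local_regression_slopes(y, t, slope_window), idx
    raise PlateIOError(f"unknown slope method {method!r}")


def _local_regression_slopes(y: np.ndarray, t: np.ndarray, w: int) -> np.ndarray:
    """Per-read slope from a least-squares line over the w nearest reads.

    The stencil shrinks one-sidedly at the window edges. Exact on linear
    input (hence on exact exponentials after the log), and with read noise
    the slope sd shrinks roughly as w^(-3/2) relative to a two-point
    difference.
    """
    n = len(y)
    h = w // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n, i + h + 1)
        tt = t[lo:hi]
        yy = y[lo:hi]
        tbar = tt.mean()
        out[i] = ((tt - tbar) @ (yy - yy.mean())) / ((tt - tbar) @ (tt - tbar))
    return out


def filter_outlier_slopes(
    slopes: np.ndarray, cfg: ExtractionConfig | None = None
) -> np.ndarray:
    """Step 3: boolean mask of slopes surviving the box-plot outlier rule.

    Quartiles use linear interpolation of order statistics; Tukey fences are
    closed, so a degenerate IQR of zero retains all equal slopes.
    """
    cfg = cfg or ExtractionConfig()
    slopes = np.asarray(slopes, dtype=float)
    if cfg.outlier_rule == "none" or len(slopes) < 3:
        return np.ones(len(slopes), dtype=bool)
    q1, q3 = np.quantile(slopes, [0.25, 0.75], method="linear")
    if cfg.outlier_rule == "below_q1":
        return slopes >= q1
    iqr = q3 - q1
    lo = q1 - cfg.tukey_k * iqr
    hi = q3 + cfg.tukey_k * iqr
    return (slopes >= lo) & (slopes <= hi)


def rate_from_slopes(
    slopes: np.ndarray, keep: np.ndarray | None = None
) -> tuple[float, int]:
    """Step 4: average the maximal surviving slope with its nearest
    surviving neighbours (one on each side, in original time order).

    Returns ``(r, n_used)``; r is floored at zero. With the maximum at a
    boundary of the surviving set only the single available neighbour is
    used.
    """
    slopes = np.asarray(slopes, dtype=float)
    if keep is None:
        keep = np.ones(len(slopes), dtype=bool)
    surv = np.nonzero(keep)[0]
    if len(surv) == 0:
        return 0.0, 0
    best = surv[int(np.argmax(slopes[surv]))]
    k = int(np.searchsorted(surv, best))
    picks = [best]
    if k > 0:
        picks.append(surv[k - 1])
    if k < len(surv) - 1:
        picks.append(surv[k + 1])
    r = float(np.mean(slopes[picks]))
    return max(r, 0.0), len(picks)


def growth_rate(
    curve: GrowthCurve, cfg: ExtractionConfig | None = None, K: float | None = None
) -> tuple[float, dict]:
    """Run steps 1-4 on one curve; returns (r, diagnostics)."""
    cfg = cfg or ExtractionConfig()
    if K is None:
        K = saturated_density(curve)[0]
    start, end, flags = exponential_window(curve, cfg, K=K)
    slopes, positions = log_slopes(
        curve, (start, end), method=cfg.slope_method, slope_window=cfg.slope_window
    )
    if len(slopes) == 0:
        flags.add(QC_ZERO_GROWTH)
        return 0.0, {"window": (start, end), "flags": flags, "n_used": 0, "n_surviving": 0}
    keep = filter_outlier_slopes(slopes, cfg)
    if not keep.any():  # unreachable with closed fences; guard for custom rules
        flags.add(QC_TOO_FEW_SLOPES)
        keep = np.ones(len(slopes), dtype=bool)
    r, n_used = rate_from_slopes(slopes, keep)
    if n_used < 3:
        flags.add(QC_TOO_FEW_SLOPES)
    diag = {
        "window": (start, end),
        "flags": flags,
        "n_used": n_used,
        "n_surviving": int(keep.sum()),
        "slopes": slopes,
        "positions": positions,
        "keep": keep,
    }
    return r, diag


def final_window_slope(curve: GrowthCurve, cfg: ExtractionConfig) -> float:
    """Least-squares ln-OD slope (h^-1) over the final ``plateau_window`` reads.

    Reads are floored at a tenth of the noise floor before the log; if fewer
    than three reads are positive the slope is reported as 0 (a flat tail).
    """
    w = min(cfg.plateau_window, len(curve.od))
    od = curve.od[-w:]
    t = curve.times[-w:]
    pos = od > 0
    if pos.sum() < 3:
        return 0.0
    y = np.log(np.maximum(od, cfg.noise_floor / 10.0))
    return float(np.polyfit(t, y, 1)[0])


def extract_parameters(
    curve: GrowthCurve, cfg: ExtractionConfig | None = None
) -> GrowthParameters:
    """Full per-curve chain: K, exponential window, slopes, filter, r, QC."""
    cfg = cfg or ExtractionConfig()
    K, edge = saturated_density(curve)
    r, diag = growth_rate(curve, cfg, K=K)
    flags = set(diag["flags"])
    if edge:
        flags.add(QC_EDGE_MAX)
    if QC_ZERO_GROWTH in flags:
        r = 0.0
    if (
        np.max(curve.od) >= cfg.noise_floor
        and final_window_slope(curve, cfg) > cfg.plateau_slope_tol
    ):
        flags.add(QC_INCOMPLETE)
    return GrowthParameters(
        curve_id=curve.curve_id,
        r=r,
        K=max(K, 0.0),
        window=diag["window"],
        n_slopes_used=diag["n_used"],
        qc_flags=flags,
        combination_id=curve.combination_id,
    )


def extract_all(
    curves: Iterable[GrowthCurve], cfg: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract parameters for many curves into a growth-record table."""
    cfg = cfg or ExtractionConfig()
    rows = []
    rep_counter: dict[str, int] = {}
    for curve in curves:
        p = extract_parameters(curve, cfg)
        rep = rep_counter.get(curve.combination_id, 0)
        rep_counter[curve.combination_id] = rep + 1
        rows.append(
            {
                "curve_id": p.curve_id,
                "combination_id": p.combination_id,
                "replicate_index": rep,
                "r": p.r,
                "K": p.K,
                "qc_flags": p.flags_str,
            }
        )
    return make_growth_table(rows)


def refine_dataset(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop curves flagged ``incomplete``; keep zero-growth curves.

    A still-rising curve carries no usable K, so it is removed; a flat curve
    carries r = 0, which is real information about the medium, so it stays.
    Returns ``(refined_table, removal_log)`` where the log lists curve_id and
    reason for every removed row.
    """
    flagged = records["qc_flags"].str.split("|").map(lambda f: QC_INCOMPLETE in f)
    log = pd.DataFrame(
        {
            "curve_id": records.loc[flagged, "curve_id"],
            "reason": QC_INCOMPLETE,
        }
    ).reset_index(drop=True)
    return records.loc[~flagged].reset_index(drop=True), log


def aggregate_combinations(records: pd.DataFrame, n_min: int = 3) -> pd.DataFrame:
    """Per-combination mean and standard error of r and K.

    SE is the sample standard deviation over sqrt(N); undefined (NaN) for a
    single replicate. Combinations with fewer than ``n_min`` replicates are
    flagged ``low_n``.
    """
    def _se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    g = records.groupby("combination_id", sort=True)
    out = pd.DataFrame(
        {
            "mean_r": g["r"].mean(),
            "se_r": g["r"].apply(_se),
            "mean_K": g["K"].mean(),
            "se_K": g["K"].apply(_se),
            "n": g.size(),
        }
    )
    out["low_n"] = out["n"] < n_min
    return out
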