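"""Synthetic plate datasets with planted growth-decision structure.

The generator emulates the statistical shape of a combinatorial media
growth assay: media recipes drawn from per-compound log-spaced concentration
grids, a planted piecewise-constant response rule mapping the 13-component
ion profile to a true growth rate r* and saturated density K*, logistic
growth curves with lag, detector background and read noise, and sporadic
artifacts (lag-phase spikes, exponential-phase spikes, runs that end before
the plateau).

The planted rule realises the two mechanism classes under study:

* trade-off chemicals — NH4+ is optimal for fast growth between 63.2 and
  282.8 mM but for high density below 63.2 mM; Mg2+ is optimal for rate
  below 22.4 mM and for density above it;
* a uniform chemical — glucose favours both objectives below 63.2 mM;
* a density decider — iron limitation: below 1 mM Fe2+ the attainable
  density is cut sharply and growth is mildly slowed.

The shared direction of the Fe effect (low Fe is bad for both objectives)
gives the population a weakly positive r-K correlation, as observed in
real media panels, despite the planted trade-offs pulling the two
parameters apart.

Default grid levels are chosen so that the geometric mean of adjacent
levels — where a midpoint split on log10 features must fall — lands exactly
on the planted boundaries (e.g. NH4 levels 20/200 mM around 63.2 mM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import features as feat
from .plate_io import (
    COMPOUNDS,
    PHOSPHATE_RATIO,
    PlateIOError,
    PlateLayout,
    PlateRun,
)

# Planted window boundaries (mM), all at geometric means of adjacent design
# levels: sqrt(20*200), sqrt(200*400), sqrt(5*100), sqrt(0.1*10),
# sqrt(0.001*0.01).
NH4_LOW = math.sqrt(20.0 * 200.0)  # 63.2455...
NH4_HIGH = math.sqrt(200.0 * 400.0)  # 282.842...
MG_BOUND = math.sqrt(5.0 * 100.0)  # 22.3606...
MG_DEPLETED = 0.1
GLC_BOUND = math.sqrt(20.0 * 200.0)
FE_BOUND = math.sqrt(0.1 * 10.0)  # 1.0
THI_BOUND = math.sqrt(0.001 * 0.01)  # 0.00316... (thiamine limitation)

#: Default per-compound concentration grids (mM). Single-level compounds are
#: held fixed; the phosphate pair keeps the 5:3 buffer-stock ratio.
DEFAULT_COMPOUND_LEVELS: dict[str, tuple[float, ...]] = {
    "glucose": (20.0, 200.0, 400.0),
    "(NH4)2SO4": (10.0, 100.0),  # NH4 = 20 / 200 mM
    "K2HPO4": (25.0,),
    "KH2PO4": (15.0,),
    "MgSO4": (5.0, 100.0),
    "thiamine_HCl": (0.001, 0.01, 0.1),
    "FeSO4": (0.1, 10.0),
    "NaCl": (10.0, 100.0, 1000.0),
    "leucine": (0.2, 0.8),
    "histidine": (0.1,),
}


@dataclass
class Scenario:
    """Design and noise model of one synthetic study.

    Defaults reproduce the assay conditions the pipeline is built for:
    C = 225 media combinations, N = 5 replicate wells each, readings every
    30 min for 48 h, additive read noise of 0.005 OD, and a 5% chance per
    well of each artifact class.
    """

    compound_levels: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOUND_LEVELS)
    )
    n_combinations: int = 225
    n_replicates: int = 5
    interval_h: float = 0.5
    duration_h: float = 48.0
    noise_sd: float = 0.005
    lag_spike_prob: float = 0.05
    exp_spike_prob: float = 0.05
    truncation_prob: float = 0.05
    od0: float = 1e-3
    background_od: float = 0.08
    lag_mean_h: float = 1.5
    lag_sd_h: float = 0.5
    rep_cv_r: float = 0.10
    rep_cv_k: float = 0.05
    rep_corr: float = -0.5
    phosphate_ratio_lock: bool = True
    confound_sulfate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.lag_spike_prob, self.exp_spike_prob, self.truncation_prob):
            if not 0.0 <= p <= 1.0:
                raise PlateIOError("artifact probabilities must be in [0, 1]")
        for compound, levels in self.compound_levels.items():
            if compound not in COMPOUNDS:
                raise PlateIOError(f"unknown compound {compound!r} in scenario")
            if any(v < 0 for v in levels) or not levels:
                raise PlateIOError(f"invalid levels for {compound!r}")
        if self.confound_sulfate:
            # Vary (NH4)2SO4 alone among the sulfate salts so that NH4+ and
            # SO4^2- change in perfect proportion (the confounding structure
            # that makes paired ions substitute for each other in trees).
            self.compound_levels = dict(self.compound_levels)
            self.compound_levels["MgSO4"] = (0.0,)
            self.compound_levels["FeSO4"] = (0.0,)

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration_h / self.interval_h)) + 1
        return np.arange(n) * self.interval_h

    @property
    def grid_size(self) -> int:
        out = 1
        for levels in self.compound_levels.values():
            out *= len(levels)
        return out


def _piecewise(c: float, rules: tuple[tuple[float, float], ...], default: float) -> float:
    """Evaluate a piecewise-constant window function: rules are
    (upper_bound, factor) pairs on half-open intervals (prev, upper]."""
    for upper, factor in rules:
        if c <= upper:
            return factor
    return default


@dataclass
class GroundTruth:
    """Planted (r*, K*) response rules on the 13-component ion profile.

    Each rule is a product of per-component window functions; a factor of
    zero models zero growth (ammonium excess, magnesium depletion). K* is
    forced to zero wherever r* is zero: a culture that never grows never
    accumulates density.
    """

    r_max: float = 0.8  # h^-1
    k_max: float = 1.0  # OD units
    rate_factors: dict[str, tuple[tuple[tuple[float, float], ...], float]] = field(
        default_factory=lambda: {
            "NH4": (((NH4_LOW, 0.52), (NH4_HIGH, 1.0)), 0.0),
            "Mg": (((1e-3, 0.0), (MG_DEPLETED, 0.25), (MG_BOUND, 1.0)), 0.75),
            "glucose": (((GLC_BOUND, 1.0),), 0.7),
            "Fe": (((FE_BOUND, 0.85),), 1.0),
            "thiamine": (((THI_BOUND, 0.9),), 1.0),
        }
    )
    density_factors: dict[str, tuple[tuple[tuple[float, float], ...], float]] = field(
        default_factory=lambda: {
            "Fe": (((FE_BOUND, 0.4),), 1.0),
            "NH4": (((NH4_LOW, 1.0), (NH4_HIGH, 0.8)), 0.0),
            "Mg": (((1e-3, 0.0), (MG_DEPLETED, 0.3), (MG_BOUND, 0.8)), 1.0),
            "glucose": (((GLC_BOUND, 1.0),), 0.55),
            "thiamine": (((THI_BOUND, 0.9),), 1.0),
        }
    )

    def response_from_ions(self, ions: Mapping[str, float]) -> tuple[float, float]:
        r = self.r_max
        for comp, (rules, default) in self.rate_factors.items():
            r *= _piecewise(float(ions[comp]), rules, default)
        k = self.k_max
        for comp, (rules, default) in self.density_factors.items():
            k *= _piecewise(float(ions[comp]), rules, default)
        if r <= 0.0:
            k = 0.0
        return r, k


def ground_truth_response(
    media_row: Mapping[str, float] | pd.Series, truth: GroundTruth | None = None
) -> tuple[float, float]:
    """Evaluate the planted rules on one media recipe (compound mM)."""
    truth = truth or GroundTruth()
    row = pd.DataFrame([dict(media_row)])
    ions = feat.expand_to_ions(row).iloc[0]
    return truth.response_from_ions(ions)


def sample_design(scenario: Scenario, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw C media combinations from the compound level grids.

    A full factorial is returned when C equals the grid product; otherwise C
    distinct grid points are sampled uniformly without replacement with the
    scenario seed. The phosphate pair must keep its 5:3 stock ratio when the
    lock is on.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    total = scenario.grid_size
    C = scenario.n_combinations
    if C > total:
        raise PlateIOError(f"C={C} exceeds the {total} distinct grid points")
    compounds = list(COMPOUNDS)
    levels = [scenario.compound_levels.get(c, (0.0,)) for c in compounds]
    radix = [len(lv) for lv in levels]
    if C == total:
        codes = np.arange(total)
    else:
        codes = np.sort(rng.choice(total, size=C, replace=False))
    rows = np.empty((C, len(compounds)))
    for i, code in enumerate(codes):
        for j in range(len(compounds) - 1, -1, -1):
            code, digit = divmod(code, radix[j])
            rows[i, j] = levels[j][digit]
    width = len(str(C))
    media = pd.DataFrame(
        rows,
        columns=compounds,
        index=pd.Index([f"C{i + 1:0{width}d}" for i in range(C)], name="combination_id"),
    )
    if scenario.phosphate_ratio_lock:
        both = (media["K2HPO4"] > 0) & (media["KH2PO4"] > 0)
        ratio = media.loc[both, "K2HPO4"] / media.loc[both, "KH2PO4"]
        if not np.allclose(ratio, PHOSPHATE_RATIO, rtol=1e-6):
            raise PlateIOError("phosphate levels violate the 5:3 ratio lock")
    return media


def simulate_curve(
    r_star: float,
    k_star: float,
    scenario: Scenario,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One raw well: logistic growth plus background and read noise.

    OD(t) = bg + K* / (1 + ((K* - od0)/od0) * exp(-r* (t - lag))) for
    r* > 0, and a flat background for r* = 0. Returns (times, raw OD).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = scenario.times
    if r_star < 0 or k_star < 0:
        raise PlateIOError("r* and K* must be non-negative")
    if r_star > 0 and k_star > scenario.od0:
        lag = max(0.0, rng.normal(scenario.lag_mean_h, scenario.lag_sd_h))
        od = logistic_od(t, r_star, k_star, scenario.od0, lag)
    else:
        od = np.zeros_like(t)
    raw = scenario.background_od + od + rng.normal(0.0, scenario.noise_sd, size=len(t))
    return t, np.maximum(raw, 0.0)


def logistic_od(
    t: np.ndarray, r: float, k: float, od0: float, lag: float = 0.0
) -> np.ndarray:
    """Closed-form logistic curve starting from od0 at t = lag."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + ((k - od0) / od0) * np.exp(-r * (t - lag)))


@dataclass
class SimulatedDataset:
    """Everything one synthetic study produces."""

    runs: list[PlateRun]
    layouts: list[PlateLayout]
    media: pd.DataFrame
    truth: pd.DataFrame  # combination_id -> r_star, K_star (pre-replicate)
    artifact_log: pd.DataFrame


def _well_ids_96() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def simulate_dataset(
    scenario: Scenario | None = None,
    truth: GroundTruth | None = None,
    with_artifacts: bool = True,
) -> SimulatedDataset:
    """Simulate the full study: design, curves, plates, artifacts, truth table.

    Replicate wells receive independent lognormal jitter on (r*, K*) —
    biological replicate variability — before curve simulation; the emitted
    truth table carries the per-combination (pre-jitter) values used for
    recovery scoring. Wells are laid out on 96-well plates with 4 background
    wells each. Fully deterministic given the scenario seed.
    """
    scenario = scenario or Scenario()
    truth = truth or GroundTruth()
    rng = np.random.default_rng(scenario.seed)
    media = sample_design(scenario, rng)
    ions = feat.expand_to_ions(media)
    resp = [truth.response_from_ions(ions.loc[c]) for c in media.index]
    truth_table = pd.DataFrame(resp, columns=["r_star", "K_star"], index=media.index)

    wells_per_plate = 96 - 4
    jobs = [(c, rep) for c in media.index for rep in range(scenario.n_replicates)]
    runs: list[PlateRun] = []
    layouts: list[PlateLayout] = []
    all_ids = _well_ids_96()
    for p0 in range(0, len(jobs), wells_per_plate):
        plate_jobs = jobs[p0 : p0 + wells_per_plate]
        plate_idx = p0 // wells_per_plate
        roles: dict[str, str] = {}
        combos: dict[str, str] = {}
        wells: dict[str, np.ndarray] = {}
        bg_ids = all_ids[: 4]
        for w in bg_ids:
            roles[w] = "background"
            _, raw = simulate_curve(0.0, 0.0, scenario, rng)
            wells[w] = raw
        for w, (combo, _rep) in zip(all_ids[4:], plate_jobs):
            roles[w] = "sample"
            combos[w] = combo
            r_star, k_star = truth_table.loc[combo]
            # Replicate-level biological variability: lognormal jitter on
            # (r, K), anticorrelated across the two parameters (the classic
            # rate-yield trade-off at the level of replicate fluctuations).
            z1, z2 = rng.normal(size=2)
            rho = scenario.rep_corr
            zk = rho * z1 + math.sqrt(max(0.0, 1.0 - rho**2)) * z2
            r_w = r_star * math.exp(scenario.rep_cv_r * z1) if r_star > 0 else 0.0
            k_w = k_star * math.exp(scenario.rep_cv_k * zk) if k_star > 0 else 0.0
            _, raw = simulate_curve(r_w, k_w, scenario, rng)
            wells[w] = raw
        run = PlateRun(run_id=f"plate{plate_idx + 1}", times=scenario.times, wells=wells)
        runs.append(run)
        layouts.append(PlateLayout(roles=roles, combinations=combos))

    if with_artifacts:
        art_rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
        logs = []
        corrupted = []
        for run, layout in zip(runs, layouts):
            new_run, log = inject_artifacts(run, scenario, art_rng, layout=layout)
            corrupted.append(new_run)
            logs.append(log)
        runs = corrupted
        logs = [lg for lg in logs if len(lg)]
        if logs:
            artifact_log = pd.concat(logs, ignore_index=True)
        else:
            artifact_log = pd.DataFrame(columns=["run_id", "well_id", "kind", "index", "value"])
    else:
        artifact_log = pd.DataFrame(columns=["run_id", "well_id", "kind", "index", "value"])
    return SimulatedDataset(
        runs=runs, layouts=layouts, media=media, truth=truth_table, artifact_log=artifact_log
    )


def inject_artifacts(
    run: PlateRun,
    scenario: Scenario,
    seed: int | np.random.Generator = 0,
    layout: PlateLayout | None = None,
) -> tuple[PlateRun, pd.DataFrame]:
    """Corrupt a run with the scenario's artifact model; returns (run, log).

    Per sample well, independently: a single +0.1..0.3 OD spike on one
    lag-phase read, a single spike on one exponential-phase read, and/or a
    time shift that leaves the curve mid-exponential at the end of the run
    (an incomplete, still-rising curve). Background wells are never touched.
    Every injection is logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sample_wells = layout.sample_wells if layout is not None else list(run.wells)
    wells = {w: od.copy() for w, od in run.wells.items()}
    log_rows = []
    bg = scenario.background_od
    for well in sample_wells:
        if well not in wells:
            continue
        od = wells[well]
        corrected = od - bg
        peak = corrected.max()
        growing = peak >= 0.05
        if growing and rng.random() < scenario.truncation_prob:
            sat = np.nonzero(corrected >= 0.6 * peak)[0]
            shift = len(od) - int(sat[0]) + int(rng.integers(2, 8))
            shift = min(shift, len(od) - 2)
            if shift > 0:
                shifted = np.empty_like(od)
                shifted[shift:] = od[: len(od) - shift]
                shifted[:shift] = bg + rng.normal(0.0, scenario.noise_sd, size=shift)
                wells[well] = np.maximum(shifted, 0.0)
                od = wells[well]
                corrected = od - bg
                peak = corrected.max()
                log_rows.append((run.run_id, well, "truncation", shift, np.nan))
        if rng.random() < scenario.lag_spike_prob:
            lag_idx = np.nonzero(corrected < 0.01)[0]
            lag_idx = lag_idx[lag_idx < int(np.argmax(corrected))]
            if len(lag_idx):
                i = int(rng.choice(lag_idx))
                amp = float(rng.uniform(0.1, 0.3))
                wells[well][i] += amp
                log_rows.append((run.run_id, well, "lag_spike", i, amp))
        if growing and rng.random() < scenario.exp_spike_prob:
            exp_idx = np.nonzero((corrected >= 0.1 * peak) & (corrected <= 0.7 * peak))[0]
            exp_idx = exp_idx[exp_idx <= int(np.argmax(corrected))]
            if len(exp_idx):
                i = int(rng.choice(exp_idx))
                amp = float(rng.uniform(0.1, 0.3))
                wells[well][i] += amp
                log_rows.append((run.run_id, well, "exp_spike", i, amp))
    log = pd.DataFrame(log_rows, columns=["run_id", "well_id", "kind", "index", "value"])
    new_run = PlateRun(
        run_id=run.run_id,
        times=run.times.copy(),
        wells=wells,
        truncated_wells=dict(run.truncated_wells),
    )
    return new_run, log


def design_ranges(media: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Tested (min, max) concentration in mM per ion component of a design."""
    ions = feat.expand_to_ions(media)
    return {c: (float(ions[c].min()), float(ions[c].max())) for c in ions.columns}
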