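"""Biological readout of fitted growth trees.

A depth-limited regression tree over log10 ion concentrations is a set of
axis-aligned boxes; the root-to-leaf path with the highest (lowest) mean
target is the predicted best (worst) recipe region. This module extracts
those paths, intersects their constraints into per-chemical optimal
concentration intervals (back-transformed to mM, with unconstrained sides
filled from the tested design range), and compares the rate-optimal and
density-optimal intervals chemical by chemical:

* overlapping interiors -> the chemical works *uniformly* (one concentration
  range serves both fast growth and high density);
* disjoint interiors (touching endpoints included) -> a *trade-off* (the two
  objectives demand different concentrations);
* present in only one tree -> *unshared*.

Also provided: the Spearman rank correlation between r and K at curve or
combination level, a multivariate OLS baseline over the 13 features, and
``run_pipeline``, which chains every stage from raw plate runs to the
mechanism calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cart, features as feat, growth, plate_io
from .cart import RegressionTree, TreeNode


@dataclass
class PathConstraint:
    component: str
    op: str  # "<=" or ">"
    threshold_log10: float

    @property
    def threshold_mM(self) -> float:
        return float(10.0 ** self.threshold_log10)


@dataclass
class LeafPath:
    """Root-to-leaf constraint list plus the leaf's mean target and size."""

    constraints: list[PathConstraint]
    leaf_mean: float
    leaf_n: int

    @property
    def components(self) -> list[str]:
        seen: list[str] = []
        for c in self.constraints:
            if c.component not in seen:
                seen.append(c.component)
        return seen


@dataclass
class ChemicalInterval:
    """Optimal concentration interval for one chemical, in mM.

    Unbounded sides are filled from the tested design range; ``lower_bounded``
    and ``upper_bounded`` record which sides came from actual tree thresholds.
    """

    component: str
    lower: float
    upper: float
    target_kind: str = ""
    lower_bounded: bool = False
    upper_bounded: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"{self.component}: contradictory interval [{self.lower}, {self.upper}]"
            )

    def interior_overlaps(self, other: "ChemicalInterval") -> bool:
        return max(self.lower, other.lower) < min(self.upper, other.upper)


@dataclass
class MechanismCall:
    component: str
    call: str  # uniform | trade_off | unshared
    rate_interval: ChemicalInterval | None = None
    density_interval: ChemicalInterval | None = None


def best_worst_paths(tree: RegressionTree) -> tuple[LeafPath, LeafPath]:
    """Paths to the leaves with maximal and minimal mean target.

    Ties go to the larger leaf, then to the leftmost leaf in tree order. A
    depth-0 tree yields two empty-constraint paths to its single leaf.
    """
    leaves: list[LeafPath] = []

    def walk(node: TreeNode, constraints: list[PathConstraint]) -> None:
        if node.is_leaf:
            leaves.append(LeafPath(list(constraints), node.mean, node.n_samples))
            return
        walk(node.left, constraints + [PathConstraint(node.feature, "<=", node.threshold)])
        walk(node.right, constraints + [PathConstraint(node.feature, ">", node.threshold)])

    walk(tree.root, [])
    best = max(enumerate(leaves), key=lambda t: (t[1].leaf_mean, t[1].leaf_n, -t[0]))[1]
    worst = min(enumerate(leaves), key=lambda t: (t[1].leaf_mean, -t[1].leaf_n, t[0]))[1]
    return best, worst


def optimal_intervals(
    path: LeafPath,
    design_ranges: Mapping[str, tuple[float, float]],
    target_kind: str = "",
) -> list[ChemicalInterval]:
    """Intersect a path's constraints into per-chemical mM intervals.

    For each component on the path, ``>`` thresholds tighten the lower bound
    and ``<=`` thresholds the upper bound (back-transformed as 10^x);
    unconstrained sides fall back to the design's tested min/max.
    """
    out = []
    for comp in path.components:
        lowers = [c.threshold_mM for c in path.constraints if c.component == comp and c.op == ">"]
        uppers = [c.threshold_mM for c in path.constraints if c.component == comp and c.op == "<="]
        design_lo, design_hi = design_ranges.get(comp, (0.0, np.inf))
        lo = max(lowers) if lowers else design_lo
        hi = min(uppers) if uppers else design_hi
        lo_b, hi_b = bool(lowers), bool(uppers)
        out.append(
            ChemicalInterval(
                component=comp,
                lower=float(lo),
                upper=float(hi),
                target_kind=target_kind,
                lower_bounded=lo_b,
                upper_bounded=hi_b,
            )
        )
    return out


def classify_mechanism(
    rate_intervals: Sequence[ChemicalInterval],
    density_intervals: Sequence[ChemicalInterval],
) -> list[MechanismCall]:
    """Call each chemical uniform, trade_off or unshared.

    Components present in both best paths are uniform when the interval
    interiors overlap and trade_off otherwise (intervals touching only at an
    endpoint count as a trade-off: the two objectives still demand different
    concentrations). Components in only one path are unshared.
    """
    by_rate = {iv.component: iv for iv in rate_intervals}
    by_density = {iv.component: iv for iv in density_intervals}
    calls = []
    for comp in list(by_rate) + [c for c in by_density if c not in by_rate]:
        r_iv = by_rate.get(comp)
        d_iv = by_density.get(comp)
        if r_iv is not None and d_iv is not None:
            call = "uniform" if r_iv.interior_overlaps(d_iv) else "trade_off"
        else:
            call = "unshared"
        calls.append(MechanismCall(comp, call, r_iv, d_iv))
    return calls


def spearman_rk(
    records: pd.DataFrame, level: str = "per_curve"
) -> tuple[float, float]:
    """Spearman rank correlation between r and K (average ranks on ties).

    ``level="per_curve"`` correlates individual curves;
    ``"per_combination"`` first averages replicates per combination. The
    p-value uses the t approximation on n - 2 degrees of freedom. Returns
    (nan, nan) when either column is constant.
    """
    if level == "per_combination":
        agg = growth.aggregate_combinations(records, n_min=1)
        r, k = agg["mean_r"].to_numpy(), agg["mean_K"].to_numpy()
    elif level == "per_curve":
        r, k = records["r"].to_numpy(), records["K"].to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(r) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    if np.all(r == r[0]) or np.all(k == k[0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(r, k)
    return float(rho), float(p)


def regression_baseline(X: pd.DataFrame, y: Sequence[float]) -> pd.DataFrame:
    """Ordinary least squares of the target on the features plus intercept.

    Returns a per-term table of estimate, standard error, t and two-sided p,
    with a ``significant`` flag at p < 0.05 (no multiplicity correction).
    A rank-deficient design raises, naming the collinear columns, since
    perfectly confounded ion pairs (e.g. Na+/Cl- from a single salt) make
    the coefficients unidentifiable.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more observations than coefficients")
    Xv = X.to_numpy(dtype=float)
    centered = Xv - Xv.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        # Identify offending columns via pivoted QR on the centered design.
        from scipy.linalg import qr

        _, R, piv = qr(centered, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(centered.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
        bad = [X.columns[j] for j in piv[diag <= tol]] + [
            X.columns[j] for j in piv[len(diag):]
        ]
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear or constant columns: {sorted(map(str, bad))}"
        )
    model = sm.OLS(y, sm.add_constant(Xv)).fit()
    out = pd.DataFrame(
        {
            "estimate": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        },
        index=["intercept"] + [str(c) for c in X.columns],
    )
    out["significant"] = out["p"] < 0.05
    return out


@dataclass
class PipelineConfig:
    """Knobs of the end-to-end analysis."""

    extraction: growth.ExtractionConfig = field(default_factory=growth.ExtractionConfig)
    seed: int = 0
    k: int = 5
    depth: int | str = "auto"  # "auto" -> select_depth over depth_grid
    depth_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    depth_tol: float = 1e-3
    min_leaf: int = 5
    n_min: int = 3


@dataclass
class AnalysisReport:
    """JSON-serialisable result of :func:`run_pipeline`."""

    growth_table: pd.DataFrame
    removal_log: pd.DataFrame
    combination_table: pd.DataFrame
    feature_matrix: pd.DataFrame
    trees: dict[str, RegressionTree]
    selected_depth: dict[str, int]
    cv: dict[str, cart.CVResult]
    stability: dict[str, cart.StabilityReport]
    best_paths: dict[str, LeafPath]
    worst_paths: dict[str, LeafPath]
    intervals: dict[str, list[ChemicalInterval]]
    mechanism_calls: list[MechanismCall]
    spearman: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        def round10(x: float) -> float:
            return float(f"{x:.10g}")

        return {
            "n_curves": int(len(self.growth_table)),
            "n_removed": int(len(self.removal_log)),
            "n_combinations": int(len(self.combination_table)),
            "selected_depth": self.selected_depth,
            "cv_mean_mse": {t: round10(cv.mean_mse) for t, cv in self.cv.items()},
            "trees": {t: tree.to_dict() for t, tree in self.trees.items()},
            "root_stability": {
                t: rep.at("root") for t, rep in self.stability.items()
            },
            "best_paths": {
                t: [asdict(c) for c in p.constraints] for t, p in self.best_paths.items()
            },
            "worst_paths": {
                t: [asdict(c) for c in p.constraints] for t, p in self.worst_paths.items()
            },
            "intervals": {
                t: [
                    {
                        "component": iv.component,
                        "lower_mM": round10(iv.lower),
                        "upper_mM": round10(iv.upper),
                    }
                    for iv in ivs
                ]
                for t, ivs in self.intervals.items()
            },
            "mechanism_calls": {c.component: c.call for c in self.mechanism_calls},
            "spearman": {
                lvl: {"rho": round10(v[0]), "p": round10(v[1])}
                for lvl, v in self.spearman.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def run_pipeline(
    runs: plate_io.PlateRun | Sequence[plate_io.PlateRun],
    layouts: plate_io.PlateLayout | Sequence[plate_io.PlateLayout],
    media: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Raw plate runs -> growth table -> features -> trees -> mechanism calls.

    Deterministic given ``config.seed``. Trees for both targets (r and K)
    are fitted on the per-curve dataset; the tree depth is cross-validated
    per target unless fixed in the config.
    """
    config = config or PipelineConfig()
    if isinstance(runs, plate_io.PlateRun):
        runs = [runs]
    if isinstance(layouts, plate_io.PlateLayout):
        layouts = [layouts]
    if len(runs) != len(layouts):
        raise ValueError("need one layout per run")
    if len(media) == 0:
        raise ValueError("empty media table")

    curves: list[growth.GrowthCurve] = []
    for run, layout in zip(runs, layouts):
        curves.extend(growth.subtract_background(run, layout))
    records = growth.extract_all(curves, config.extraction)
    refined, removal_log = growth.refine_dataset(records)
    combos = growth.aggregate_combinations(refined, n_min=config.n_min)

    ions = feat.expand_to_ions(media)
    fm = feat.log_features(ions, on_all_zero="drop")
    X = fm.loc[refined["combination_id"]].reset_index(drop=True)
    ranges = {c: (float(ions[c].min()), float(ions[c].max())) for c in fm.columns}

    trees: dict[str, RegressionTree] = {}
    depths: dict[str, int] = {}
    cvs: dict[str, cart.CVResult] = {}
    stab: dict[str, cart.StabilityReport] = {}
    best: dict[str, LeafPath] = {}
    worst: dict[str, LeafPath] = {}
    intervals: dict[str, list[ChemicalInterval]] = {}
    for target, col in (("rate", "r"), ("density", "K")):
        y = refined[col].to_numpy(dtype=float)
        if config.depth == "auto":
            d = cart.select_depth(
                X, y, depth_grid=config.depth_grid, tol=config.depth_tol,
                k=config.k, seed=config.seed, min_leaf=config.min_leaf,
            )
        else:
            d = int(config.depth)
        depths[target] = d
        trees[target] = cart.fit_tree(X, y, max_depth=d, min_leaf=config.min_leaf)
        cvs[target] = cart.kfold_mse(X, y, d, k=config.k, seed=config.seed, min_leaf=config.min_leaf)
        stab[target] = cart.split_stability(
            X, y, d, k=config.k, seed=config.seed, min_leaf=config.min_leaf
        )
        b, w = best_worst_paths(trees[target])
        best[target], worst[target] = b, w
        intervals[target] = optimal_intervals(b, ranges, target_kind=target)

    calls = classify_mechanism(intervals["rate"], intervals["density"])
    spearman = {
        "per_curve": spearman_rk(refined, "per_curve"),
        "per_combination": spearman_rk(refined, "per_combination"),
    }
    return AnalysisReport(
        growth_table=refined,
        removal_log=removal_log,
        combination_table=combos,
        feature_matrix=fm,
        trees=trees,
        selected_depth=depths,
        cv=cvs,
        stability=stab,
        best_paths=best,
        worst_paths=worst,
        intervals=intervals,
        mechanism_calls=calls,
        spearman=spearman,
    )
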