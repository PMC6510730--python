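"""From-scratch CART regression trees with cross-validation utilities.

The tree is grown by greedy binary recursive partitioning: at each node every
candidate split — the arithmetic midpoint between each pair of consecutive
distinct sorted values of each feature — is scored by the summed squared
error of the two children, and the split minimising it (equivalently,
maximising variance reduction) is taken. Rows with feature value equal to
the threshold go left. Ties are broken deterministically by lower feature
column index, then lower threshold, so that alternation in the stability
report reflects resampling rather than arbitrary ordering.

On log10-concentration features this midpoint convention means that a
back-transformed threshold is the geometric mean of two adjacent tested
concentrations.

The module also provides k-fold cross-validated mse, depth selection by mse
plateau (grow the tree until extra depth no longer changes the
cross-validated error), and a per-node-position report of which feature is
chosen across folds (split stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class CartError(ValueError):
    pass


@dataclass
class TreeNode:
    """One node of a regression tree; internal nodes carry a split."""

    n_samples: int
    mean: float
    mse: float  # training mse of the samples at this node
    depth: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {
            "n": self.n_samples,
            "mean": self.mean,
            "mse": self.mse,
        }
        if not self.is_leaf:
            d["feature"] = self.feature
            d["threshold"] = self.threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d


@dataclass
class RegressionTree:
    root: TreeNode
    feature_names: list[str]
    max_depth: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = _as_matrix(X, self.feature_names)
        out = np.empty(len(Xv))
        self._route(self.root, Xv, np.arange(len(Xv)), out)
        return out

    def _route(self, node: TreeNode, Xv: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.mean
            return
        j = self.feature_names.index(node.feature)
        go_left = Xv[idx, j] <= node.threshold
        self._route(node.left, Xv, idx[go_left], out)
        self._route(node.right, Xv, idx[~go_left], out)

    def nodes(self) -> Iterator[tuple[str, TreeNode]]:
        """Yield (position, node) pairs, positions like root, root.L, root.R.L."""
        stack = [("root", self.root)]
        while stack:
            pos, node = stack.pop()
            yield pos, node
            if not node.is_leaf:
                stack.append((pos + ".R", node.right))
                stack.append((pos + ".L", node.left))

    @property
    def n_leaves(self) -> int:
        return sum(1 for _, n in self.nodes() if n.is_leaf)

    def depth(self) -> int:
        return max(n.depth for _, n in self.nodes())

    def to_dict(self) -> dict:
        return self.root.to_dict()

    def render(self) -> str:
        """Plain-text rendering: per node the split, cv-style mse, n and mean."""
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, label: str) -> None:
            pad = "  " * indent
            head = f"{pad}{label} n={node.n_samples} mean={node.mean:.4g} mse={node.mse:.4g}"
            if not node.is_leaf:
                head += f" split: {node.feature} <= {node.threshold:.4g} (log10 mM)"
            lines.append(head)
            if not node.is_leaf:
                walk(node.left, indent + 1, "L:")
                walk(node.right, indent + 1, "R:")

        walk(self.root, 0, "root:")
        return "\n".join(lines)


def _as_matrix(X: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if names is not None:
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise CartError(f"missing feature columns {missing}")
            X = X[list(names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _feature_names(X: pd.DataFrame | np.ndarray) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return [f"x{j}" for j in range(np.asarray(X).shape[1])]


def _best_split(
    Xv: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature index, threshold, child SSE) or None if no valid split.

    Scanned in column order with thresholds ascending and strict improvement,
    which implements the (column index, threshold) tie-break.
    """
    n = len(y)
    best: tuple[int, float, float] | None = None
    best_sse = np.inf
    for j in range(Xv.shape[1]):
        xs = Xv[:, j]
        order = np.argsort(xs, kind="stable")
        sx = xs[order]
        sy = y[order]
        cs = np.cumsum(sy)
        cs2 = np.cumsum(sy * sy)
        nl = np.arange(1, n)  # left sizes for a split after position nl-1
        valid = (sx[:-1] < sx[1:]) & (nl >= min_leaf) & (n - nl >= min_leaf)
        if not valid.any():
            continue
        sum_l = cs[:-1]
        sq_l = cs2[:-1]
        sum_r = cs[-1] - sum_l
        sq_r = cs2[-1] - sq_l
        with np.errstate(invalid="ignore"):
            sse = (sq_l - sum_l**2 / nl) + (sq_r - sum_r**2 / (n - nl))
        sse[~valid] = np.inf
        i = int(np.argmin(sse))  # first minimum -> lowest threshold
        # Strict improvement beyond float noise: perfectly confounded
        # features (identical partitions) must tie exactly, so that the
        # column-order tie-break, not summation round-off, decides.
        if best is None or sse[i] < best_sse - 1e-9 * (abs(best_sse) + 1.0):
            best_sse = float(sse[i])
            best = (j, float((sx[i] + sx[i + 1]) / 2.0), best_sse)
    return best


def fit_tree(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    max_depth: int = 4,
    min_leaf: int = 5,
) -> RegressionTree:
    """Grow a regression tree by greedy variance-reduction splitting.

    Splitting stops at ``max_depth``, when a node holds fewer than
    ``2 * min_leaf`` samples, or when no split reduces the squared error.
    A constant target yields a single-leaf tree.
    """
    names = _feature_names(X)
    Xv = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise CartError("empty training data")
    if Xv.shape[0] != len(y):
        raise CartError("X and y length mismatch")
    if not np.isfinite(Xv).all() or not np.isfinite(y).all():
        raise CartError("missing or non-finite values in training data")

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        mean = float(sub_y.mean())
        sse = float(((sub_y - mean) ** 2).sum())
        node = TreeNode(n_samples=len(idx), mean=mean, mse=sse / len(idx), depth=depth)
        if depth >= max_depth or len(idx) < 2 * min_leaf or sse <= 0.0:
            return node
        found = _best_split(Xv[idx], sub_y, min_leaf)
        if found is None:
            return node
        j, thr, child_sse = found
        if not child_sse < sse - 1e-12 * max(sse, 1.0):  # no real reduction
            return node
        go_left = Xv[idx, j] <= thr
        node.feature = names[j]
        node.threshold = thr
        node.left = grow(idx[go_left], depth + 1)
        node.right = grow(idx[~go_left], depth + 1)
        return node

    root = grow(np.arange(len(y)), 0)
    return RegressionTree(root=root, feature_names=names, max_depth=max_depth)


def predict(tree: RegressionTree, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Route rows through the tree (``<=`` goes left) and return leaf means."""
    return tree.predict(X)


@dataclass
class CVResult:
    k: int
    fold_mse: list[float]
    seed: int

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, k)]


def kfold_mse(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    max_depth: int = 4,
    k: int = 5,
    seed: int = 0,
    min_leaf: int = 5,
) -> CVResult:
    """k-fold cross-validated mse: random near-equal folds, fit on the rest,
    score the held-out fold."""
    names = _feature_names(X)
    Xv = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise CartError("k must be >= 2")
    if k > n:
        raise CartError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    fold_mse = []
    for fold in _fold_indices(n, k, rng):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        tree = fit_tree(pd.DataFrame(Xv[mask], columns=names), y[mask], max_depth, min_leaf)
        pred = tree.predict(pd.DataFrame(Xv[fold], columns=names))
        fold_mse.append(float(np.mean((pred - y[fold]) ** 2)))
    return CVResult(k=k, fold_mse=fold_mse, seed=seed)


def select_depth(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    depth_grid: Sequence[int] = (0, 1, 2, 3, 4, 5, 6, 7, 8),
    tol: float = 1e-3,
    k: int = 5,
    seed: int = 0,
    min_leaf: int = 5,
) -> int:
    """Fix the depth where extra depth stops changing the cross-validated mse.

    Returns the smallest depth d in the grid with
    ``|mean_mse(next) - mean_mse(d)| <= tol`` (absolute, on the target's
    squared scale); if the mse never plateaus, the depth of minimal mean mse.
    The same fold partition (same seed) is reused at every depth so that the
    comparison is paired.
    """
    depth_grid = list(depth_grid)
    if any(b <= a for a, b in zip(depth_grid, depth_grid[1:])):
        raise CartError("depth_grid must be strictly increasing")
    mses = [kfold_mse(X, y, d, k=k, seed=seed, min_leaf=min_leaf).mean_mse for d in depth_grid]
    for d, m, m_next in zip(depth_grid, mses, mses[1:]):
        if abs(m_next - m) <= tol:
            return d
    return depth_grid[int(np.argmin(mses))]


@dataclass
class StabilityReport:
    """Per node position, the frequency of each split feature across folds."""

    frequencies: dict[str, dict[str, float]]
    n_fits: int

    def at(self, position: str) -> dict[str, float]:
        return self.frequencies.get(position, {})


def split_stability(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float] | np.ndarray,
    max_depth: int = 4,
    k: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    min_leaf: int = 5,
) -> StabilityReport:
    """Which feature occupies each node position across resampled fits.

    Over ``n_repeats`` random k-fold partitions, a tree is fitted on each of
    the ``n_repeats * k`` training folds and the split feature at every node
    position recorded; frequencies are counts over all fits, so positions
    absent from some fitted trees sum to less than 1.
    """
    names = _feature_names(X)
    Xv = _as_matrix(X, names)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise CartError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    counts: dict[str, dict[str, int]] = {}
    n_fits = n_repeats * k
    for _ in range(n_repeats):
        for fold in _fold_indices(n, k, rng):
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            tree = fit_tree(pd.DataFrame(Xv[mask], columns=names), y[mask], max_depth, min_leaf)
            for pos, node in tree.nodes():
                if not node.is_leaf:
                    counts.setdefault(pos, {}).setdefault(node.feature, 0)
                    counts[pos][node.feature] += 1
    freqs = {
        pos: {f: c / n_fits for f, c in sorted(feat.items())}
        for pos, feat in sorted(counts.items())
    }
    return StabilityReport(frequencies=freqs, n_fits=n_fits)
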