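"""Stoichiometric expansion of media recipes into ionic/molecular features.

A medium is mixed from ten compounds, but several of them dissociate into
shared ions (both phosphates contribute K+; three salts contribute SO4^2-),
so the compounds are not the natural variables of the growth response. This
module expands each recipe into the concentrations of 13 ionic/molecular
components and log10-transforms them into the feature matrix used by the
regression trees. Working in log10 mM keeps the decade-spanning design
ranges comparable and makes tree thresholds fall at geometric means of
adjacent tested concentrations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .plate_io import COMPOUNDS, PlateIOError

#: The 13 tracked components, in fixed column order: the carbon source and
#: nutrient cations first, organic micronutrients next, counter-ions last.
#: The order matters because the tree learner breaks exact split ties by
#: column index: when two components are perfectly confounded (a nutrient
#: and the counter-ion it was dosed with, e.g. Mg2+ and SO4^2- from MgSO4),
#: the split is attributed to the biologically primary nutrient rather than
#: the counter-ion.
COMPONENTS = (
    "glucose",
    "NH4",
    "Mg",
    "Fe",
    "K",
    "Na",
    "thiamine",
    "leucine",
    "histidine",
    "SO4",
    "PO4",
    "Cl",
    "H",
)

#: Canonical stoichiometry: compound -> {component: coefficient}. Hydrate
#: water contributes nothing; the HCl of thiamine hydrochloride contributes
#: one H+ and one Cl- per molecule.
CANONICAL_EXPANSION: dict[str, dict[str, int]] = {
    "glucose": {"glucose": 1},
    "(NH4)2SO4": {"NH4": 2, "SO4": 1},
    "K2HPO4": {"K": 2, "PO4": 1},
    "KH2PO4": {"K": 1, "PO4": 1},
    "MgSO4": {"Mg": 1, "SO4": 1},
    "thiamine_HCl": {"thiamine": 1, "H": 1, "Cl": 1},
    "FeSO4": {"Fe": 1, "SO4": 1},
    "NaCl": {"Na": 1, "Cl": 1},
    "leucine": {"leucine": 1},
    "histidine": {"histidine": 1},
}


def expansion_matrix(expansion: dict[str, dict[str, int]] | None = None) -> pd.DataFrame:
    """Stoichiometry as a compounds x components coefficient matrix."""
    expansion = expansion if expansion is not None else CANONICAL_EXPANSION
    mat = pd.DataFrame(0.0, index=list(COMPOUNDS), columns=list(COMPONENTS))
    for compound, parts in expansion.items():
        if compound not in mat.index:
            raise PlateIOError(f"unknown compound in expansion: {compound!r}")
        for component, coeff in parts.items():
            if component not in mat.columns:
                raise PlateIOError(f"unknown component {component!r} for {compound!r}")
            if not (isinstance(coeff, (int, np.integer)) and coeff > 0):
                raise PlateIOError(f"coefficient for {compound!r}/{component!r} must be a positive integer")
            mat.loc[compound, component] = float(coeff)
    return mat


def expand_to_ions(
    media: pd.DataFrame,
    expansion: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Expand a media table (mM of compounds) to component concentrations (mM).

    Linear in the media table: component c = sum over compounds of
    coefficient(compound, c) * concentration(compound).
    """
    unknown = [c for c in media.columns if c not in COMPOUNDS]
    if unknown:
        raise PlateIOError(f"unknown compounds in media table: {unknown}")
    mat = expansion_matrix(expansion)
    full = media.reindex(columns=list(COMPOUNDS), fill_value=0.0).astype(float)
    out = full.to_numpy() @ mat.to_numpy()
    return pd.DataFrame(out, index=media.index, columns=list(COMPONENTS))


def log_features(
    components: pd.DataFrame,
    on_all_zero: str = "error",
) -> pd.DataFrame:
    """log10-transform a component table (mM) into the CART feature matrix.

    Zeros cannot be log-transformed; a zero concentration is floored one
    decade below the smallest positive value observed in its column, and the
    substituted value is recorded in ``result.attrs["zero_floor"]``. A column
    that is zero everywhere is uninformative and raises, unless
    ``on_all_zero="drop"`` removes it.

    Parameters
    ----------
    components
        Non-negative concentrations, rows = combinations (or curves).
    on_all_zero
        ``"error"`` (default) or ``"drop"``.
    """
    if (components.to_numpy() < 0).any():
        raise PlateIOError("negative concentrations cannot be log-transformed")
    all_zero = [c for c in components.columns if (components[c] == 0).all()]
    if all_zero:
        if on_all_zero == "drop":
            components = components.drop(columns=all_zero)
        else:
            raise PlateIOError(
                f"all-zero component columns {all_zero}; pass on_all_zero='drop' to remove them"
            )
    out = pd.DataFrame(index=components.index, dtype=float)
    zero_floor: dict[str, float] = {}
    for col in components.columns:
        vals = components[col].to_numpy(dtype=float)
        logs = np.empty_like(vals)
        pos = vals > 0
        logs[pos] = np.log10(vals[pos])
        if (~pos).any():
            floor = np.log10(vals[pos].min()) - 1.0
            logs[~pos] = floor
            zero_floor[col] = floor
        out[col] = logs
    out.attrs["zero_floor"] = zero_floor
    return out


def feature_correlations(fm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the (log) feature columns.

    Zero-variance columns yield NaN rows/columns (correlation undefined);
    the matrix is symmetric with unit diagonal elsewhere.
    """
    if len(fm) < 3:
        raise PlateIOError("need at least 3 rows to correlate features")
    corr = fm.corr(method="pearson")
    # pandas leaves the diagonal of constant columns at 1; mark undefined.
    constant = fm.std(ddof=0) == 0
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr
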