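"""Amoeboid/ramified classification from multimodality-weighted shape indices.

Each morphometric feature carries a multimodality index (MMI) — a
bimodality coefficient of its distribution across the cell population —
and a direction label saying whether high values mark amoeboid (compact,
activated) or ramified (branched, surveillant) morphology. Min–max-scaled
features are combined, per direction set, into an amoeboid index and a
ramified index; a cell is assigned to whichever index is larger. The
fraction of amoeboid-labeled cells per sample is the amoeboid ratio.

The package ships a reference MMI table (weights and directions from the
original morphometric screen of injury-activated microglia); the weights
can alternatively be re-estimated from the dataset under analysis.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .morpho import FEATURE_NAMES

LABELS = ("amoeboid", "ramified")


class UndefinedMMIError(ValueError):
    """MMI is undefined (zero variance or too few observations)."""


def load_reference_mmi() -> pd.DataFrame:
    """The shipped per-feature MMI weights and direction labels.

    Columns: ``feature``, ``mmi`` in [0, 1], ``direction`` in
    {amoeboid, ramified}. High-MMI features (≥ 0.5) are the strongly
    bimodal ones that also drive unsupervised clustering.
    """
    with resources.files("gliamorph.data").joinpath("reference_mmi.csv").open() as fh:
        table = pd.read_csv(fh)
    return validate_mmi_table(table)


def validate_mmi_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"feature", "mmi", "direction"}
    if not required.issubset(table.columns):
        raise ValueError(f"MMI table needs columns {sorted(required)}")
    if table["feature"].duplicated().any():
        raise ValueError("duplicate feature names in MMI table")
    if not table["mmi"].between(0, 1).all():
        raise ValueError("MMI values must lie in [0, 1]")
    bad = set(table["direction"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown direction labels: {bad}")
    return table.reset_index(drop=True)


def compute_mmi(values) -> float:
    """Sarle-type bimodality coefficient of one feature's distribution.

    b = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3))) with g₁ the sample skewness
    and g₂ the sample excess kurtosis (both bias-corrected). Asymptotically
    b → 1 for a symmetric two-point distribution, ≈ 1/3 for a normal and
    ≈ 0.555 for a uniform; the result is clipped to [0, 1].
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 4:
        raise UndefinedMMIError("MMI needs at least 4 finite values")
    if np.ptp(x) == 0:
        raise UndefinedMMIError("MMI undefined for a zero-variance feature")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    b = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return float(np.clip(b, 0.0, 1.0))


def mmi_table_from_data(features: pd.DataFrame, directions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Estimate MMI per feature from the current population.

    Direction labels are taken from ``directions`` (feature/direction
    frame) or, by default, from the shipped reference table.
    """
    ref = directions if directions is not None else load_reference_mmi()
    dir_map = dict(zip(ref["feature"], ref["direction"]))
    rows = []
    for col in features.columns:
        if col not in dir_map:
            continue
        try:
            m = compute_mmi(features[col])
        except UndefinedMMIError:
            warnings.warn(f"feature '{col}' has undefined MMI; dropped")
            continue
        rows.append({"feature": col, "mmi": m, "direction": dir_map[col]})
    return validate_mmi_table(pd.DataFrame(rows))


def scale_features(features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature min–max scaling across the analyzed population to [0, 1].

    Constant features cannot be scaled and are dropped with a warning.
    """
    if len(features) < 2:
        raise ValueError("scaling needs at least 2 cells")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"feature '{col}' is constant; dropped from scaling")
            continue
        out[col] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=features.index)


def indices(
    scaled: pd.DataFrame,
    mmi_table: pd.DataFrame,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Amoeboid and ramified indices per cell from scaled features.

    Each index combines the scaled features of its direction set with the
    MMI values as weights. The default MMI-weighted mean puts both indices
    on a common [0, 1] scale even though the direction sets differ in size;
    ``aggregate='sum'`` restores plain weighted sums.
    """
    mmi_table = validate_mmi_table(mmi_table)
    out = {}
    for label in LABELS:
        sub = mmi_table[mmi_table["direction"] == label]
        if sub.empty:
            raise ValueError(f"no features with direction '{label}'")
        missing = [f for f in sub["feature"] if f not in scaled.columns]
        if missing:
            raise KeyError(f"feature columns missing from scaled table: {missing}")
        w = sub["mmi"].to_numpy(dtype=float)
        X = scaled[list(sub["feature"])].to_numpy(dtype=float)
        if aggregate == "mean":
            out[f"{label}_index"] = X @ w / w.sum()
        elif aggregate == "sum":
            out[f"{label}_index"] = X @ w
        else:
            raise ValueError("aggregate must be 'mean' or 'sum'")
    return pd.DataFrame(out, index=scaled.index)


def classify_cells(index_table: pd.DataFrame) -> pd.Series:
    """Label each cell by the larger index; ties go to ramified.

    The tie rule is conservative with respect to detecting amoeboid
    (activated) cells.
    """
    a = index_table["amoeboid_index"].to_numpy(dtype=float)
    r = index_table["ramified_index"].to_numpy(dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(r).all()):
        raise ValueError("indices must be finite")
    return pd.Series(np.where(a > r, "amoeboid", "ramified"), index=index_table.index, name="label")


def amoeboid_ratio(labels: pd.Series, samples: pd.Series) -> pd.DataFrame:
    """Percentage of amoeboid-labeled cells per sample.

    Returns a tidy frame (sample, n_cells, amoeboid_ratio_pct) ready for
    group statistics. Empty samples are excluded with a warning.
    """
    df = pd.DataFrame({"label": np.asarray(labels), "sample": np.asarray(samples)})
    empty = df.groupby("sample").size() == 0
    if empty.any():
        warnings.warn(f"samples with no cells excluded: {list(empty[empty].index)}")
    grp = df.groupby("sample")["label"]
    out = pd.DataFrame(
        {
            "n_cells": grp.size(),
            "amoeboid_ratio_pct": 100.0 * grp.apply(lambda s: (s == "amoeboid").mean()),
        }
    ).reset_index()
    return out


class AmoeboidRamifiedClassifier(ClassifierMixin, BaseEstimator):
    """MMI-weighted two-index morphology classifier.

    ``fit`` learns the per-feature min–max ranges of the reference
    population (and, when ``mmi_table='fit'``, re-estimates the MMI weights
    from it); ``predict`` scales new profiles with those ranges, forms the
    amoeboid and ramified indices and assigns the larger one.

    Parameters
    ----------
    mmi_table : None, 'fit', or DataFrame
        None uses the shipped reference weights; 'fit' estimates MMI from
        the training population; a DataFrame supplies custom weights
        (columns feature/mmi/direction).
    aggregate : {'mean', 'sum'}
        How scaled features combine into an index.
    """

    def __init__(self, mmi_table=None, aggregate: str = "mean"):
        self.mmi_table = mmi_table
        self.aggregate = aggregate

    def fit(self, X: pd.DataFrame, y=None):
        X = self._check_frame(X)
        if self.mmi_table is None:
            table = load_reference_mmi()
        elif isinstance(self.mmi_table, str) and self.mmi_table == "fit":
            table = mmi_table_from_data(X)
        else:
            table = validate_mmi_table(self.mmi_table)
        self.feature_min_ = X.min(axis=0)
        self.feature_max_ = X.max(axis=0)
        usable = [
            f
            for f in table["feature"]
            if f in X.columns and self.feature_max_[f] > self.feature_min_[f]
        ]
        dropped = set(table["feature"]) & set(X.columns) - set(usable)
        if dropped:
            warnings.warn(f"constant features dropped from the indices: {sorted(dropped)}")
        self.mmi_table_ = table[table["feature"].isin(usable)].reset_index(drop=True)
        self.classes_ = np.array(LABELS)
        return self

    def _check_frame(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_NAMES)
        return X

    def _scale(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = (self.feature_max_ - self.feature_min_).replace(0, np.nan)
        scaled = (X - self.feature_min_) / rng
        return scaled.dropna(axis=1, how="all")

    def decision_function(self, X) -> pd.DataFrame:
        """Per-cell amoeboid and ramified indices."""
        check_is_fitted(self, "mmi_table_")
        X = self._check_frame(X)
        return indices(self._scale(X), self.mmi_table_, aggregate=self.aggregate)

    def predict(self, X) -> np.ndarray:
        return classify_cells(self.decision_function(X)).to_numpy()

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
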