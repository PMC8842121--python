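"""Linear and parameter-free additive models of construct activity.

Constructs are featurized as 0/1 indicators of the individual mutations in
their provenance; ordinary least squares (minimum-norm on rank-deficient
designs) predicts log2 expression, and the fit is evaluated by Pearson r and
the fraction of points inside a +/-3*SD noise band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats


class ModelError(ValueError):
    pass


@dataclass
class FeatureVocabulary:
    features: list[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ModelError("duplicate features in vocabulary")
        self.index = {f: i for i, f in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class LinearFit:
    intercept: float
    coefficients: np.ndarray
    p_values: np.ndarray
    std_errors: np.ndarray
    predictions: np.ndarray
    pearson_r: float
    band_sd: float
    rank_deficient: bool = False
    feature_names: list[str] = field(default_factory=list)


def featurize(construct_features: list[list[str]], vocabulary: FeatureVocabulary) -> np.ndarray:
    """Binary design matrix: one row per construct, one column per feature.

    A wild-type construct (no mutations) is an all-zero row; a feature not
    in the vocabulary is an error naming it.
    """
    X = np.zeros((len(construct_features), len(vocabulary)))
    unknown = set()
    for i, feats in enumerate(construct_features):
        for f in feats:
            if f not in vocabulary.index:
                unknown.add(f)
            else:
                X[i, vocabulary.index[f]] = 1.0
    if unknown:
        raise ModelError(f"unknown features in provenance: {sorted(unknown)}")
    return X


def fit_linear(X: np.ndarray, y, *, band_sd: float | None = None,
               feature_names: list[str] | None = None) -> LinearFit:
    """OLS with intercept; minimum-norm (pinv) solution when rank-deficient."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ModelError("X rows must match len(y)")
    if y.size < 2:
        raise ModelError("need at least 2 observations")
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design).fit()
    predictions = np.asarray(fit.fittedvalues)
    rank_deficient = bool(np.linalg.matrix_rank(design) < design.shape[1])
    if np.std(predictions) > 0 and np.std(y) > 0:
        r = float(stats.pearsonr(predictions, y).statistic)
    else:
        r = float("nan")
    if band_sd is None:
        resid = y - predictions
        band_sd = float(np.std(resid, ddof=1)) if y.size > 1 else 0.0
    return LinearFit(
        intercept=float(fit.params[0]),
        coefficients=np.asarray(fit.params[1:]),
        p_values=np.asarray(fit.pvalues[1:]),
        std_errors=np.asarray(fit.bse[1:]),
        predictions=predictions,
        pearson_r=r,
        band_sd=band_sd,
        rank_deficient=rank_deficient,
        feature_names=feature_names or [],
    )


def additive_predict(
    single_effect_table: dict[str, float],
    construct_features: list[list[str]],
    wt_mean: float,
) -> tuple[np.ndarray, int]:
    """Parameter-free prediction: wt mean plus the sum of single-feature deltas.

    Constructs referencing a feature absent from the table are skipped
    (prediction NaN) and counted.
    """
    predictions = np.full(len(construct_features), np.nan)
    skipped = 0
    for i, feats in enumerate(construct_features):
        if any(f not in single_effect_table for f in feats):
            skipped += 1
            continue
        predictions[i] = wt_mean + sum(single_effect_table[f] for f in feats)
    return predictions, skipped


def evaluate(predictions, observations, band_sd: float) -> tuple[float, float]:
    """Pearson r and the fraction of points within +/-3*band_sd of y = x."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.size != o.size or p.size < 2:
        raise ModelError("need equal-length vectors of at least 2 points")
    keep = np.isfinite(p) & np.isfinite(o)
    p, o = p[keep], o[keep]
    if np.std(p) == 0 or np.std(o) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(p, o).statistic)
    fraction = float(np.mean(np.abs(o - p) <= 3.0 * band_sd))
    return r, fraction
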