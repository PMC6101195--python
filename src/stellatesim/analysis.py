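"""Degeneracy analytics on valid model populations.

Pairwise Pearson correlations over the 55 parameters (1,485 unique pairs)
and over measurement panels; pairwise distances between models in parameter
space using the min-max-normalized Euclidean metric (bounded by sqrt(55))
and the Mahalanobis metric (normalized by the distance between the all-min
and all-max corner vectors under the population covariance); nonparametric
cross-set comparisons (Kruskal-Wallis plus pairwise Mann-Whitney).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from stellatesim.parameters import ParameterSpace, load_parameter_space

MEASUREMENT_PANEL_14 = (
    "v_rmp", "sag", "r_in", "q_r", "f_r", "f_osc", "n400", "v_ap",
    "i_sta_peak", "t_ecdw", "t_tcdw", "f_sta", "q_sta", "phi_l",
)


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray  # symmetric, unit diagonal; NaN where undefined

    @property
    def n_unique_pairs(self) -> int:
        p = len(self.names)
        return p * (p - 1) // 2

    def unique_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.names), k=1)
        return self.r[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


@dataclass
class DistanceMatrix:
    ids: list
    d: np.ndarray  # symmetric, zero diagonal
    metric: str  # "normalized-euclidean" | "mahalanobis"
    normalization: float  # maximum attainable distance for this metric

    def unique_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def _pearson_matrix(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    # constant columns yield undefined correlations: report missing, not zero
    const = x.std(axis=0) == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def parameter_correlations(params: pd.DataFrame) -> CorrelationMatrix:
    """55x55 Pearson matrix across a (valid) population (needs >= 3 rows)."""
    if len(params) < 3:
        raise ValueError("need at least 3 models for correlations")
    return CorrelationMatrix(list(params.columns), _pearson_matrix(params))


def measurement_correlations(
    measurements: pd.DataFrame,
    panel: tuple[str, ...] = MEASUREMENT_PANEL_14,
) -> CorrelationMatrix:
    """Pearson matrix over a measurement panel (default: the 14-measurement
    panel of eight intrinsic and six spike-triggered-average quantities).

    Columns missing from ``measurements`` are dropped with a warning-level
    restriction rather than an error.
    """
    cols = [c for c in panel if c in measurements.columns]
    if len(cols) < 2:
        raise ValueError("fewer than two panel measurements available")
    return CorrelationMatrix(cols, _pearson_matrix(measurements[cols]))


def _minmax_scale(params: pd.DataFrame, space: ParameterSpace) -> np.ndarray:
    lo = space.lower[params.columns].to_numpy(dtype=float)
    hi = space.upper[params.columns].to_numpy(dtype=float)
    return (params.to_numpy(dtype=float) - lo) / (hi - lo)


def normalized_euclidean(
    params: pd.DataFrame, space: ParameterSpace | None = None
) -> DistanceMatrix:
    """Pairwise Euclidean distances on min-max-rescaled parameters.

    Each coordinate is rescaled to [0, 1] by its sampling range, so distances
    are bounded by sqrt(p) (= sqrt(55) for the full parameter set).
    """
    if len(params) < 2:
        raise ValueError("need at least 2 models for distances")
    space = space or load_parameter_space()
    x = _minmax_scale(params, space)
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(list(params.index), d, "normalized-euclidean",
                          float(np.sqrt(x.shape[1])))


def mahalanobis(
    params: pd.DataFrame,
    space: ParameterSpace | None = None,
    regularize: bool | None = None,
) -> DistanceMatrix:
    """Pairwise Mahalanobis distances with the covariance estimated from the
    population itself (unnormalized parameter values).

    With fewer models than parameters the sample covariance is singular;
    diagonal loading eps*I with eps = 1e-6 * trace(Sigma)/p is applied (and
    recorded in the metric tag). The normalization constant is the distance
    between the synthetic all-maximum and all-minimum corner vectors.
    """
    if len(params) < 2:
        raise ValueError("need at least 2 models for distances")
    space = space or load_parameter_space()
    x = params.to_numpy(dtype=float)
    n, p = x.shape
    sigma = np.cov(x, rowvar=False)
    if regularize is None:
        regularize = n <= p
    tag = "mahalanobis"
    if regularize:
        eps = 1e-6 * np.trace(sigma) / p
        sigma = sigma + eps * np.eye(p)
        tag = "mahalanobis(diagonal-loaded)"
    vi = np.linalg.inv(sigma)
    d = squareform(pdist(x, metric="mahalanobis", VI=vi))
    if set(params.columns) <= set(space.names):
        xmax = space.upper[params.columns].to_numpy(dtype=float)
        xmin = space.lower[params.columns].to_numpy(dtype=float)
        diff = xmax - xmin
        dmax = float(np.sqrt(diff @ vi @ diff))
    else:  # ad-hoc variable panel: no tabulated corner vectors
        dmax = float("nan")
    return DistanceMatrix(list(params.index), d, tag, dmax)


def compare_sets(
    populations: list[pd.DataFrame] | list,
    measurement: str,
) -> dict:
    """Kruskal-Wallis across sets plus two-sided pairwise Mann-Whitney tests
    on one measurement of the valid models of each set.

    Accepts Populations or plain measurement DataFrames. No multiple-testing
    correction is applied; raw p-values are reported.
    """
    samples = []
    for pop in populations:
        df = pop.valid_measurements() if hasattr(pop, "valid_measurements") else pop
        vals = df[measurement].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError("each set needs at least 2 valid models")
        samples.append(vals)
    if len(samples) < 2:
        raise ValueError("need at least 2 sets to compare")
    try:
        kw_stat, kw_p = stats.kruskal(*samples)
    except ValueError:  # all values identical across sets
        kw_stat, kw_p = 0.0, 1.0
    pairwise = {}
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            try:
                _, p = stats.mannwhitneyu(samples[i], samples[j],
                                          alternative="two-sided")
            except ValueError:
                p = 1.0
            pairwise[(i, j)] = float(p)
    return {
        "measurement": measurement,
        "kruskal_p": float(kw_p),
        "kruskal_stat": float(kw_stat),
        "mannwhitney_p": pairwise,
        "n_per_set": [len(s) for s in samples],
    }
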