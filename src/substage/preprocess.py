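"""Biomarker QC and per-feature two-component mixture modelling.

Each retained biomarker is described by a two-component Gaussian mixture:
a *normal* component (initialised from the cognitively normal arm) and an
*abnormal* component (initialised from the dementia arm), with a shared
within-component variance so that the posterior probability of
abnormality is monotone in the oriented biomarker value. Features are
first oriented so that abnormality always points upwards (dementia mean
above control mean), then screened: exactly constant columns, columns
too heavy-tailed for a Gaussian mixture (excess kurtosis above a
threshold), and columns whose EM fit fails to converge or degenerates
are removed and logged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from .containers import BiomarkerMatrix, ConfigurationError, EventProbabilityMatrix

#: fittability thresholds (see docs/methods.md)
KURTOSIS_THRESHOLD = 10.0
MAX_EM_ITER = 500
SD_COLLAPSE_TOL = 1e-6
WEIGHT_BOUNDARY = 0.01
MIN_SEPARATION = 0.5   # minimal |mean_ab - mean_no| in within-component SDs


@dataclass
class MixtureFit:
    """Two-component Gaussian fit for one oriented biomarker.

    ``status`` is ``"ok"`` for a usable fit; any other value marks the
    feature unfittable and is consumed by :func:`filter_features`.
    """

    feature: str
    mean_normal: float
    sd_normal: float
    mean_abnormal: float
    sd_abnormal: float
    weight_abnormal: float
    status: str = "ok"

    @property
    def converged(self) -> bool:
        return self.status == "ok"

    def log_densities(self, x: np.ndarray):
        """Log densities (normal, abnormal) at x; NaN -> 0 (density 1)."""
        x = np.asarray(x, dtype=float)
        miss = ~np.isfinite(x)
        xf = np.where(miss, self.mean_normal, x)
        log_no = stats.norm.logpdf(xf, self.mean_normal, self.sd_normal)
        log_ab = stats.norm.logpdf(xf, self.mean_abnormal, self.sd_abnormal)
        log_no = np.where(miss, 0.0, np.maximum(log_no, -700.0))
        log_ab = np.where(miss, 0.0, np.maximum(log_ab, -700.0))
        return log_no, log_ab

    def p_event(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of the abnormal component; NaN -> 0.5."""
        x = np.asarray(x, dtype=float)
        miss = ~np.isfinite(x)
        log_no, log_ab = self.log_densities(x)
        w = self.weight_abnormal
        num = np.log(w) + log_ab
        den = np.logaddexp(num, np.log1p(-w) + log_no)
        p = np.exp(num - den)
        return np.where(miss, 0.5, p)


def orient_features(matrix: BiomarkerMatrix, signs: Mapping[str, float] | None = None):
    """Flip feature signs so abnormality (AD mean >= CN mean) increases.

    With ``signs`` given, applies them verbatim (used to re-orient a
    validation cohort with training-derived signs). Otherwise signs are
    estimated from the CN and AD arms; both must be present.

    Returns (oriented matrix, signs as a pandas Series).
    """
    if signs is None:
        cn = matrix.arm("CN")
        ad = matrix.arm("AD")
        if cn.n_subjects == 0 or ad.n_subjects == 0:
            raise ConfigurationError(
                "orientation requires both CN and AD subjects"
            )
        diff = ad.values.mean() - cn.values.mean()
        signs = pd.Series(np.where(diff >= 0, 1.0, -1.0), index=matrix.values.columns)
    else:
        signs = pd.Series(signs, dtype=float).reindex(matrix.values.columns)
        if signs.isna().any():
            missing = list(signs.index[signs.isna()])
            raise ConfigurationError(f"no orientation sign for features: {missing}")
    oriented = BiomarkerMatrix(matrix.subjects, matrix.values * signs)
    return oriented, signs


def fit_event_mixture(values: pd.Series | np.ndarray, diagnosis: pd.Series | np.ndarray,
                      feature: str = "feature") -> MixtureFit:
    """Fit the two-component mixture for one oriented feature.

    The normal component is initialised from the CN arm and the abnormal
    component from the AD arm; components share one variance and are
    relabelled if needed so the abnormal mean is the larger one.
    Degenerate outcomes (non-convergence within 500 EM iterations,
    collapsed variance, heavy tails, boundary mixing weight) are returned
    as flagged fits, never as exceptions or NaNs.
    """
    x = np.asarray(values, dtype=float)
    dx = np.asarray(diagnosis)
    ok = np.isfinite(x)
    if ok.sum() < 20 or not (((dx == "CN") & ok).any() and ((dx == "AD") & ok).any()):
        raise ConfigurationError(
            f"{feature}: need >= 20 non-missing values spanning CN and AD arms"
        )
    xs = x[ok]
    sd_all = float(np.std(xs))
    if sd_all == 0.0:
        return MixtureFit(feature, float(xs[0]), 0.0, float(xs[0]), 0.0, 0.5,
                          status="zero_variance")
    if stats.kurtosis(xs, fisher=True) > KURTOSIS_THRESHOLD:
        return MixtureFit(feature, float(np.mean(xs)), sd_all, float(np.mean(xs)),
                          sd_all, 0.5, status="heavy_tailed")

    cn_vals = x[(dx == "CN") & ok]
    ad_vals = x[(dx == "AD") & ok]
    means_init = np.array([[np.mean(cn_vals)], [np.mean(ad_vals)]])
    w_ad = len(ad_vals) / (len(cn_vals) + len(ad_vals))
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        max_iter=MAX_EM_ITER,
        means_init=means_init,
        weights_init=np.array([1 - w_ad, w_ad]),
        reg_covar=1e-10,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(xs.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = float(np.sqrt(gm.covariances_.ravel()[0]))
    weights = gm.weights_.ravel()
    hi, lo = (1, 0) if mu[1] >= mu[0] else (0, 1)
    fit = MixtureFit(
        feature,
        mean_normal=float(mu[lo]),
        sd_normal=sd,
        mean_abnormal=float(mu[hi]),
        sd_abnormal=sd,
        weight_abnormal=float(weights[hi]),
    )
    if not gm.converged_:
        fit.status = "not_converged"
    elif sd < SD_COLLAPSE_TOL * sd_all:
        fit.status = "sd_collapse"
    elif not WEIGHT_BOUNDARY < fit.weight_abnormal < 1 - WEIGHT_BOUNDARY:
        fit.status = "boundary_weight"
    elif (fit.mean_abnormal - fit.mean_normal) < MIN_SEPARATION * sd:
        # effectively single-component: the event posterior carries no signal
        fit.status = "no_separation"
    return fit


def filter_features(matrix: BiomarkerMatrix, variance_eps: float = 0.0):
    """Remove zero-variance and mixture-unfittable features.

    Returns (filtered matrix with original signs, removal log). The log
    is a DataFrame with one row per removed feature and its reason
    (``zero_variance``, ``heavy_tailed``, ``not_converged``,
    ``sd_collapse``, ``boundary_weight``); its content does not depend on
    column order.
    """
    if not matrix.feature_names:
        raise ConfigurationError("matrix has no features")
    removed: list[tuple[str, str]] = []
    variances = matrix.values.var(ddof=0)
    keep = []
    for name in matrix.feature_names:
        if not np.isfinite(variances[name]) or variances[name] <= variance_eps:
            removed.append((name, "zero_variance"))
        else:
            keep.append(name)
    if keep:
        oriented, _ = orient_features(matrix.select_features(keep))
        retained = []
        for name in keep:
            fit = fit_event_mixture(
                oriented.values[name], oriented.diagnosis, feature=name
            )
            if fit.converged:
                retained.append(name)
            else:
                removed.append((name, fit.status))
        keep = retained
    if not keep:
        raise ConfigurationError("all features removed by quality filters")
    log = pd.DataFrame(sorted(removed), columns=["feature", "reason"])
    return matrix.select_features(keep), log


def event_probabilities(fits: Mapping[str, MixtureFit],
                        matrix: BiomarkerMatrix) -> EventProbabilityMatrix:
    """Evaluate mixture densities and event posteriors on an oriented matrix.

    Every feature of ``matrix`` must have a converged fit. Missing values
    yield posterior 0.5 and equal (unit) component densities, leaving the
    subject-level likelihood unaffected.
    """
    feats = matrix.feature_names
    bad = [f for f in feats if f not in fits or not fits[f].converged]
    if bad:
        raise ConfigurationError(f"no converged mixture fit for features: {bad}")
    n, d = matrix.n_subjects, len(feats)
    p = np.empty((n, d))
    log_ab = np.empty((n, d))
    log_no = np.empty((n, d))
    miss = np.zeros((n, d), dtype=bool)
    X = matrix.values.to_numpy(dtype=float)
    for j, name in enumerate(feats):
        fit = fits[name]
        col = X[:, j]
        miss[:, j] = ~np.isfinite(col)
        log_no[:, j], log_ab[:, j] = fit.log_densities(col)
        p[:, j] = fit.p_event(col)
    return EventProbabilityMatrix(matrix.subject_ids, feats, p, log_ab, log_no, miss)


# ---------------------------------------------------------------------------


class EventMixturePreprocessor(TransformerMixin, BaseEstimator):
    """Feature QC + orientation + mixture fitting as one transformer.

    ``fit`` learns orientation signs, the retained feature set and the
    per-feature mixtures from a training cohort (CN + AD); ``transform``
    maps any cohort measured on the same raw features to an
    :class:`EventProbabilityMatrix` using the training parameters only,
    preserving the train/validation firewall.

    Attributes
    ----------
    retained_features_ : list of surviving feature names
    removal_log_ : DataFrame (feature, reason) of dropped columns
    signs_ : orientation sign per retained feature
    fits_ : dict feature -> :class:`MixtureFit`
    """

    def __init__(self, variance_eps: float = 0.0):
        self.variance_eps = variance_eps

    def fit(self, X: BiomarkerMatrix, y=None):
        filtered, log = filter_features(X, self.variance_eps)
        oriented, signs = orient_features(filtered)
        fits = {
            name: fit_event_mixture(oriented.values[name], oriented.diagnosis,
                                    feature=name)
            for name in oriented.feature_names
        }
        self.retained_features_ = oriented.feature_names
        self.removal_log_ = log
        self.signs_ = signs
        self.fits_ = fits
        return self

    def transform(self, X: BiomarkerMatrix) -> EventProbabilityMatrix:
        if not hasattr(self, "fits_"):
            raise ConfigurationError("preprocessor is not fitted")
        sub = X.select_features(self.retained_features_)
        oriented, _ = orient_features(sub, signs=self.signs_)
        return event_probabilities(self.fits_, oriented)

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        doc = {
            "variance_eps": self.variance_eps,
            "signs": {k: float(v) for k, v in self.signs_.items()},
            "fits": {k: asdict(v) for k, v in self.fits_.items()},
            "removal_log": self.removal_log_.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EventMixturePreprocessor":
        doc = json.loads(Path(path).read_text())
        pre = cls(variance_eps=doc["variance_eps"])
        pre.signs_ = pd.Series(doc["signs"])
        pre.fits_ = {k: MixtureFit(**v) for k, v in doc["fits"].items()}
        pre.removal_log_ = pd.DataFrame(
            doc["removal_log"], columns=["feature", "reason"]
        )
        pre.retained_features_ = list(pre.fits_)
        return pre
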