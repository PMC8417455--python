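"""Predictive pHFA score: whitening -> PCA (95% variance) -> logistic regression.

The pathological high-frequency activity (pHFA) score is a per-channel value
in [0, 1] estimating how likely the channel's interictal high-frequency
background is pathological (inside the seizure-onset zone).  To avoid
in-sample optimism, scores are produced with hold-out-one-patient
cross-validation: each patient's channels are scored by a model trained on
every other patient.

Per training fold:

1. whiten each of the 38 time-integrated features with the training mean and
   (n-1) standard deviation;
2. project onto the smallest number of principal components capturing at
   least 95% of the training variance;
3. fit an (unregularised) logistic regression of SOZ membership on the
   component scores.  On complete separation the fit falls back to a tiny
   ridge penalty (1e-6) with a warning, keeping the output deterministic.

Held-out channels are transformed with the training whitening and loadings
only.  The product of the pHFA score with the channel's HFO rate (events/min)
gives a hybrid biomarker that is high only where both agree, analogous to a
logical AND and insensitive to the differing units of the two measures.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

VARIANCE_THRESHOLD = 0.95
RIDGE_FALLBACK = 1e-6


def _logistic_fit(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Newton IRLS logistic fit; ridge fallback on separation. Returns (k+1,) coefs."""
    X = np.column_stack([np.ones(len(Z)), Z])

    def irls(alpha: float) -> np.ndarray | None:
        beta = np.zeros(X.shape[1])
        pen = np.full(X.shape[1], alpha)
        pen[0] = 0.0  # intercept unpenalised
        for _ in range(200):
            eta = np.clip(X @ beta, -500, 500)
            p = 1.0 / (1.0 + np.exp(-eta))
            W = p * (1.0 - p)
            g = X.T @ (y - p) - pen * beta
            H = (X.T * W) @ X + np.diag(pen)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                return None
            beta = beta + step
            if not np.all(np.isfinite(beta)):
                return None
            if np.max(np.abs(step)) < 1e-10:
                return beta
        return None

    beta = irls(0.0)
    if beta is None or np.max(np.abs(beta)) > 30:
        # separation: the unpenalised MLE diverges.  Use the smallest ridge
        # penalty on the escalation ladder that yields a converged fit.
        for alpha in (RIDGE_FALLBACK, 1e-3, 1e-1):
            warnings.warn(
                f"logistic separation: falling back to ridge penalty {alpha:g}"
            )
            beta = irls(alpha)
            if beta is not None:
                break
        if beta is None:
            raise RuntimeError("logistic fit failed even with ridge fallback")
    return beta


@dataclass
class PhfaFit:
    """Fitted fold model: whitening parameters, PCA loadings, logistic coefs."""

    mean_: np.ndarray
    sd_: np.ndarray
    loadings_: np.ndarray  # (n_features, k), orthonormal columns
    explained_variance_ratio_: np.ndarray
    k_: int
    coef_: np.ndarray  # (k+1,) with intercept first
    feature_names_: list = field(default_factory=list)

    def transform(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Whiten with training statistics and project onto the training PCs."""
        X = self._as_matrix(features)
        return ((X - self.mean_) / self.sd_) @ self.loadings_

    def score(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        """pHFA score in [0, 1] per channel."""
        Z = self.transform(features)
        eta = self.coef_[0] + Z @ self.coef_[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))

    def _as_matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if self.feature_names_ and list(features.columns) != self.feature_names_:
                features = features[self.feature_names_]
            return np.ascontiguousarray(features.to_numpy(dtype=np.float64))
        X = np.asarray(features, dtype=np.float64)
        if X.shape[1] != len(self.mean_):
            raise ValueError(
                f"expected {len(self.mean_)} features, got {X.shape[1]}"
            )
        return X


@dataclass
class PhfaModel:
    """Single-fold pHFA model (statsmodels-style Model -> fit -> results).

    Parameters
    ----------
    features : pandas.DataFrame
        Training channels x time-integrated feature columns.
    labels : array-like of {0, 1}
        SOZ membership of the training channels.
    """

    features: pd.DataFrame
    labels: np.ndarray
    variance_threshold: float = VARIANCE_THRESHOLD

    def fit(self) -> PhfaFit:
        # canonical C layout: reduction order (hence low-order bits) must not
        # depend on the DataFrame's internal block layout
        X = np.ascontiguousarray(self.features.to_numpy(dtype=np.float64))
        y = np.asarray(self.labels, dtype=np.float64)
        if len(X) != len(y):
            raise ValueError("features and labels must align")
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValueError("both classes must be present in training data")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        dead = ~(sd > 0)
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} zero-variance feature(s); sd set to 1"
            )
            sd = np.where(dead, 1.0, sd)
        Z = (X - mean) / sd
        pca = PCA(svd_solver="full").fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_threshold) + 1)
        k = min(k, len(cum))
        loadings = pca.components_[:k].T
        coef = _logistic_fit(Z @ loadings, y)
        return PhfaFit(
            mean_=mean,
            sd_=sd,
            loadings_=loadings,
            explained_variance_ratio_=pca.explained_variance_ratio_[:k],
            k_=k,
            coef_=coef,
            feature_names_=list(self.features.columns),
        )


def product_score(phfa: np.ndarray, hfo_rate: np.ndarray) -> np.ndarray:
    """Hybrid biomarker: elementwise pHFA x HFO-rate (units events/min)."""
    phfa = np.asarray(phfa, dtype=np.float64)
    hfo_rate = np.asarray(hfo_rate, dtype=np.float64)
    if np.any(hfo_rate < 0):
        raise ValueError("HFO rates must be nonnegative")
    return phfa * hfo_rate


@dataclass
class LopoResults:
    """Hold-out-one-patient cross-validated channel scores."""

    scores: pd.DataFrame  # patient, channel, soz, phfa[, hfo_rate, product], fold_k
    fold_models: dict  # patient -> PhfaFit
    failed_folds: dict  # patient -> reason

    def summary(self) -> str:
        ks = {p: m.k_ for p, m in self.fold_models.items()}
        lines = [
            f"LOPO pHFA scores: {len(self.scores)} channels, "
            f"{len(self.fold_models)} folds "
            f"(components per fold: min {min(ks.values())}, "
            f"max {max(ks.values())})"
        ]
        if self.failed_folds:
            lines.append(f"failed folds: {sorted(self.failed_folds)}")
        return "\n".join(lines)


def lopo_scores(
    features: pd.DataFrame,
    labels: np.ndarray,
    patients: np.ndarray,
    hfo_rates: np.ndarray | None = None,
    channels: np.ndarray | None = None,
    variance_threshold: float = VARIANCE_THRESHOLD,
) -> LopoResults:
    """Score every channel via hold-out-one-patient cross-validation.

    Each patient's channels are scored exactly once, by a model trained on all
    remaining patients.  A fold whose training data contain one class fails
    loudly (recorded in ``failed_folds``) while the other folds proceed.
    """
    labels = np.asarray(labels, dtype=np.float64)
    patients = np.asarray(patients)
    channels = (
        np.asarray(features.index) if channels is None else np.asarray(channels)
    )
    rates = None if hfo_rates is None else np.asarray(hfo_rates, dtype=np.float64)
    uniq = np.unique(patients)
    if uniq.size < 3:
        raise ValueError("LOPO cross-validation needs >= 3 patients")
    rows = []
    fold_models: dict = {}
    failed: dict = {}
    for held in uniq:
        test = patients == held
        train = ~test
        try:
            fit = PhfaModel(
                features[train], labels[train], variance_threshold
            ).fit()
        except ValueError as exc:
            warnings.warn(f"fold {held!r} failed: {exc}")
            failed[held] = str(exc)
            continue
        fold_models[held] = fit
        sub = pd.DataFrame(
            {
                "patient": patients[test],
                "channel": channels[test],
                "soz": labels[test].astype(int),
                "phfa": fit.score(features[test]),
                "fold_k": fit.k_,
            }
        )
        if rates is not None:
            sub["hfo_rate"] = rates[test]
            sub["product"] = product_score(
                sub["phfa"].to_numpy(), sub["hfo_rate"].to_numpy()
            )
        rows.append(sub)
    scores = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return LopoResults(scores=scores, fold_models=fold_models, failed_folds=failed)
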