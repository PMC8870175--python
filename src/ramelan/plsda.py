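"""PLS-DA classification of lesion samples from their mean spectra.

One mean spectrum per sample (the average of its 15-20 acquired spectra)
is regressed against dummy class-membership columns with NIPALS PLS2
(mean-centering only — spectra share units, so no autoscaling). A sample
is predicted as the class whose dummy response is largest.

Three binary schemes mirror the clinical questions: the dysplastic-nevus
class against everything else ("dn_vs_rest"), against melanoma only
("dn_vs_mm"), and against compound nevus only ("dn_vs_cn").

Cross-validation is venetian blinds: rows are deterministically ordered by
(class, sample_id) and row i goes to fold i mod n_splits; each fold is
refit from scratch (including re-centering). Variable Importance in
Projection (VIP) scores identify the wavenumbers that drive the model;
they are normalized so that the squared VIPs average to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SpectralDataset
from .errors import CVError, ConfigurationError, ConsistencyError, FitError

logger = logging.getLogger(__name__)

#: scheme name -> mapping from lesion class to scheme class (absent
#: lesion classes are excluded from the scheme)
SCHEMES: dict[str, dict[str, str]] = {
    "dn_vs_rest": {"DN": "DN", "MM": "MM+CN", "CN": "MM+CN"},
    "dn_vs_mm": {"DN": "DN", "MM": "MM"},
    "dn_vs_cn": {"DN": "DN", "CN": "CN"},
}


@dataclass(frozen=True)
class SampleSpectrumMatrix:
    """One mean spectrum per sample, deterministically ordered."""

    spectra: np.ndarray  # n_samples x n_channels
    labels: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != self.spectra.shape[0] or len(self.sample_ids) != len(
            self.labels
        ):
            raise ConsistencyError("labels/sample_ids do not match the matrix")


def build_sample_matrix(dataset: SpectralDataset) -> SampleSpectrumMatrix:
    """Average each sample's spectra; rows ordered by (class, sample_id)."""
    meta = dataset.meta
    if meta["class_label"].isna().any():
        raise ConsistencyError("classification needs a class label per spectrum")
    per_sample = meta.groupby("sample_id", sort=False)["class_label"].nunique()
    if (per_sample > 1).any():
        bad = per_sample[per_sample > 1].index.tolist()
        raise ConsistencyError(f"samples with mixed class labels: {bad}")
    key = meta[["sample_id", "class_label"]].drop_duplicates()
    key = key.sort_values(["class_label", "sample_id"]).reset_index(drop=True)
    rows = []
    for sample_id in key["sample_id"]:
        mask = (meta["sample_id"] == sample_id).to_numpy()
        rows.append(dataset.intensity_matrix[mask].mean(axis=0))
    return SampleSpectrumMatrix(
        spectra=np.vstack(rows),
        labels=tuple(key["class_label"]),
        sample_ids=tuple(key["sample_id"]),
    )


def _apply_scheme(
    matrix: SampleSpectrumMatrix, scheme: str
) -> tuple[np.ndarray, list[str], list[str]]:
    if scheme not in SCHEMES:
        raise ConfigurationError(
            f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}"
        )
    mapping = SCHEMES[scheme]
    keep = [i for i, lab in enumerate(matrix.labels) if lab in mapping]
    labels = [mapping[matrix.labels[i]] for i in keep]
    ids = [matrix.sample_ids[i] for i in keep]
    return matrix.spectra[keep], labels, ids


@dataclass
class PLSDAModel:
    """Fitted NIPALS PLS2 discriminant model."""

    scheme: str
    classes: tuple[str, ...]
    n_latent_variables: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # c x A
    x_scores: np.ndarray  # n x A
    coefficients: np.ndarray = field(init=False)  # p x c

    def __post_init__(self) -> None:
        pw = self.x_loadings.T @ self.weights
        self.coefficients = (
            self.weights @ np.linalg.solve(pw, self.y_loadings.T)
        )

    def decision_values(self, spectra: np.ndarray) -> np.ndarray:
        """Predicted dummy responses, one column per class."""
        return (np.atleast_2d(spectra) - self.x_mean) @ self.coefficients + self.y_mean

    def predict(self, spectra: np.ndarray) -> list[str]:
        y = self.decision_values(spectra)
        return [self.classes[i] for i in np.argmax(y, axis=1)]


def _nipals_pls2(
    x: np.ndarray, y: np.ndarray, n_lv: int, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, p = x.shape
    c = y.shape[1]
    weights = np.zeros((p, n_lv))
    x_loadings = np.zeros((p, n_lv))
    y_loadings = np.zeros((c, n_lv))
    x_scores = np.zeros((n, n_lv))
    xa, ya = x.copy(), y.copy()
    for a in range(n_lv):
        u = ya[:, int(np.argmax(ya.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = ya[:, 0] + 1e-12
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = xa.T @ u
            norm_w = np.linalg.norm(w)
            if norm_w == 0:
                raise FitError(f"degenerate predictor matrix at LV {a + 1}")
            w /= norm_w
            t = xa @ w
            tt = float(t @ t)
            if tt == 0:
                raise FitError(f"zero-variance score at LV {a + 1}")
            q = ya.T @ t / tt
            qq = float(q @ q)
            if qq == 0:
                break
            u = ya @ q / qq
            if np.linalg.norm(t - t_old) <= tol * max(np.linalg.norm(t), 1e-300):
                break
            t_old = t
        p_load = xa.T @ t / tt
        xa = xa - np.outer(t, p_load)
        ya = ya - np.outer(t, q)
        weights[:, a] = w
        x_loadings[:, a] = p_load
        y_loadings[:, a] = q
        x_scores[:, a] = t
    return weights, x_loadings, y_loadings, x_scores


def _fit_mapped(x: np.ndarray, labels: list[str], scheme: str, n_lv: int) -> PLSDAModel:
    """Fit on scheme-mapped labels (the CV refits land here directly)."""
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ConfigurationError(f"scheme {scheme!r} leaves fewer than 2 classes")
    n, p = x.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ConfigurationError(
            f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}"
        )
    y = np.array([[1.0 if lab == cl else 0.0 for cl in classes] for lab in labels])
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    if np.allclose(xc, 0):
        raise FitError("constant predictor matrix")
    weights, x_loadings, y_loadings, x_scores = _nipals_pls2(
        xc, y - y_mean, n_lv
    )
    return PLSDAModel(
        scheme=scheme,
        classes=classes,
        n_latent_variables=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        x_scores=x_scores,
    )


def fit_plsda(matrix: SampleSpectrumMatrix, scheme: str, n_lv: int) -> PLSDAModel:
    """Fit the PLS-DA model for one classification scheme."""
    x, labels, _ = _apply_scheme(matrix, scheme)
    return _fit_mapped(x, labels, scheme, n_lv)


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable Importance in Projection per channel.

    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ), where
    SS_a is the response sum of squares explained by latent variable a.
    The squared VIPs therefore average exactly to 1.
    """
    p = model.weights.shape[0]
    tt = np.sum(model.x_scores**2, axis=0)
    ss = tt * np.sum(model.y_loadings**2, axis=0)
    total = ss.sum()
    if total <= 0:
        raise FitError("model explains no response variance; VIP undefined")
    w_norm = model.weights / np.linalg.norm(model.weights, axis=0, keepdims=True)
    return np.sqrt(p * (w_norm**2 @ ss) / total)


@dataclass(frozen=True)
class ConfusionMatrix:
    """One-vs-rest counts per class, aggregated over CV folds."""

    counts: pd.DataFrame  # index: class; columns: tp, fn, fp, tn

    @property
    def n_samples(self) -> int:
        row = self.counts.iloc[0]
        return int(row["tp"] + row["fn"] + row["fp"] + row["tn"])

    def sensitivity(self, label: str) -> float:
        row = self.counts.loc[label]
        return round(100.0 * row["tp"] / (row["tp"] + row["fn"]), 1)

    def specificity(self, label: str) -> float:
        row = self.counts.loc[label]
        return round(100.0 * row["tn"] / (row["tn"] + row["fp"]), 1)

    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sensitivity_percent": [
                    self.sensitivity(c) for c in self.counts.index
                ],
                "specificity_percent": [
                    self.specificity(c) for c in self.counts.index
                ],
            },
            index=self.counts.index,
        )


def confusion_from_predictions(
    truth: list[str], predicted: list[str], classes: tuple[str, ...]
) -> ConfusionMatrix:
    counts = {}
    truth_arr = np.array(truth)
    pred_arr = np.array(predicted)
    for cl in classes:
        is_cl = truth_arr == cl
        pred_cl = pred_arr == cl
        counts[cl] = {
            "tp": int(np.sum(is_cl & pred_cl)),
            "fn": int(np.sum(is_cl & ~pred_cl)),
            "fp": int(np.sum(~is_cl & pred_cl)),
            "tn": int(np.sum(~is_cl & ~pred_cl)),
        }
    return ConfusionMatrix(pd.DataFrame(counts).T[["tp", "fn", "fp", "tn"]])


def venetian_blinds_cv(
    matrix: SampleSpectrumMatrix,
    scheme: str,
    n_lv: int,
    n_splits: int = 10,
) -> tuple[ConfusionMatrix, pd.DataFrame]:
    """Interleaved k-fold CV: ordered sample i is held out in fold i mod k.

    Returns the aggregated one-vs-rest confusion matrix and the per-class
    sensitivity/specificity table (percent, one decimal).
    """
    x, labels, ids = _apply_scheme(matrix, scheme)
    n = x.shape[0]
    if n < n_splits:
        raise CVError(f"{n} samples cannot fill {n_splits} venetian blinds")
    classes = tuple(sorted(set(labels)))
    folds = np.arange(n) % n_splits
    predictions: list[str | None] = [None] * n
    for fold in range(n_splits):
        test = folds == fold
        train = ~test
        train_labels = [labels[i] for i in np.where(train)[0]]
        if set(train_labels) != set(classes):
            raise CVError(f"fold {fold} training set lost a class")
        model = _fit_mapped(x[train], train_labels, scheme, n_lv)
        for i, pred in zip(np.where(test)[0], model.predict(x[test])):
            predictions[i] = pred
    confusion = confusion_from_predictions(labels, predictions, classes)
    return confusion, confusion.metrics()


def select_n_lv(
    matrix: SampleSpectrumMatrix,
    scheme: str,
    max_lv: int = 10,
    n_splits: int = 10,
) -> int:
    """Latent-variable count minimizing CV misclassifications (ties -> fewer)."""
    x, labels, _ = _apply_scheme(matrix, scheme)
    cap = min(x.shape[0] - 1 - (x.shape[0] // n_splits), x.shape[1])
    if max_lv > cap:
        logger.warning("max_lv %d capped to %d", max_lv, cap)
        max_lv = cap
    best_lv, best_errors = 1, np.inf
    for n_lv in range(1, max_lv + 1):
        confusion, _ = venetian_blinds_cv(matrix, scheme, n_lv, n_splits)
        errors = int(confusion.counts["fn"].sum())
        if errors < best_errors:
            best_lv, best_errors = n_lv, errors
    return best_lv
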