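"""Length-stratified PLS QSAR of log10(IC50) on z-scale descriptors.

The regression engine is an in-house NIPALS partial least-squares
implementation (univariate response), because the modelling procedure itself
— two latent components, autoscaling, t,u-score outlier pruning — is the
method this package exists to provide.  It follows the SIMCA defaults:

* X and y are autoscaled (mean-centred, unit variance, ddof=1) before
  component extraction; zero-variance descriptor columns are tolerated
  (scale 1) but flagged.
* Two components by default; overridable.
* The t,u inner relation ``u_a ≈ b_a · t_a`` is used for outlier pruning:
  with a univariate response the y-side score u_a is the current y residual,
  the inner-relation slope b_a equals the y loading q_a, and the
  inner-relation residual is exactly the y residual after deflating
  component a.  Samples whose standardized residual exceeds a threshold
  (default 2.5 SD) in any component are removed and the model refit, up to
  a bounded number of rounds — an explicit operationalization of pruning
  "by eye" from t,u score plots.

Model quality is reported as the training R² and the leave-one-out
cross-validated Q² (1 − PRESS/SS_tot).  IC50 values are µM throughout;
training sets admit only IC50 < 15 mM (15,000 µM).  The activity transform
is log base 10 (monotone, so threshold screening is base-invariant).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .zscale import encode_peptide, encode_peptides

IC50_ADMISSION_UM = 15_000.0  # 15 mM admission bound for training peptides
SUPPORTED_LENGTHS = (3, 6, 7, 8)
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QsarDataset:
    """Training records (peptide, IC50 µM) for one peptide length class."""

    sequences: tuple[str, ...]
    ic50_um: np.ndarray
    length_class: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ic50_um", np.asarray(self.ic50_um, float))
        if len(self.sequences) != len(self.ic50_um):
            raise ValueError("sequences and ic50 values differ in length")
        if any(len(s) != self.length_class for s in self.sequences):
            raise ValueError(f"all peptides must have length {self.length_class}")
        if np.any(self.ic50_um <= 0):
            raise ValueError("IC50 values must be positive (µM)")
        if np.any(self.ic50_um >= IC50_ADMISSION_UM):
            raise ValueError(
                f"IC50 values must be below the {IC50_ADMISSION_UM:g} µM "
                "admission bound; use QsarDataset.admit() to filter"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def admit(cls, sequences: Sequence[str], ic50_um: Sequence[float],
              length_class: int) -> "QsarDataset":
        """Build a dataset, dropping records at/above the 15 mM admission bound."""
        ic50 = np.asarray(ic50_um, float)
        keep = ic50 < IC50_ADMISSION_UM
        return cls(tuple(s for s, k in zip(sequences, keep) if k),
                   ic50[keep], length_class)

    @classmethod
    def from_csv(cls, path: str | Path, length_class: int) -> "QsarDataset":
        """Read a training CSV with columns ``peptide, ic50_uM``."""
        df = pd.read_csv(path, comment="#")
        df = df[df["peptide"].str.len() == length_class]
        return cls.admit(df["peptide"].tolist(), df["ic50_uM"].to_numpy(),
                         length_class)

    @property
    def log_ic50(self) -> np.ndarray:
        return np.log10(self.ic50_um)

    def descriptors(self) -> np.ndarray:
        return encode_peptides(self.sequences)

    def drop(self, indices: Sequence[int]) -> "QsarDataset":
        drop = set(indices)
        keep = [i for i in range(len(self)) if i not in drop]
        return QsarDataset(tuple(self.sequences[i] for i in keep),
                           self.ic50_um[keep], self.length_class)


@dataclass
class PlsModel:
    """A fitted NIPALS PLS regression of log10(IC50) on descriptors."""

    length_class: int
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray        # W, (p × A)
    x_loadings: np.ndarray     # P, (p × A)
    y_loadings: np.ndarray     # q, (A,)
    scores_t: np.ndarray       # T, (n × A), X-side
    scores_u: np.ndarray       # U, (n × A), y-side
    coefficients: np.ndarray   # B on the original descriptor scale, (p,)
    intercept: float
    r2: float
    q2: float | None = None
    excluded_indices: tuple[int, ...] = ()
    zero_variance_columns: tuple[int, ...] = ()

    def predict_log_ic50(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + np.atleast_2d(x) @ self.coefficients

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v
        payload = {k: enc(v) for k, v in vars(self).items()}
        payload["excluded_indices"] = list(self.excluded_indices)
        payload["zero_variance_columns"] = list(self.zero_variance_columns)
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PlsModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        arrays = {"x_mean", "x_scale", "weights", "x_loadings", "y_loadings",
                  "scores_t", "scores_u", "coefficients"}
        kwargs = {
            k: (np.asarray(v, float) if k in arrays else v)
            for k, v in payload.items()
        }
        kwargs["excluded_indices"] = tuple(kwargs["excluded_indices"])
        kwargs["zero_variance_columns"] = tuple(kwargs["zero_variance_columns"])
        return cls(**kwargs)


@dataclass(frozen=True)
class PredictionRecord:
    """QSAR prediction for one peptide."""

    peptide: str
    predicted_log_ic50: float
    predicted_ic50: float
    model_length_class: int


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

def _autoscale(X: np.ndarray, y: np.ndarray):
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
    zero_var = tuple(int(j) for j in np.flatnonzero(x_scale < _EPS))
    x_scale = np.where(x_scale < _EPS, 1.0, x_scale)
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=1)) if len(y) > 1 else 1.0
    if y_scale < _EPS:
        raise ValueError("response y is constant; nothing to regress")
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    return Xs, ys, x_mean, x_scale, y_mean, y_scale, zero_var


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int = 2,
            *, length_class: int | None = None) -> PlsModel:
    """Fit a NIPALS PLS regression of y on X with autoscaling.

    Deterministic given input order.  If the data run out of structure before
    ``n_components`` (X residual vanishes), the remaining components are zero.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if n < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} samples, got {n}"
        )
    Xs, ys, x_mean, x_scale, y_mean, y_scale, zero_var = _autoscale(X, y)

    A = n_components
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    T = np.zeros((n, A))
    U = np.zeros((n, A))

    Xr, yr = Xs.copy(), ys.copy()
    for a in range(A):
        w = Xr.T @ yr
        wn = np.linalg.norm(w)
        if wn < _EPS:       # no covariance left to model
            break
        w /= wn
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        W[:, a] = w
        T[:, a] = t
        U[:, a] = yr        # univariate y: the y-side score is the y residual
        P[:, a] = Xr.T @ t / tt
        q[a] = float(yr @ t) / tt
        Xr = Xr - np.outer(t, P[:, a])
        yr = yr - q[a] * t

    # regression vector on the scaled data: B_s = W (PᵀW)⁻¹ q
    PtW = P.T @ W
    B_scaled = W @ np.linalg.solve(PtW + np.eye(A) * (_EPS * (np.abs(PtW).max() or 1)),
                                   q)
    coefficients = y_scale * B_scaled / x_scale
    intercept = y_mean - float(x_mean @ coefficients)

    fitted = intercept + X @ coefficients
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    return PlsModel(
        length_class=length_class if length_class is not None else p // 5,
        n_components=n_components,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        weights=W, x_loadings=P, y_loadings=q, scores_t=T, scores_u=U,
        coefficients=coefficients, intercept=intercept, r2=r2,
        zero_variance_columns=zero_var,
    )


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> float:
    """Leave-one-out cross-validated Q² = 1 − PRESS / SS_tot."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out validation needs at least 3 samples")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        model = fit_pls(X[mask], y[mask], n_components)
        press += float((y[i] - model.predict_log_ic50(X[i])[0]) ** 2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def fit_dataset(dataset: QsarDataset, n_components: int = 2,
                *, with_q2: bool = True) -> PlsModel:
    """Encode a training dataset and fit its length-class PLS model."""
    X = dataset.descriptors()
    y = dataset.log_ic50
    model = fit_pls(X, y, n_components, length_class=dataset.length_class)
    if with_q2:
        model.q2 = loo_q2(X, y, n_components)
    return model


# ---------------------------------------------------------------------------
# t,u-score outlier pruning
# ---------------------------------------------------------------------------

def inner_relation_residuals(model: PlsModel) -> np.ndarray:
    """Standardized t,u inner-relation residuals, one column per component.

    The residual of sample j at component a is ``u_a[j] − b_a t_a[j]`` with
    inner slope ``b_a = q_a``; columns are standardized to unit SD.
    """
    resid = model.scores_u - model.scores_t * model.y_loadings
    sd = resid.std(axis=0, ddof=1)
    sd = np.where(sd < _EPS, 1.0, sd)
    return resid / sd


def exclude_outliers(model: PlsModel, dataset: QsarDataset,
                     threshold_sd: float = 2.5, max_rounds: int = 5
                     ) -> tuple[QsarDataset, PlsModel]:
    """Iteratively drop samples off the t,u inner relation and refit.

    A sample is an outlier when its standardized inner-relation residual
    exceeds ``threshold_sd`` in any component.  Stops when no sample exceeds
    the threshold, after ``max_rounds`` refits, or (with a warning recorded
    on the model) when pruning would leave fewer than n_components + 2
    samples.  Removed indices (in the original dataset's numbering) are
    recorded on the returned model.
    """
    current = dataset
    original_indices = list(range(len(dataset)))
    removed: list[int] = []
    for _ in range(max_rounds):
        if not np.isfinite(threshold_sd):
            break
        resid = inner_relation_residuals(model)
        flagged = np.flatnonzero(np.any(np.abs(resid) > threshold_sd, axis=1))
        if flagged.size == 0:
            break
        if len(current) - flagged.size < model.n_components + 2:
            break  # keep last valid model rather than collapse the fit
        removed.extend(original_indices[i] for i in flagged)
        original_indices = [idx for i, idx in enumerate(original_indices)
                            if i not in set(flagged.tolist())]
        current = current.drop(flagged.tolist())
        model = fit_dataset(current, model.n_components, with_q2=False)
    model.q2 = loo_q2(current.descriptors(), current.log_ic50, model.n_components)
    model.excluded_indices = tuple(sorted(removed))
    return current, model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: PlsModel, peptide: str) -> PredictionRecord:
    """Predict the IC50 (µM) of a peptide with its length-class model."""
    if len(peptide) != model.length_class:
        raise ValueError(
            f"peptide {peptide!r} has length {len(peptide)}; this model handles "
            f"length {model.length_class} — use the model trained for "
            f"{len(peptide)}-residue peptides"
        )
    log_ic50 = float(model.predict_log_ic50(encode_peptide(peptide))[0])
    return PredictionRecord(
        peptide=peptide,
        predicted_log_ic50=log_ic50,
        predicted_ic50=float(10.0 ** log_ic50),
        model_length_class=model.length_class,
    )


def predict_many(models: dict[int, PlsModel],
                 peptides: Sequence[str]) -> list[PredictionRecord]:
    """Route each peptide to the model for its length; skip lengths without one."""
    return [
        predict(models[len(p)], p)
        for p in peptides
        if len(p) in models
    ]
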