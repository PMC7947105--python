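"""Internal/external validation battery and applicability domain.

Implements the statistics conventionally demanded of a QSAR model before
it is trusted for prediction:

* training R², adjusted R², SEE, Friedman LOF;
* leave-one-out cross-validated Q²;
* external R²pred against a reference mean activity, and the squared
  Pearson correlation of experimental vs predicted test activities;
* per-descriptor variance-inflation factors and mean effects;
* Y-randomization (cRp²) against chance correlation;
* leverage-based applicability domain with the warning threshold
  h* = 3(p+1)/n and Williams-plot data (standardized residual vs
  leverage).

A checklist compares the results with the generally recommended minima
(R² ≥ 0.6, Q² ≥ 0.5, R² − Q² < 0.3, ≥ 5 external compounds, cRp² ≥ 0.5).

Two conventions exist in the literature for the reference mean in R²pred:
the mean of the training activities, or the mean over all compounds.  The
published worked example uses the all-compound mean (4.3699 rather than
the training mean 4.4348); ``reference_mean_convention`` selects which.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataio import QsarDataset
from .linear_model import LinearModel, fit_ols, lof as lof_stat, predict, see as see_stat

__all__ = [
    "ValidationReport",
    "AdResult",
    "r_squared",
    "adjusted_r2",
    "q2_loo",
    "r2_pred",
    "pearson_r",
    "vif_all",
    "mean_effects",
    "leverages",
    "warning_leverage",
    "williams_data",
    "y_randomization",
    "build_report",
    "CHECKLIST_THRESHOLDS",
]

CHECKLIST_THRESHOLDS = {
    "r2": 0.6,            # coefficient of determination >= 0.6
    "q2_loo": 0.5,        # cross-validated R-squared >= 0.5
    "r2_minus_q2": 0.3,   # R^2 - Q^2 < 0.3
    "n_test": 5,          # external test compounds >= 5
    "crp2": 0.5,          # Y-randomization coefficient >= 0.5
}


@dataclass
class AdResult:
    """Applicability-domain verdict for one compound."""

    compound_id: str
    leverage: float
    standardized_residual: float
    in_domain: bool
    partition: str = ""


@dataclass
class ValidationReport:
    r2: float
    r2_adjusted: float
    q2_loo: float
    r2_pred: float
    r2_test_pearson: float
    see: float
    lof: float
    reference_mean: float
    reference_mean_convention: str
    per_descriptor: pd.DataFrame
    pearson_matrix: pd.DataFrame
    warning_leverage: float
    ad_results: list[AdResult]
    checklist: dict[str, bool]
    y_randomization: Optional[tuple[float, float]] = None  # (mean R²_r, cRp²)

    @property
    def influential_compounds(self) -> list[str]:
        return [
            r.compound_id
            for r in self.ad_results
            if r.leverage > self.warning_leverage
        ]

    @property
    def outliers(self) -> list[str]:
        return [
            r.compound_id
            for r in self.ad_results
            if abs(r.standardized_residual) > 3
        ]

    @property
    def all_pass(self) -> bool:
        return all(self.checklist.values())


def r_squared(y_exp: np.ndarray, y_pred: np.ndarray, y_ref_mean: float) -> float:
    """1 − Σ(exp−pred)² / Σ(exp−ref_mean)²."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    den = float(((y_exp - y_ref_mean) ** 2).sum())
    if den == 0:
        raise ValueError("zero denominator: experimental values equal the reference mean")
    return 1.0 - float(((y_exp - y_pred) ** 2).sum()) / den


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Standard adjusted R²: 1 − (1−R²)(n−1)/(n−p−1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n} <= p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _hat_diagonal(X: np.ndarray) -> np.ndarray:
    A = np.column_stack([np.ones(X.shape[0]), X])
    G = A.T @ A
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular design cross-product") from exc
    return np.einsum("ij,jk,ik->i", A, Ginv, A)


def q2_loo(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated R² (PRESS-based).

    Uses the hat-matrix identity ``e_i / (1 − h_ii)`` for the deleted
    residuals, which equals refitting the model without each compound.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError(f"LOO needs n > p+2, got n={n}, p={p}")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise ValueError("rank-deficient design in leave-one-out refits")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    h = _hat_diagonal(X)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("a leave-one-out refit is rank-deficient (leverage 1)")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant activity vector")
    return 1.0 - press / ss_tot


def r2_pred(
    y_exp_test: np.ndarray, y_pred_test: np.ndarray, reference_mean: float
) -> float:
    """External predictivity: 1 − Σ(pred−exp)² / Σ(exp−ref_mean)²."""
    y_exp_test = np.asarray(y_exp_test, dtype=float)
    y_pred_test = np.asarray(y_pred_test, dtype=float)
    if y_exp_test.size < 1 or y_exp_test.shape != y_pred_test.shape:
        raise ValueError("need equal-length, nonempty test vectors")
    den = float(((y_exp_test - reference_mean) ** 2).sum())
    if den == 0:
        raise ValueError("zero denominator in R²pred")
    num = float(((y_pred_test - y_exp_test) ** 2).sum())
    return 1.0 - num / den


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def vif_all(X: np.ndarray, descriptor_names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor 1/(1−R²_j) for each descriptor.

    R²_j comes from regressing descriptor j on all the others (with
    intercept).  Perfectly collinear descriptors get ``inf`` rather than an
    exception.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two descriptors")
    names = descriptor_names or [f"x{j}" for j in range(p)]
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ beta
        ss_tot = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2_j = 1.0 - float((resid**2).sum()) / ss_tot
        out[j] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return pd.Series(out, index=names, name="VIF")


def mean_effects(model: LinearModel, X_train: np.ndarray) -> pd.Series:
    """Normalized descriptor contributions B_j·ΣD_j / Σ_j(B_j·ΣD_j); sum to 1."""
    X_train = np.asarray(X_train, dtype=float)
    col_sums = X_train.sum(axis=0)
    weighted = model.coefficients * col_sums
    total = weighted.sum()
    if total == 0:
        raise ValueError("mean effects undefined: weighted column sums cancel")
    return pd.Series(weighted / total, index=model.descriptor_names, name="ME")


def leverages(X_train: np.ndarray, X_query: np.ndarray | None = None) -> np.ndarray:
    """Leverage h_i = x_i (XᵀX)⁻¹ x_iᵀ with an intercept column appended.

    With ``X_query`` omitted, returns the training self-leverages (the hat
    matrix diagonal), which lie in [1/n, 1] and sum to p+1.
    """
    X_train = np.asarray(X_train, dtype=float)
    A = np.column_stack([np.ones(X_train.shape[0]), X_train])
    G = A.T @ A
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular training cross-product") from exc
    if X_query is None:
        Q = A
    else:
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        Q = np.column_stack([np.ones(X_query.shape[0]), X_query])
    return np.einsum("ij,jk,ik->i", Q, Ginv, Q)


def warning_leverage(p: int, n: int) -> float:
    """Warning leverage h* = 3(p+1)/n for p descriptors, n training compounds."""
    if n <= 0:
        raise ValueError("training size must be positive")
    return 3.0 * (p + 1) / n


def williams_data(
    model: LinearModel,
    dataset: QsarDataset,
    residual_scale: float | None = None,
) -> list[AdResult]:
    """Leverage and standardized residual for every compound.

    Residuals are standardized by the training fit's SEE.  A compound is
    in-domain when its leverage is at most h* and |standardized residual|
    is at most 3.
    """
    if dataset.partition is None:
        raise ValueError("dataset must carry a train/test partition")
    train = dataset.subset("train")
    X_train = train.table.select(list(model.descriptor_names)).values
    n_train, p = X_train.shape
    h_star = warning_leverage(p, n_train)

    if residual_scale is None:
        resid_train = train.y - predict(model, X_train)
        residual_scale = see_stat(resid_train, n_train, p)

    X_all = dataset.table.select(list(model.descriptor_names)).values
    h_all = leverages(X_train, X_all)
    resid_all = dataset.y - predict(model, X_all)
    # an (effectively) exact training fit leaves nothing to standardize by
    std_resid = (
        resid_all / residual_scale
        if residual_scale > 1e-12
        else np.zeros_like(resid_all)
    )
    out = []
    for cid, h, sr, tag in zip(
        dataset.compound_ids, h_all, std_resid, dataset.partition
    ):
        out.append(
            AdResult(
                compound_id=cid,
                leverage=float(h),
                standardized_residual=float(sr),
                in_domain=bool(h <= h_star and abs(sr) <= 3),
                partition=str(tag),
            )
        )
    return out


def y_randomization(
    X: np.ndarray, y: np.ndarray, n_permutations: int = 100, seed: int = 0
) -> tuple[float, float]:
    """Chance-correlation check by refitting on permuted activities.

    Returns ``(mean permuted R², cRp²)`` where
    ``cRp² = R · sqrt(R² − mean R²_r)`` and R² is the unpermuted fit's
    value.  A model whose cRp² falls below 0.5 may owe its fit to chance.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    base = fit_ols(X, y)
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_permutations)
    for i in range(n_permutations):
        r2s[i] = fit_ols(X, rng.permutation(y)).r2
    mean_r2_r = float(r2s.mean())
    gap = base.r2 - mean_r2_r
    crp2 = float(np.sqrt(base.r2) * np.sqrt(gap)) if gap > 0 else 0.0
    return mean_r2_r, crp2


def build_report(
    model: LinearModel,
    dataset: QsarDataset,
    reference_mean_convention: str = "training_only",
    n_permutations: int = 100,
    seed: int = 0,
    d_smoothing: float = 0.5,
) -> ValidationReport:
    """Assemble the full validation battery for a fitted model.

    ``reference_mean_convention`` is ``"training_only"`` (the training-set
    mean activity; default for new work) or ``"all_compounds"`` (the mean
    over every compound; the published worked example's convention).
    """
    if dataset.partition is None:
        raise ValueError("dataset must carry a train/test partition")
    if reference_mean_convention not in ("training_only", "all_compounds"):
        raise ValueError(
            "reference_mean_convention must be 'training_only' or 'all_compounds'"
        )
    train = dataset.subset("train")
    test = dataset.subset("test")
    names = list(model.descriptor_names)
    X_train = train.table.select(names).values
    X_test = test.table.select(names).values
    n, p = X_train.shape

    y_train_pred = predict(model, X_train)
    resid = train.y - y_train_pred
    see_value = see_stat(resid, n, p)
    r2 = r_squared(train.y, y_train_pred, float(train.y.mean()))
    lof_value = lof_stat(see_value, c=p + 1, d=d_smoothing, p=p, M=n)
    q2 = q2_loo(X_train, train.y)

    ref_mean = (
        float(dataset.y.mean())
        if reference_mean_convention == "all_compounds"
        else float(train.y.mean())
    )
    y_test_pred = predict(model, X_test)
    r2p = r2_pred(test.y, y_test_pred, ref_mean)
    r2_test = pearson_r(test.y, y_test_pred) ** 2

    vifs = vif_all(X_train, names)
    mes = mean_effects(model, X_train)
    per_descriptor = pd.DataFrame({"vif": vifs, "mean_effect": mes})
    pearson_matrix = pd.DataFrame(
        np.corrcoef(X_train, rowvar=False), index=names, columns=names
    )

    h_star = warning_leverage(p, n)
    ad = williams_data(model, dataset, residual_scale=see_value)

    mean_r2_r, crp2 = y_randomization(X_train, train.y, n_permutations, seed)

    checklist = {
        "r2": r2 >= CHECKLIST_THRESHOLDS["r2"],
        "q2_loo": q2 >= CHECKLIST_THRESHOLDS["q2_loo"],
        "r2_minus_q2": (r2 - q2) < CHECKLIST_THRESHOLDS["r2_minus_q2"],
        "n_test": test.table.n_compounds >= CHECKLIST_THRESHOLDS["n_test"],
        "crp2": crp2 >= CHECKLIST_THRESHOLDS["crp2"],
    }
    return ValidationReport(
        r2=r2,
        r2_adjusted=adjusted_r2(r2, n, p),
        q2_loo=q2,
        r2_pred=r2p,
        r2_test_pearson=r2_test,
        see=see_value,
        lof=lof_value,
        reference_mean=ref_mean,
        reference_mean_convention=reference_mean_convention,
        per_descriptor=per_descriptor,
        pearson_matrix=pearson_matrix,
        warning_leverage=h_star,
        ad_results=ad,
        checklist=checklist,
        y_randomization=(mean_r2_r, crp2),
    )
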