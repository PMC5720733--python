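"""Partial least squares QSAR models and their validation statistics.

The regression engine is single-response NIPALS PLS: latent factors are
extracted sequentially, each maximizing covariance with the activity, with
rank-one deflation in between.  Up to six factors are used, the customary
over-fitting guard for grid descriptors with far more columns than rows.

A model is judged by

* ``R2``        coefficient of determination on the training set,
* ``RCV2``      leave-one-out cross-validated Q2,
* ``SD``        standard error of the training fit (n - NC - 1 denominator),
* ``stability`` squared Pearson correlation between LOO and full-model
                training predictions,
* ``Rtest2``    squared Pearson correlation between predicted and observed
                test activities (the predictive-residual variant ``q2_ext``
                is reported alongside),
* ``RMSE``      root-mean-square test error,

and a model is *acceptable* when RCV2 > 0.5 and Rtest2 > 0.5.  During
leave-one-out, column elimination and scaling stay frozen from the full
training set by default (``loo_mode="frozen"``); a strict per-fold refit is
available behind ``loo_mode="strict"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .dataset import SplitAssignment
from .errors import DomainError, ParameterError
from .fields import DescriptorMatrix

__all__ = [
    "QSARModel",
    "ValidationReport",
    "pls_fit",
    "pls_predict",
    "loo_predictions",
    "validate_model",
    "field_contributions",
    "select_models",
    "fit_qsar",
]

ACCEPTABILITY_RCV2 = 0.5
ACCEPTABILITY_RTEST2 = 0.5


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential NIPALS factors for a single response.

    Returns weights W (p, k), loadings P (p, k) and y-loadings q (k,); may
    extract fewer than requested factors if the residual rank is exhausted.
    """
    X = Xc.copy()
    y = yc.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = X.T @ t / tt
        q = float(t @ y) / tt
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        return np.zeros((Xc.shape[1], 0)), np.zeros((Xc.shape[1], 0)), np.zeros(0)
    return np.stack(W, axis=1), np.stack(P, axis=1), np.asarray(Q)


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Regression vector b with Xc @ b reproducing the fitted values."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def _nested_coefficients(W, P, q) -> list[np.ndarray]:
    """Coefficient vectors for 1..k factors from one sequential fit."""
    return [
        _coefficients(W[:, : k + 1], P[:, : k + 1], q[: k + 1])
        for k in range(W.shape[1])
    ]


@dataclass
class QSARModel:
    """A fitted PLS model over scaled descriptor columns."""

    field_set: tuple[str, ...]
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, k)
    loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    coef: np.ndarray  # (p,)
    fitted: np.ndarray  # training predictions
    column_fields: np.ndarray | None = None  # field tag per column
    column_sd: np.ndarray | None = None  # pre-scaling training sd per column
    column_scale: np.ndarray | None = None  # scaling divisor per column

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)


def pls_fit(
    X: np.ndarray, y: np.ndarray, n_components: int,
    field_set: Sequence[str] = (),
    column_fields: np.ndarray | None = None,
    column_sd: np.ndarray | None = None,
    column_scale: np.ndarray | None = None,
) -> QSARModel:
    """Fit a NIPALS PLS model with at most ``n_components`` latent factors."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ParameterError("X must be (n, p) with matching y")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if np.ptp(y) < 1e-12:
        raise DomainError("constant response: nothing to regress on")
    usable = min(n_components, X.shape[0] - 1, X.shape[1])
    if usable < n_components:
        warnings.warn(
            f"n_components reduced from {n_components} to {usable} (rank limit)"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, usable)
    if W.shape[1] < usable:
        warnings.warn(
            f"only {W.shape[1]} factors extractable (residual rank exhausted)"
        )
    b = _coefficients(W, P, q)
    fitted = (X - x_mean) @ b + y_mean
    return QSARModel(
        field_set=tuple(field_set),
        n_components=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        loadings=P,
        y_loadings=q,
        coef=b,
        fitted=fitted,
        column_fields=column_fields,
        column_sd=column_sd,
        column_scale=column_scale,
    )


def pls_predict(model: QSARModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != len(model.coef):
        raise ParameterError(
            f"expected {len(model.coef)} columns, got {X_new.shape[1]}"
        )
    return (X_new - model.x_mean) @ model.coef + model.y_mean


def loo_predictions(
    X: np.ndarray, y: np.ndarray, n_components: int
) -> np.ndarray:
    """Leave-one-out predictions for 1..n_components factors.

    Returns an (n, n_components) array; column k holds the LOO prediction of
    each sample from a (k+1)-factor model fitted on the other n-1 rows.  If a
    fold's residual rank is exhausted early its last available prediction is
    carried forward.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    out = np.empty((n, n_components))
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X[keep], y[keep]
        xm, ym = Xi.mean(axis=0), yi.mean()
        W, P, q = _nipals_pls1(Xi - xm, yi - ym, n_components)
        preds = [
            float((X[i] - xm) @ b + ym) for b in _nested_coefficients(W, P, q)
        ]
        if not preds:
            preds = [ym]
        while len(preds) < n_components:
            preds.append(preds[-1])
        out[i] = preds
    return out


def _pearson2(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) < 1e-15 or np.ptp(b) < 1e-15:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class ValidationReport:
    """All headline statistics of one field combination + factor count."""

    field_set: tuple[str, ...]
    n_components: int
    r2: float
    rcv2: float
    sd: float
    stability: float
    rtest2: float
    rmse: float
    q2_ext: float
    mean_signed_error: float
    mean_unsigned_error: float
    fraction_small_residual: float
    contributions: dict[str, float]
    acceptable: bool
    unreliable: bool = False
    alignment: str | None = None
    model: QSARModel | None = dc_field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "alignment": self.alignment,
            "fields": "".join(self.field_set),
            "NC": self.n_components,
            "R2": round(self.r2, 4),
            "RCV2": round(self.rcv2, 4),
            "SD": round(self.sd, 4),
            "stability": round(self.stability, 4),
            "Rtest2": round(self.rtest2, 4),
            "RMSE": round(self.rmse, 4),
            "q2_ext": round(self.q2_ext, 4),
            "mean_signed_error": round(self.mean_signed_error, 4),
            "mean_unsigned_error": round(self.mean_unsigned_error, 4),
            "fraction_residual_lt_0.5": round(self.fraction_small_residual, 4),
            "contributions_pct": {
                k: round(v, 2) for k, v in self.contributions.items()
            },
            "acceptable": self.acceptable,
            "unreliable": self.unreliable,
        }


def field_contributions(model: QSARModel) -> dict[str, float]:
    """Percent contribution of each field: sum |b_j| * sd_j, normalized to 100.

    ``b_j`` is the raw-unit coefficient (the fitted coefficient mapped back
    through the column's scaling divisor) and ``sd_j`` the column's training
    standard deviation, the customary "stdev*coeff" mass.
    """
    if model.column_fields is None or model.column_sd is None:
        raise ParameterError("model lacks column metadata for contributions")
    scale = (
        model.column_scale
        if model.column_scale is not None
        else np.ones_like(model.coef)
    )
    mass = np.abs(model.coef / scale) * model.column_sd
    total = mass.sum()
    fields = list(dict.fromkeys(model.field_set))
    if total < 1e-15:
        warnings.warn("all-zero coefficients: reporting uniform contributions")
        return {f: 100.0 / len(fields) for f in fields}
    return {
        f: float(100.0 * mass[model.column_fields == f].sum() / total)
        for f in fields
    }


def _strict_loo_predictions(
    raw_blocks: dict[str, np.ndarray],
    y: np.ndarray,
    n_components: int,
    sd_threshold: float,
    scaling: str,
) -> np.ndarray:
    """LOO with per-fold column elimination and rescaling (strict protocol)."""
    n = len(y)
    out = np.empty((n, n_components))
    for i in range(n):
        keep = np.arange(n) != i
        fold_blocks, held_blocks = [], []
        for block in raw_blocks.values():
            sd = block[keep].std(axis=0, ddof=1)
            retain = sd >= sd_threshold
            sub = block[keep][:, retain]
            if scaling == "auto":
                div = sd[retain]
            else:
                bsd = float(sub.std(ddof=1)) if sub.size > 1 else 1.0
                div = bsd if bsd > 1e-12 else 1.0
            fold_blocks.append(sub / div)
            held_blocks.append(block[i][retain] / div)
        Xi = np.hstack(fold_blocks)
        xi = np.concatenate(held_blocks)
        xm, ym = Xi.mean(axis=0), y[keep].mean()
        W, P, q = _nipals_pls1(Xi - xm, y[keep] - ym, n_components)
        preds = [float((xi - xm) @ b + ym) for b in _nested_coefficients(W, P, q)]
        if not preds:
            preds = [ym]
        while len(preds) < n_components:
            preds.append(preds[-1])
        out[i] = preds
    return out


def fit_qsar(
    dm: DescriptorMatrix,
    split: SplitAssignment,
    fields: Sequence[str],
    n_components: int,
) -> QSARModel:
    """Fit one field combination on the training rows of a descriptor matrix."""
    sub = dm.subset_fields(fields)
    X_train = sub.rows_for(split.train_ids)
    y_train = _activities_for(sub, split.train_ids)
    return pls_fit(
        X_train,
        y_train,
        n_components,
        field_set=tuple(fields),
        column_fields=sub.column_fields,
        column_sd=sub.train_sd,
        column_scale=sub.column_scale,
    )


def attach_activities(dm: DescriptorMatrix, activities: dict[str, float]) -> None:
    """Associate observed activities with a descriptor matrix's rows."""
    dm.activities = dict(activities)


def _activities_for(dm: DescriptorMatrix, ids: Sequence[str]) -> np.ndarray:
    if dm.activities is None:
        raise ParameterError(
            "descriptor matrix has no activities; call attach_activities first"
        )
    return np.array([dm.activities[cid] for cid in ids], float)


def validate_model(
    dm: DescriptorMatrix,
    split: SplitAssignment,
    fields: Sequence[str],
    n_components: int,
    loo_mode: str = "frozen",
    alignment: str | None = None,
) -> ValidationReport:
    """Compute the full statistics table row for one (fields, NC) choice."""
    reports = _evaluate_combination(
        dm, split, fields, n_components, loo_mode, alignment, fixed_nc=True
    )
    return reports


def _evaluate_combination(
    dm: DescriptorMatrix,
    split: SplitAssignment,
    fields: Sequence[str],
    nc_max: int,
    loo_mode: str,
    alignment: str | None,
    fixed_nc: bool = False,
) -> ValidationReport:
    if loo_mode not in ("frozen", "strict"):
        raise ParameterError("loo_mode must be 'frozen' or 'strict'")
    sub = dm.subset_fields(fields)
    X_train = sub.rows_for(split.train_ids)
    y_train = _activities_for(sub, split.train_ids)
    X_test = sub.rows_for(split.test_ids)
    y_test = _activities_for(sub, split.test_ids)
    n_train = len(y_train)
    nc_cap = max(1, min(nc_max, n_train - 1, max(X_train.shape[1], 1)))

    if loo_mode == "frozen":
        loo = loo_predictions(X_train, y_train, nc_cap)
    else:
        if not sub.raw:
            raise ParameterError("strict LOO needs raw field blocks")
        train_idx = [sub.ids.index(cid) for cid in split.train_ids]
        raw_blocks = {f: sub.raw[f][train_idx] for f in sub.field_set}
        loo = _strict_loo_predictions(
            raw_blocks, y_train, nc_cap, sub.sd_threshold, sub.scaling
        )

    ss_tot = float(((y_train - y_train.mean()) ** 2).sum())
    rcv2_by_nc = 1.0 - ((y_train[:, None] - loo) ** 2).sum(axis=0) / ss_tot
    if fixed_nc:
        nc = min(nc_max, nc_cap)
    else:
        nc = int(np.argmax(rcv2_by_nc)) + 1
    rcv2 = float(rcv2_by_nc[nc - 1])

    model = pls_fit(
        X_train, y_train, nc,
        field_set=tuple(fields),
        column_fields=sub.column_fields,
        column_sd=sub.train_sd,
        column_scale=sub.column_scale,
    )
    fitted = model.fitted
    res_train = y_train - fitted
    r2 = 1.0 - float((res_train**2).sum()) / ss_tot
    dof = max(n_train - model.n_components - 1, 1)
    sd = float(np.sqrt((res_train**2).sum() / dof))
    stability = _pearson2(loo[:, nc - 1], fitted)

    pred_test = pls_predict(model, X_test) if len(y_test) else np.zeros(0)
    if len(y_test):
        rtest2 = _pearson2(pred_test, y_test)
        rmse = float(np.sqrt(np.mean((pred_test - y_test) ** 2)))
        q2_ext = 1.0 - float(((y_test - pred_test) ** 2).sum()) / float(
            ((y_test - y_train.mean()) ** 2).sum()
        )
    else:
        rtest2, rmse, q2_ext = 0.0, float("nan"), float("nan")

    all_res = np.concatenate([res_train, y_test - pred_test])
    return ValidationReport(
        field_set=tuple(fields),
        n_components=model.n_components,
        r2=r2,
        rcv2=rcv2,
        sd=sd,
        stability=stability,
        rtest2=rtest2,
        rmse=rmse,
        q2_ext=q2_ext,
        mean_signed_error=float(all_res.mean()),
        mean_unsigned_error=float(np.abs(all_res).mean()),
        fraction_small_residual=float((np.abs(all_res) < 0.5).mean()),
        contributions=field_contributions(model),
        acceptable=bool(rcv2 > ACCEPTABILITY_RCV2 and rtest2 > ACCEPTABILITY_RTEST2),
        unreliable=len(y_test) < 3,
        alignment=alignment,
        model=model,
    )


def select_models(
    dm: DescriptorMatrix,
    split: SplitAssignment,
    combinations: Sequence[Sequence[str]],
    nc_max: int = 6,
    loo_mode: str = "frozen",
    alignment: str | None = None,
) -> list[ValidationReport]:
    """Evaluate field combinations and rank them.

    For each combination the factor count in 1..nc_max maximizing RCV2 is
    chosen; reports are ranked by (acceptable, RCV2, Rtest2, stability,
    -RMSE) lexicographically, best first.
    """
    if not combinations:
        raise ParameterError("need at least one field combination")
    reports = []
    for combo in combinations:
        if not combo:
            raise ParameterError("empty field combination")
        reports.append(
            _evaluate_combination(dm, split, combo, nc_max, loo_mode, alignment)
        )
    reports.sort(
        key=lambda r: (r.acceptable, r.rcv2, r.rtest2, r.stability, -r.rmse),
        reverse=True,
    )
    return reports
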