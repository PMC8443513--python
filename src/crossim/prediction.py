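"""L1-penalized marker-effect model and prediction values.

The prediction model is the linear regression y_i = mu + sum_j beta_j x_ij +
e_i fitted with the lasso: coefficients minimise

    (1/2n) * sum_i (y_i - mu - sum_j beta_j x_ij)^2 + lambda * sum_j |beta_j|

with the penalty lambda chosen to minimise mean cross-validated squared error
over a standard decreasing lambda path (10-fold by default, fold assignment
randomised from the supplied generator and recorded in the model metadata).
The intercept is unpenalized and predictors enter on their raw {-1, 0, +1}
code scale — codes share a common unit, so no standardization is applied.

The prediction value (PV) of a genotype is mu + sum_j beta_j x_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .errors import (
    DataError,
    DegenerateTrainingWarning,
    ParameterError,
    ParseError,
    StructuralError,
)

__all__ = [
    "TrainingData",
    "PredictionModel",
    "fit_model",
    "predict",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class TrainingData:
    """An (n x m) genotype code matrix with phenotypes and marker ids."""

    X: np.ndarray
    y: np.ndarray
    marker_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "X", np.asarray(self.X, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        if self.X.ndim != 2:
            raise StructuralError("X must be a 2-D code matrix")
        n, m = self.X.shape
        if self.y.shape != (n,):
            raise StructuralError("y must have one phenotype per row of X")
        if len(self.marker_ids) != m:
            raise StructuralError("one marker id per column of X")
        if len(set(self.marker_ids)) != m:
            raise StructuralError("marker ids must be unique")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise DataError("training data contains missing/non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class PredictionModel:
    """Fitted marker-effect model: intercept, one coefficient per training
    marker (zeros retained), the selected penalty and training metadata."""

    intercept: float
    coef: np.ndarray
    marker_ids: tuple
    lambda_: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.marker_ids = tuple(self.marker_ids)
        if self.coef.shape != (len(self.marker_ids),):
            raise StructuralError("one coefficient per marker id")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))


def fit_model(
    data: TrainingData,
    n_folds: int = 10,
    rng: Optional[np.random.Generator] = None,
    n_alphas: int = 100,
    max_iter: int = 50_000,
) -> PredictionModel:
    """Fit the lasso model, selecting lambda by ``n_folds``-fold CV.

    A constant response cannot identify any marker effect; in that degenerate
    case a warning is issued and an intercept-only model (lambda = inf) is
    returned.
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    if data.n < n_folds:
        raise ParameterError("need at least one training sample per CV fold")
    if rng is None:
        rng = np.random.default_rng()
    fold_seed = int(rng.integers(0, 2**31))
    if np.ptp(data.y) == 0.0:
        warnings.warn(
            "constant training response; returning intercept-only model",
            DegenerateTrainingWarning,
            stacklevel=2,
        )
        return PredictionModel(
            intercept=float(data.y[0]) if data.n else 0.0,
            coef=np.zeros(data.m),
            marker_ids=data.marker_ids,
            lambda_=float("inf"),
            meta={"n": data.n, "n_folds": n_folds, "fold_seed": fold_seed,
                  "degenerate": True},
        )
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    est = LassoCV(alphas=n_alphas, cv=cv, max_iter=max_iter)
    with warnings.catch_warnings():
        # coordinate descent can emit convergence chatter on near-degenerate
        # folds late in a selection scheme; the fit itself is still usable
        warnings.simplefilter("ignore")
        est.fit(data.X, data.y)
    return PredictionModel(
        intercept=float(est.intercept_),
        coef=est.coef_.copy(),
        marker_ids=data.marker_ids,
        lambda_=float(est.alpha_),
        meta={"n": data.n, "n_folds": n_folds, "fold_seed": fold_seed},
    )


def predict(
    model: PredictionModel,
    codes: np.ndarray,
    marker_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """PV = mu + codes @ beta for one code vector or an (n, m) matrix.

    If ``marker_ids`` is given, its order must match the model's markers
    exactly (checked by id, not just count).
    """
    codes = np.asarray(codes, dtype=float)
    if marker_ids is not None and tuple(marker_ids) != model.marker_ids:
        raise StructuralError("marker ids do not match the model's markers")
    if codes.shape[-1] != len(model.marker_ids):
        raise StructuralError(
            f"{codes.shape[-1]} code columns for {len(model.marker_ids)} markers"
        )
    return model.intercept + codes @ model.coef


# ---------------------------------------------------------------------------
# model TSV round-trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = ".17g"  # shortest lossless decimal for float64


def write_model(model: PredictionModel, path) -> None:
    """Write `#intercept <v> lambda <v>` then one `marker_id<TAB>coefficient`
    row per marker; lossless for float64 values."""
    with open(path, "w") as fh:
        fh.write(
            f"#intercept\t{model.intercept:{_FLOAT_FMT}}"
            f"\tlambda\t{model.lambda_:{_FLOAT_FMT}}\n"
        )
        for mid, c in zip(model.marker_ids, model.coef):
            fh.write(f"{mid}\t{c:{_FLOAT_FMT}}\n")


def read_model(path) -> PredictionModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty model file (line 1)")
    head = lines[0].split("\t")
    if len(head) != 4 or head[0] != "#intercept" or head[2] != "lambda":
        raise ParseError(f"{path}: malformed header (line 1)")
    try:
        intercept = float(head[1])
        lambda_ = float(head[3])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric header value (line 1)") from exc
    ids, coefs = [], []
    seen = set()
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: expected 2 columns (line {ln})")
        mid, val = parts
        if mid in seen:
            raise ParseError(f"{path}: duplicate marker id {mid!r} (line {ln})")
        seen.add(mid)
        try:
            coefs.append(float(val))
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-numeric coefficient (line {ln})"
            ) from exc
        ids.append(mid)
    return PredictionModel(
        intercept=intercept,
        coef=np.array(coefs, dtype=float),
        marker_ids=tuple(ids),
        lambda_=lambda_,
    )
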