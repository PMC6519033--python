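"""Constant-rate estimation by penalized additive spline regression.

The response is a Box-Cox transform t(rho) of the per-segment recombination
rate; each summary statistic enters through a cubic B-spline (P-spline: cubic
regression splines with a second-difference coefficient penalty), so

    t(rho_i) = f_1(z_i1) + ... + f_q(z_iq) + eps_i.

The transform exponent lambda is chosen by profile maximum likelihood against
the additive fit on the training grid and stored with the model.  A
quantile-regression bias correction (linear on the transformed scale, one
line per quantile) maps the raw transformed prediction to a corrected rate;
the default working quantile is 0.35.

Models serialize to a single self-describing JSON file (knots, coefficients,
lambda, bias table, training metadata) and evaluate identically after a
save/load round trip.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import f as f_dist
from statsmodels.regression.quantile_regression import QuantReg

from .stats import PREDICTORS, SummaryVector

__all__ = [
    "TrainedModel",
    "RateEstimate",
    "boxcox",
    "inverse_boxcox",
    "fit_gam",
    "predict_rho",
    "predict_table",
    "fit_bias_correction",
    "apply_bias_correction",
    "term_f_tests",
]

logger = logging.getLogger(__name__)

_FORMAT = "ldjump-model-v1"
_DEGREE = 3
DEFAULT_QUANTILES = (0.25, 0.35, 0.45, 0.5)


def boxcox(rho, lmbda: float):
    """t(rho) = (rho^lambda - 1)/lambda, or log(rho) at lambda = 0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("Box-Cox transform requires rho > 0")
    if lmbda == 0.0:
        out = np.log(rho)
    else:
        out = (rho**lmbda - 1.0) / lmbda
    return out if out.ndim else float(out)

def inverse_boxcox(t, lmbda: float):
    """Inverse transform; arguments below the domain are clamped to 0."""
    t = np.asarray(t, dtype=float)
    if lmbda == 0.0:
        out = np.exp(t)
    else:
        base = lmbda * t + 1.0
        out = np.where(base > 0.0, np.abs(base) ** (1.0 / lmbda), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RateEstimate:
    """A per-segment rate estimate.

    ``rho_hat_raw`` is the back-transformed regression prediction, ``t_raw``
    the same value on the transformed scale (kept for the bias correction),
    ``rho_hat`` the current working estimate (bias-corrected once
    :func:`apply_bias_correction` has run).
    """

    rho_hat: float
    rho_hat_raw: float
    t_raw: float
    imputed: bool = False


def _knot_vector(x: np.ndarray, name: str, n_interior: int) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError(
            f"predictor {name!r} is constant on the training data "
            "(rank-deficient design)"
        )
    qs = np.quantile(x, np.linspace(0.0, 1.0, n_interior + 2)[1:-1])
    interior = np.unique(qs[(qs > lo) & (qs < hi)])
    return np.concatenate(
        [[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]
    )


def _spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[_DEGREE], knots[-_DEGREE - 1]
    n_out = int(np.sum((x < lo) | (x > hi)))
    if n_out:
        logger.info(
            "%d predictor values outside the training hull; clamped", n_out
        )
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, _DEGREE, extrapolate=False).toarray()


@dataclass
class TrainedModel:
    """Serialized additive model: Box-Cox lambda, spline terms, bias table."""

    lmbda: float
    predictor_names: tuple[str, ...]
    knots: dict[str, np.ndarray]
    coefs: dict[str, np.ndarray]
    intercept: float
    bias_correction: dict[float, tuple[float, float]] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    @property
    def demography_tag(self) -> str:
        return self.training_meta.get("demography_tag", "neutral")

    def design(self, X: np.ndarray) -> np.ndarray:
        """Full design matrix (intercept column + one block per predictor)."""
        blocks = [np.ones((X.shape[0], 1))]
        for j, name in enumerate(self.predictor_names):
            blocks.append(_spline_design(X[:, j], self.knots[name]))
        return np.hstack(blocks)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        """t(rho) prediction for rows of predictor values (ordered)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        beta = np.concatenate(
            [[self.intercept]] + [self.coefs[p] for p in self.predictor_names]
        )
        return self.design(X) @ beta

    # -- persistence ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": _FORMAT,
            "lambda": self.lmbda,
            "predictors": list(self.predictor_names),
            "degree": _DEGREE,
            "splines": {
                p: {
                    "knots": self.knots[p].tolist(),
                    "coef": self.coefs[p].tolist(),
                }
                for p in self.predictor_names
            },
            "intercept": self.intercept,
            "bias_correction": {
                f"{q:g}": list(ab) for q, ab in self.bias_correction.items()
            },
            "training_meta": self.training_meta,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        payload = json.loads(text)
        if payload.get("format") != _FORMAT:
            raise ValueError(f"unrecognized model format {payload.get('format')!r}")
        names = tuple(payload["predictors"])
        return cls(
            lmbda=float(payload["lambda"]),
            predictor_names=names,
            knots={p: np.array(payload["splines"][p]["knots"]) for p in names},
            coefs={p: np.array(payload["splines"][p]["coef"]) for p in names},
            intercept=float(payload["intercept"]),
            bias_correction={
                float(q): (float(a), float(b))
                for q, (a, b) in payload["bias_correction"].items()
            },
            training_meta=payload["training_meta"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text())


def _prepare_training(table: pd.DataFrame, predictor_names):
    cols = list(predictor_names) + ["rho"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"training table lacks columns {missing}")
    sub = table.loc[:, cols].replace([np.inf, -np.inf], np.nan).dropna()
    sub = sub[sub["rho"] > 0]
    return sub[list(predictor_names)].to_numpy(float), sub["rho"].to_numpy(float)


def _penalized_design(X, predictor_names, n_interior, penalty):
    knots = {}
    blocks = [np.ones((X.shape[0], 1))]
    pen_blocks = [np.zeros((1, 1))]
    for j, name in enumerate(predictor_names):
        kv = _knot_vector(X[:, j], name, n_interior)
        knots[name] = kv
        B = _spline_design(X[:, j], kv)
        m = B.shape[1]
        D2 = np.diff(np.eye(m), n=2, axis=0)
        pen_blocks.append(penalty * D2.T @ D2 + 1e-8 * np.eye(m))
        blocks.append(B)
    design = np.hstack(blocks)
    P = np.zeros((design.shape[1], design.shape[1]))
    off = 0
    for pb in pen_blocks:
        m = pb.shape[0]
        P[off : off + m, off : off + m] = pb
        off += m
    return design, P, knots


def _solve(design, P, y):
    A = design.T @ design + P
    return np.linalg.solve(A, design.T @ y)


def fit_gam(
    table: pd.DataFrame,
    lambda_policy: str | float = "profile",
    predictor_names: tuple[str, ...] = PREDICTORS,
    n_interior_knots: int = 8,
    penalty: float = 1.0,
    training_meta: dict | None = None,
) -> TrainedModel:
    """Fit the additive spline model of t(rho) on the summary statistics.

    ``table`` holds one row per training segment with the predictor columns
    and a ``rho`` column; rows with rho <= 0 or undefined statistics are
    dropped.  ``lambda_policy`` is either "profile" (profile maximum
    likelihood over a lambda grid) or a fixed exponent.  The in-sample R^2 on
    the transformed scale is stored in ``training_meta``.
    """
    X, rho = _prepare_training(table, predictor_names)
    if len(rho) < 8 * len(predictor_names):
        raise ValueError(f"too few usable training rows ({len(rho)})")
    design, P, knots = _penalized_design(
        X, predictor_names, n_interior_knots, penalty
    )

    log_jacobian = float(np.sum(np.log(rho)))
    n = len(rho)

    def rss_at(lmbda):
        y = boxcox(rho, lmbda)
        beta = _solve(design, P, y)
        resid = y - design @ beta
        return float(resid @ resid), beta, y

    if lambda_policy == "profile":
        grid = np.linspace(0.0, 1.0, 21)
        best_ll, lmbda = -np.inf, 1.0
        for lam in grid:
            rss, _, _ = rss_at(float(lam))
            ll = -0.5 * n * math.log(rss / n) + (lam - 1.0) * log_jacobian
            if ll > best_ll:
                best_ll, lmbda = ll, float(lam)
    else:
        lmbda = float(lambda_policy)

    rss, beta, y = rss_at(lmbda)
    r2_transformed = 1.0 - rss / float(np.sum((y - y.mean()) ** 2))

    coefs = {}
    off = 1
    for name in predictor_names:
        m = len(knots[name]) - _DEGREE - 1
        coefs[name] = beta[off : off + m]
        off += m
    meta = dict(training_meta or {})
    meta.setdefault("demography_tag", "neutral")
    meta.update(
        n_training_rows=int(n),
        lambda_policy="profile" if lambda_policy == "profile" else "fixed",
        penalty=penalty,
        n_interior_knots=n_interior_knots,
        r2_transformed=float(r2_transformed),
    )
    return TrainedModel(
        lmbda=lmbda,
        predictor_names=tuple(predictor_names),
        knots=knots,
        coefs=coefs,
        intercept=float(beta[0]),
        training_meta=meta,
    )


def term_f_tests(
    table: pd.DataFrame, model: TrainedModel, penalty: float | None = None
) -> dict[str, float]:
    """Approximate term-wise F-test p-values by dropping one predictor.

    Degrees of freedom use the unpenalized basis sizes; with the mild default
    penalty this is a good approximation on training sets of several hundred
    rows.
    """
    names = model.predictor_names
    X, rho = _prepare_training(table, names)
    y = boxcox(rho, model.lmbda)
    pen = model.training_meta.get("penalty", 1.0) if penalty is None else penalty
    nik = model.training_meta.get("n_interior_knots", 8)
    design, P, _ = _penalized_design(X, names, nik, pen)
    beta = _solve(design, P, y)
    rss_full = float(np.sum((y - design @ beta) ** 2))
    p_full = design.shape[1]
    out = {}
    for i, name in enumerate(names):
        reduced = tuple(n_ for n_ in names if n_ != name)
        Xr = np.delete(X, i, axis=1)
        d_r, P_r, _ = _penalized_design(Xr, reduced, nik, pen)
        beta_r = _solve(d_r, P_r, y)
        rss_r = float(np.sum((y - d_r @ beta_r) ** 2))
        df1 = p_full - d_r.shape[1]
        df2 = len(y) - p_full
        F = max(0.0, (rss_r - rss_full) / df1) / (rss_full / df2)
        out[name] = float(f_dist.sf(F, df1, df2))
    return out


def predict_table(
    model: TrainedModel, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Raw predictions for a table of predictor columns.

    Returns ``(t_raw, rho_raw)``: the transformed-scale linear predictor and
    its back-transform floored at 0.
    """
    X = table.loc[:, list(model.predictor_names)].to_numpy(float)
    t = model.linear_predictor(X)
    return t, np.maximum(inverse_boxcox(t, model.lmbda), 0.0)


def predict_rho(model: TrainedModel, sv: SummaryVector) -> RateEstimate:
    """Raw (uncorrected) rate estimate for one segment's summary vector."""
    if sv.imputed:
        raise ValueError(
            "segment flagged for imputation; impute from neighbours instead"
        )
    include_tajd = "tajd" in model.predictor_names
    x = sv.values(include_tajd=include_tajd)
    t = float(model.linear_predictor(x[None, :])[0])
    rho = max(float(inverse_boxcox(t, model.lmbda)), 0.0)
    return RateEstimate(rho_hat=rho, rho_hat_raw=rho, t_raw=t, imputed=False)


def fit_bias_correction(
    model: TrainedModel,
    calibration: pd.DataFrame,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
) -> TrainedModel:
    """Fit linear quantile regressions of t(rho_true) on the raw prediction.

    The calibration rows must be simulated independently of the training
    rows.  Coefficients for each quantile are stored on the model; the model
    is returned (mutated in place) for chaining.
    """
    X, rho = _prepare_training(calibration, model.predictor_names)
    t_hat = model.linear_predictor(X)
    t_true = boxcox(rho, model.lmbda)
    exog = np.column_stack([np.ones_like(t_hat), t_hat])
    for q in quantiles:
        res = QuantReg(t_true, exog).fit(q=q)
        a, b = float(res.params[0]), float(res.params[1])
        if b <= 0:
            logger.warning("bias correction at q=%g has non-positive slope", q)
        model.bias_correction[round(float(q), 6)] = (a, b)
    return model


def apply_bias_correction(
    model: TrainedModel, estimate: RateEstimate, q: float = 0.35
) -> RateEstimate:
    """Correct a raw estimate with the stored quantile-regression line."""
    key = round(float(q), 6)
    if key not in model.bias_correction:
        avail = sorted(model.bias_correction)
        raise ValueError(f"no bias correction for q={q}; available: {avail}")
    a, b = model.bias_correction[key]
    rho = max(float(inverse_boxcox(a + b * estimate.t_raw, model.lmbda)), 0.0)
    return RateEstimate(
        rho_hat=rho,
        rho_hat_raw=estimate.rho_hat_raw,
        t_raw=estimate.t_raw,
        imputed=estimate.imputed,
    )
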