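"""Exponential and product-unit base-function regression.

Two model families, both linear in their parameters after a log transform:

* exponential:   y = alpha * exp(beta * z)          (ln y = ln alpha + beta z)
* product-unit:  y = alpha * x1^b1 * ... * xp^bp    (ln y = ln alpha + sum bj ln xj)

Fitting is least squares on the log-linearized model (optionally weighted),
delegated to statsmodels. Confidence intervals come from the t distribution
on the linearized scale; alpha's interval is back-transformed by
exponentiation. Prediction intervals for the response are computed from the
stored sufficient statistics (coefficients, (X'X)^-1, residual variance,
degrees of freedom), so a deserialized model predicts without refitting.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "VariableTransform",
    "BaseFunctionModel",
    "fit_exponential",
    "fit_product_unit",
    "predict_interval",
    "select_best",
]


@dataclass(frozen=True)
class VariableTransform:
    """Maps named table columns onto the model's regressor(s).

    Each source column is divided by its scale divisor; with
    ``combine="product"`` the scaled sources are multiplied into one composite
    regressor, with ``combine="single"`` the (exactly one) scaled source is
    the regressor.
    """

    sources: tuple[str, ...]
    divisors: tuple[float, ...]
    combine: Literal["single", "product"] = "single"

    def __post_init__(self) -> None:
        if len(self.sources) != len(self.divisors):
            raise ValueError("sources and divisors must have equal length")
        if any(d <= 0 for d in self.divisors):
            raise ValueError("divisors must be > 0")
        if self.combine == "single" and len(self.sources) != 1:
            raise ValueError('combine="single" requires exactly one source')
        if self.combine not in ("single", "product"):
            raise ValueError(f"unknown combine mode {self.combine!r}")

    def apply(self, data: Mapping[str, float] | pd.DataFrame) -> np.ndarray:
        """Evaluate the transform on a mapping or DataFrame of source columns."""
        cols = [np.asarray(data[s], dtype=float) / d for s, d in zip(self.sources, self.divisors)]
        if self.combine == "product":
            return np.prod(np.column_stack([np.atleast_1d(c) for c in cols]), axis=1)
        return np.atleast_1d(cols[0])


@dataclass
class BaseFunctionModel:
    """A fitted exponential or product-unit relationship."""

    form: Literal["exponential", "product_unit"]
    alpha: float
    betas: tuple[float, ...]
    alpha_ci: tuple[float, float]
    beta_cis: tuple[tuple[float, float], ...]
    r_squared: float
    f_stat: float
    n_obs: int
    sigma2: float
    df_resid: int
    xtx_inv: list[list[float]]
    response_name: str | None = None
    response_divisor: float = 1.0
    transform: VariableTransform | None = None
    r_squared_original: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha_ci[0] <= self.alpha <= self.alpha_ci[1]):
            raise ValueError("alpha outside its confidence interval")
        for b, (lo, hi) in zip(self.betas, self.beta_cis):
            if not (lo <= b <= hi):
                raise ValueError("beta outside its confidence interval")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")

    @property
    def n_params(self) -> int:
        return 1 + len(self.betas)

    # -- prediction ------------------------------------------------------
    def _design_row(self, x_new: Sequence[float] | float) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x_new, dtype=float))
        if x.size != len(self.betas):
            raise ValueError(f"expected {len(self.betas)} regressor value(s), got {x.size}")
        if self.form == "exponential":
            return np.concatenate([[1.0], x])
        if np.any(x <= 0):
            raise ValueError("product-unit regressors must be > 0")
        return np.concatenate([[1.0], np.log(x)])

    def predict(self, x_new: Sequence[float] | float) -> float:
        """Point prediction on the (scaled) response scale."""
        row = self._design_row(x_new)
        coef = np.concatenate([[math.log(self.alpha)], self.betas])
        return float(np.exp(row @ coef))

    def predict_interval(
        self, x_new: Sequence[float] | float, level: float = 0.95
    ) -> tuple[float, float, float]:
        """(point, lower, upper): back-transformed prediction interval.

        The interval is for a new observation on the linearized (log) scale,
        exponentiated back; with zero residual variance it degenerates to the
        point prediction.
        """
        if not (0 < level < 1):
            raise ValueError("level must be in (0, 1)")
        row = self._design_row(x_new)
        coef = np.concatenate([[math.log(self.alpha)], self.betas])
        eta = float(row @ coef)
        if self.sigma2 == 0.0 or self.df_resid == 0:
            point = math.exp(eta)
            return point, point, point
        xtx_inv = np.asarray(self.xtx_inv)
        se = math.sqrt(self.sigma2 * (1.0 + float(row @ xtx_inv @ row)))
        tcrit = float(scipy.stats.t.ppf(0.5 + level / 2.0, self.df_resid))
        return math.exp(eta), math.exp(eta - tcrit * se), math.exp(eta + tcrit * se)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.transform is not None:
            d["transform"] = dataclasses.asdict(self.transform)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BaseFunctionModel":
        d = dict(d)
        d["betas"] = tuple(d["betas"])
        d["alpha_ci"] = tuple(d["alpha_ci"])
        d["beta_cis"] = tuple(tuple(ci) for ci in d["beta_cis"])
        if d.get("transform") is not None:
            t = d["transform"]
            d["transform"] = VariableTransform(
                tuple(t["sources"]), tuple(t["divisors"]), t["combine"]
            )
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BaseFunctionModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit_linearized(
    design: np.ndarray,
    logy: np.ndarray,
    y: np.ndarray,
    form: str,
    weights: np.ndarray | None,
    **meta,
) -> BaseFunctionModel:
    n, p1 = design.shape
    p = p1 - 1
    if weights is None:
        res = sm.OLS(logy, design).fit()
    else:
        res = sm.WLS(logy, design, weights=np.asarray(weights, dtype=float)).fit()

    coef = np.asarray(res.params, dtype=float)
    df_resid = int(res.df_resid)
    ssr = float(res.ssr)
    tss = float(np.sum((logy - logy.mean()) ** 2))
    exact = df_resid == 0 or (tss > 0 and ssr / tss < 1e-12) or ssr < 1e-24

    if exact:
        sigma2 = 0.0
        r2 = 1.0
        fstat = math.inf
        ci = np.column_stack([coef, coef])
    else:
        sigma2 = ssr / df_resid
        r2 = float(res.rsquared)
        fstat = float(res.fvalue)
        ci = np.asarray(res.conf_int(alpha=0.05))

    xtx = design.T @ design
    if weights is not None:
        xtx = design.T @ (np.asarray(weights)[:, None] * design)
    xtx_inv = np.linalg.pinv(xtx)

    # diagnostic: goodness of fit on the original (back-transformed) scale
    fitted = np.exp(design @ coef)
    tss_orig = float(np.sum((y - y.mean()) ** 2))
    r2_orig = 1.0 - float(np.sum((y - fitted) ** 2)) / tss_orig if tss_orig > 0 else 1.0

    alpha = math.exp(coef[0])
    return BaseFunctionModel(
        form=form,  # type: ignore[arg-type]
        alpha=alpha,
        betas=tuple(float(b) for b in coef[1:]),
        alpha_ci=(math.exp(ci[0, 0]), math.exp(ci[0, 1])),
        beta_cis=tuple((float(lo), float(hi)) for lo, hi in ci[1:]),
        r_squared=min(r2, 1.0),
        f_stat=fstat,
        n_obs=n,
        sigma2=sigma2,
        df_resid=df_resid,
        xtx_inv=xtx_inv.tolist(),
        r_squared_original=r2_orig,
        **meta,
    )


def _check_response(y: np.ndarray) -> None:
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.any(y <= 0):
        raise ValueError("response values must be > 0 (log-linearized fit)")


def fit_exponential(
    z: Sequence[float],
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    **meta,
) -> BaseFunctionModel:
    """Fit y = alpha * exp(beta*z) by least squares on ln y = ln alpha + beta z.

    ``meta`` passes through BaseFunctionModel bookkeeping fields
    (``response_name``, ``response_divisor``, ``transform``).
    """
    z = np.asarray(z, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if z.shape[0] != y.shape[0]:
        raise ValueError("z and y must have equal length")
    if y.size < 3:
        raise ValueError(f"need at least 3 observations, got {y.size}")
    _check_response(y)
    if np.any(~np.isfinite(z)):
        raise ValueError("regressor contains non-finite values")
    if np.ptp(z) == 0:
        raise ValueError("regressor has zero variance (singular fit)")
    design = np.column_stack([np.ones_like(z), z])
    return _fit_linearized(design, np.log(y), y, "exponential", weights, **meta)


def fit_product_unit(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float],
    weights: Sequence[float] | None = None,
    **meta,
) -> BaseFunctionModel:
    """Fit y = alpha * prod xj^bj by least squares on the log-log scale."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if n != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations for {p} regressor(s), got {n}")
    _check_response(y)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("product-unit regressors must be finite and > 0")
    design = np.column_stack([np.ones(n), np.log(x)])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design (collinear regressors)")
    return _fit_linearized(design, np.log(y), y, "product_unit", weights, **meta)


def predict_interval(
    model: BaseFunctionModel, x_new: Sequence[float] | float, level: float = 0.95
) -> tuple[float, float, float]:
    """Module-level alias of :meth:`BaseFunctionModel.predict_interval`."""
    return model.predict_interval(x_new, level=level)


def select_best(candidates: Sequence[BaseFunctionModel]) -> BaseFunctionModel:
    """Pick the candidate with minimal residual variance on the linearized scale.

    Ties break on fewer parameters, then on declaration order. Candidates must
    share a response (checked via ``response_name`` when set).
    """
    if not candidates:
        raise ValueError("empty candidate list")
    names = {m.response_name for m in candidates if m.response_name is not None}
    if len(names) > 1:
        raise ValueError(f"candidates fit different responses: {sorted(names)}")
    return min(enumerate(candidates), key=lambda kv: (kv[1].sigma2, kv[1].n_params, kv[0]))[1]
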