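"""Quadratic response-surface fitting, optimization and verification.

The surface is the full second-order polynomial in coded units,

    y = b0 + sum_i b_i X_i + sum_i b_ii X_i^2 + sum_{i<j} b_ij X_i X_j,

fit by ordinary least squares on a central composite design.  Optima are
located by a fine grid search over a bounded region (square or disk of
radius alpha) polished by local ascent; multiple responses are combined
through a Derringer-type desirability: each response is linearly scaled to
[0, 1] using its own min/max over the region and the geometric mean is
maximized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .design import DesignTable


@dataclass
class QuadraticModel:
    """Full quadratic polynomial in coded factors.

    Coefficients are ordered: intercept, linear terms, pure quadratic
    terms, then interactions (i<j pairs in lexicographic order).
    """

    factor_names: list[str]
    intercept: float
    linear: np.ndarray
    quadratic: np.ndarray
    interaction: np.ndarray  # b_ij for i<j, lexicographic
    std_errors: np.ndarray | None = None   # same order as coef_vector
    p_values: np.ndarray | None = None
    residual_dof: int | None = None
    residual_variance: float | None = None
    cov_params: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.factor_names)
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        if self.linear.shape != (k,) or self.quadratic.shape != (k,):
            raise ValueError("need one linear and one quadratic coefficient per factor")
        if self.interaction.shape != (k * (k - 1) // 2,):
            raise ValueError("need k(k-1)/2 interaction coefficients")

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def term_names(self) -> list[str]:
        f = self.factor_names
        names = ["intercept"] + list(f)
        names += [f"{x}^2" for x in f]
        names += [f"{f[i]}*{f[j]}" for i in range(self.k) for j in range(i + 1, self.k)]
        return names

    @property
    def coef_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.intercept], self.linear, self.quadratic, self.interaction]
        )

    def design_matrix(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.k:
            raise ValueError(f"points must have {self.k} coordinates")
        cols = [np.ones(len(pts))]
        cols += [pts[:, i] for i in range(self.k)]
        cols += [pts[:, i] ** 2 for i in range(self.k)]
        cols += [
            pts[:, i] * pts[:, j]
            for i in range(self.k)
            for j in range(i + 1, self.k)
        ]
        return np.column_stack(cols)

    def stationary_point(self) -> np.ndarray:
        """Solve grad y = 0: closed-form stationary point in coded units."""
        k = self.k
        H = np.zeros((k, k))
        idx = 0
        for i in range(k):
            H[i, i] = 2.0 * self.quadratic[i]
            for j in range(i + 1, k):
                H[i, j] = H[j, i] = self.interaction[idx]
                idx += 1
        return np.linalg.solve(H, -self.linear)

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"term": self.term_names, "coefficient": self.coef_vector})
        if self.std_errors is not None:
            df["std_error"] = self.std_errors
        if self.p_values is not None:
            df["p_value"] = self.p_values
        return df


@dataclass
class OptimumResult:
    coded_optimum: np.ndarray
    natural_optimum: dict[str, float] | None
    predicted: dict[str, float]
    predicted_sd: dict[str, float]
    region: str
    desirability: float | None = None


@dataclass
class VerificationResult:
    predicted_mean: float
    predicted_sd: float
    experimental_mean: float
    experimental_sd: float
    n_experimental: int
    n_predicted: int
    percent_difference: float
    t_statistic: float
    p_value: float

    @property
    def agrees(self) -> bool:
        return self.p_value > 0.05


def quadratic_from_coefficients(
    factor_names: list[str],
    intercept: float,
    linear,
    quadratic,
    interaction,
) -> QuadraticModel:
    """Construct a model from literal (e.g. published) coefficients."""
    return QuadraticModel(
        factor_names=list(factor_names),
        intercept=float(intercept),
        linear=np.asarray(linear, float),
        quadratic=np.asarray(quadratic, float),
        interaction=np.atleast_1d(np.asarray(interaction, float)),
    )


def fit_quadratic(design: DesignTable, response_name: str) -> QuadraticModel:
    """OLS fit of the full quadratic in coded units with per-term t tests."""
    if response_name not in design.responses:
        raise KeyError(f"design has no response {response_name!r}")
    k = len(design.factor_names)
    template = QuadraticModel(
        factor_names=list(design.factor_names),
        intercept=0.0,
        linear=np.zeros(k),
        quadratic=np.zeros(k),
        interaction=np.zeros(k * (k - 1) // 2),
    )
    X = template.design_matrix(design.coded_matrix)
    y = design.responses[response_name]
    n_params = X.shape[1]
    if design.n_runs <= n_params:
        raise ValueError(
            f"{design.n_runs} runs cannot identify {n_params} quadratic terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < n_params:
        # name the deficient columns for the error message
        _, R = np.linalg.qr(X)
        bad = [
            template.term_names[j]
            for j in range(n_params)
            if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))
        ]
        raise ValueError(f"singular design matrix; deficient terms: {bad}")
    res = sm.OLS(y, X).fit()
    coef = res.params
    n_int = k * (k - 1) // 2
    return QuadraticModel(
        factor_names=list(design.factor_names),
        intercept=float(coef[0]),
        linear=coef[1 : 1 + k],
        quadratic=coef[1 + k : 1 + 2 * k],
        interaction=coef[1 + 2 * k : 1 + 2 * k + n_int],
        std_errors=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        residual_dof=int(res.df_resid),
        residual_variance=float(res.mse_resid) if res.df_resid > 0 else np.nan,
        cov_params=np.asarray(res.cov_params()),
    )


def predict_surface(model: QuadraticModel, points) -> np.ndarray:
    """Evaluate the quadratic at coded ``points`` (n x k or a single point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    vals = model.design_matrix(pts) @ model.coef_vector
    return float(vals[0]) if single else vals


def prediction_sd(model: QuadraticModel, point) -> float:
    """Standard deviation of the predicted mean at ``point`` (needs a fit)."""
    if model.cov_params is None or model.residual_variance is None:
        return float("nan")
    x = model.design_matrix(np.atleast_2d(point))[0]
    return float(np.sqrt(x @ model.cov_params @ x))


def _region_grid(k: int, region: str, radius: float, step: float) -> np.ndarray:
    axes = [np.arange(-radius, radius + step / 2, step) for _ in range(k)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    if region == "disk":
        pts = pts[np.linalg.norm(pts, axis=1) <= radius + 1e-12]
    elif region != "square":
        raise ValueError("region must be 'square' or 'disk'")
    return pts


def _polish(objective, x0: np.ndarray, region: str, radius: float) -> np.ndarray:
    if region == "square":
        res = optimize.minimize(
            lambda x: -objective(x),
            x0,
            method="L-BFGS-B",
            bounds=[(-radius, radius)] * len(x0),
        )
        x = res.x
    else:  # disk: project-gradient via penalty-free trust region on the ball
        cons = optimize.NonlinearConstraint(
            lambda x: float(np.dot(x, x)), 0.0, radius ** 2
        )
        res = optimize.minimize(
            lambda x: -objective(x), x0, method="SLSQP", constraints=[cons]
        )
        x = res.x
        if np.linalg.norm(x) > radius:
            x = x * (radius / np.linalg.norm(x))
    return x


def optimize_response(
    models: QuadraticModel | list[QuadraticModel],
    region: str = "square",
    radius: float = 1.414,
    mode: str = "single",
    step: float = 0.01,
    response_names: list[str] | None = None,
    factor_specs=None,
) -> OptimumResult:
    """Maximize one response, or the joint desirability of several.

    Grid search at coded resolution ``step`` over the region, refined by a
    local ascent from the best grid node.  Ties on the grid are broken
    toward the lower second coordinate (temperature), then the lower first
    coordinate (solvent fraction).
    """
    if isinstance(models, QuadraticModel):
        models = [models]
    if mode == "single" and len(models) != 1:
        raise ValueError("single mode takes exactly one model")
    k = models[0].k
    if response_names is None:
        response_names = [f"response_{i + 1}" for i in range(len(models))]
    grid = _region_grid(k, region, radius, step)
    preds = np.column_stack([predict_surface(m, grid) for m in models])

    desirability = None
    if mode == "single":
        values = preds[:, 0]
        if np.ptp(values) == 0:
            warnings.warn("response is constant over the region; returning origin",
                          stacklevel=2)
            best = np.zeros(k)
        else:
            best = grid[_argmax_tiebreak(values, grid)]
            best = _polish(lambda x: predict_surface(models[0], x), best,
                           region, radius)
        obj = lambda x: predict_surface(models[0], x)  # noqa: E731
    elif mode == "desirability":
        lo, hi = preds.min(axis=0), preds.max(axis=0)
        span = hi - lo
        if np.all(span == 0):
            warnings.warn("all responses constant over the region; returning origin",
                          stacklevel=2)
            best = np.zeros(k)
            desirability = 1.0
        else:
            span = np.where(span == 0, 1.0, span)
            d = np.clip((preds - lo) / span, 0.0, 1.0)
            D = np.exp(np.mean(np.log(np.maximum(d, 1e-300)), axis=1))

            def obj(x):
                p = np.array([predict_surface(m, x) for m in models])
                dd = np.clip((p - lo) / span, 1e-300, 1.0)
                return float(np.exp(np.mean(np.log(dd))))

            best = grid[_argmax_tiebreak(D, grid)]
            best = _polish(obj, best, region, radius)
            desirability = obj(best)
    else:
        raise ValueError("mode must be 'single' or 'desirability'")

    predicted = {
        name: float(predict_surface(m, best))
        for name, m in zip(response_names, models)
    }
    predicted_sd = {
        name: prediction_sd(m, best) for name, m in zip(response_names, models)
    }
    natural = None
    if factor_specs is not None:
        from .design import decode

        natural = decode(dict(zip(models[0].factor_names, best)), factor_specs)
    return OptimumResult(
        coded_optimum=np.asarray(best, float),
        natural_optimum=natural,
        predicted=predicted,
        predicted_sd=predicted_sd,
        region=f"{region}(radius={radius})",
        desirability=desirability,
    )


def _argmax_tiebreak(values: np.ndarray, grid: np.ndarray) -> int:
    """Index of the max; ties go to lower last coordinate, then lower first."""
    vmax = values.max()
    tied = np.flatnonzero(values >= vmax - 1e-12 * max(1.0, abs(vmax)))
    keys = [tuple(grid[i][::-1]) for i in tied]
    return int(tied[min(range(len(tied)), key=lambda j: keys[j])])


def verify_optimum(
    predicted_mean: float,
    predicted_sd: float,
    experimental_mean: float,
    experimental_sd: float,
    n_experimental: int,
    n_predicted: int = 3,
) -> VerificationResult:
    """Welch two-sample t test from summary statistics.

    Compares the model prediction (with its sd, nominal n defaulting to 3)
    against the experimental replicate mean.  Percent difference is
    |pred - exp| / pred x 100.
    """
    if predicted_sd < 0 or experimental_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_experimental < 2:
        raise ValueError("need at least 2 experimental replicates")
    v1 = predicted_sd ** 2 / n_predicted
    v2 = experimental_sd ** 2 / n_experimental
    diff = predicted_mean - experimental_mean
    if v1 + v2 == 0:
        t, p = (0.0, 1.0) if diff == 0 else (np.inf * np.sign(diff), 0.0)
    else:
        t = diff / np.sqrt(v1 + v2)
        dof = (v1 + v2) ** 2 / (
            (v1 ** 2 / (n_predicted - 1) if n_predicted > 1 else 0.0)
            + v2 ** 2 / (n_experimental - 1)
        )
        p = 2 * stats.t.sf(abs(t), dof)
    pct = abs(diff) / abs(predicted_mean) * 100 if predicted_mean != 0 else np.nan
    return VerificationResult(
        predicted_mean=predicted_mean,
        predicted_sd=predicted_sd,
        experimental_mean=experimental_mean,
        experimental_sd=experimental_sd,
        n_experimental=n_experimental,
        n_predicted=n_predicted,
        percent_difference=float(pct),
        t_statistic=float(t),
        p_value=float(p),
    )
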