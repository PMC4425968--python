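"""Regression layer: inverse resistance–compliance models with a group
indicator, simple linear fits, nested-model F-tests and residual-standard-
error model selection.

The headline model is the two-parameter inverse law

    Ca = a / (b + R) + ε,   R = PVR or TPR in Wood units,

fitted by nonlinear least squares over both cohorts at once, with an
indicator for the PAH group giving each group its own parameters. With the
numerator shared (``share_numerator=True``) the fit has parameters
(a, b_NPH, b_PAH); freeing it gives (a_NPH, b_NPH, a_PAH, b_PAH). A small
zoo of alternative curves (a/x + c, a·exp(−b·x) + c) supports selection by
residual standard error, RSE = √(RSS/(n − p)), smaller is better with a
fewer-parameters tie-break. A nested F-test on pooled vs per-group fits
tests whether the resistance–compliance relationship differs between
groups — i.e. whether RC time is constant across health and disease.

Estimators follow sklearn conventions (``fit``/``predict``, ``get_params``,
trailing-underscore fitted attributes); the module-level
``fit_inverse_model`` / ``fit_linear`` helpers wrap them and return frozen
fit-report dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ContractError, ConvergenceError, DomainError

# --------------------------------------------------------------------------
# fit reports


@dataclass(frozen=True)
class NLSFit:
    """A converged nonlinear least-squares fit with Wald inference.

    ``params`` maps parameter names (e.g. ``a``, ``b_g0``, ``b_g1``) to
    estimates; ``se`` and ``pvalues`` carry the asymptotic (Jacobian-based)
    standard errors and two-sided t-test p-values at n − p residual df.
    """

    model: str
    params: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    rss: float
    residual_standard_error: float
    n: int
    n_params: int
    converged: bool
    n_iter: int
    y: np.ndarray = field(repr=False, compare=False)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_params

    def to_report(self) -> dict:
        """Flat JSON-serializable key-value report."""
        d = {
            "model": self.model,
            "rss": self.rss,
            "residual_standard_error": self.residual_standard_error,
            "n": self.n,
            "n_params": self.n_params,
            "df_resid": self.df_resid,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        for k, v in self.params.items():
            d[f"param_{k}"] = v
        for k, v in self.se.items():
            d[f"se_{k}"] = v
        for k, v in self.pvalues.items():
            d[f"pvalue_{k}"] = v
        return d


#: The inverse-law fit report is structurally a generic NLS fit report.
InverseModelFit = NLSFit


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with r² and a two-sided slope t-test."""

    slope: float
    intercept: float
    r_squared: float
    residual_standard_error: float
    n: int
    slope_pvalue: float
    rss: float
    n_params: int = 2
    y: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def to_report(self) -> dict:
        return {
            "model": "linear",
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "residual_standard_error": self.residual_standard_error,
            "n": self.n,
            "slope_pvalue": self.slope_pvalue,
            "rss": self.rss,
        }


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    df_num: int
    df_den: int
    pvalue: float


# --------------------------------------------------------------------------
# grouped nonlinear estimators


def _validate_xy(X, y, groups):
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise DomainError("X must be a single predictor column")
        x = x[:, 0]
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("x and y must have the same length")
    if groups is None:
        g = np.zeros(x.shape, dtype=int)
    else:
        g = np.asarray(groups)
        if g.shape != x.shape:
            raise DomainError("groups must align with x")
        _, g = np.unique(g, return_inverse=True)
    return x, y, g


class _GroupedCurveModel(BaseEstimator, RegressorMixin):
    """Per-group curve parameters (optionally some shared), trust-region
    nonlinear least squares, RSE and Wald inference from the Jacobian."""

    model_name = "curve"

    def __init__(self, max_iter: int = 200, rss_rtol: float = 1e-10,
                 b_margin: float = 1e-3):
        self.max_iter = max_iter
        self.rss_rtol = rss_rtol
        self.b_margin = b_margin

    # -- subclass hooks ---------------------------------------------------
    def _shared_names(self) -> tuple[str, ...]:
        return ()

    def _group_names(self) -> tuple[str, ...]:
        raise NotImplementedError

    def _curve(self, x: np.ndarray, p: dict[str, float]) -> np.ndarray:
        """Evaluate the curve; ``p`` holds shared + this group's params."""
        raise NotImplementedError

    def _starts(self, x, y) -> list[np.ndarray]:
        """Candidate single-group start vectors (shared then group params)."""
        raise NotImplementedError

    def _group_lower(self, x) -> dict[str, float]:
        """Lower bounds for per-group parameters (default unbounded)."""
        return {}

    # -- packing ----------------------------------------------------------
    def _labels(self, n_groups: int) -> list[str]:
        labels = list(self._shared_names())
        for g in range(n_groups):
            suffix = f"_g{g}" if n_groups > 1 else ""
            labels += [f"{name}{suffix}" for name in self._group_names()]
        return labels

    def _unpack(self, theta: np.ndarray, n_groups: int) -> list[dict[str, float]]:
        ns = len(self._shared_names())
        shared = dict(zip(self._shared_names(), theta[:ns]))
        ng = len(self._group_names())
        out = []
        for g in range(n_groups):
            p = dict(shared)
            p.update(zip(self._group_names(), theta[ns + g * ng: ns + (g + 1) * ng]))
            out.append(p)
        return out

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, groups=None):
        x, y, g = _validate_xy(X, y, groups)
        n_groups = int(g.max()) + 1
        ns, ng = len(self._shared_names()), len(self._group_names())
        n_params = ns + n_groups * ng
        for gi in range(n_groups):
            if int((g == gi).sum()) < 3:
                raise DomainError(f"group {gi} has fewer than 3 points")
        if x.size <= n_params:
            raise DomainError(f"n={x.size} too small for {n_params} parameters")

        def residuals(theta):
            per_group = self._unpack(theta, n_groups)
            pred = np.empty_like(y)
            for gi in range(n_groups):
                m = g == gi
                pred[m] = self._curve(x[m], per_group[gi])
            return pred - y

        lo = np.full(n_params, -np.inf)
        group_lower = self._group_lower(x)
        for i, name in enumerate(self._labels(n_groups)):
            base = name.split("_g")[0]
            if base in group_lower:
                lo[i] = group_lower[base]
        hi = np.full(n_params, np.inf)

        best = None
        for start in self._starts(x, y):
            theta0 = np.concatenate([start[:ns]] + [start[ns:]] * n_groups)
            theta0 = np.clip(theta0, lo + 1e-9, hi)
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi),
                ftol=self.rss_rtol, xtol=1e-12, gtol=1e-14,
                max_nfev=self.max_iter * (n_params + 1),
            )
            if best is None or res.cost < best.cost:
                best = res
        if best.status == 0:
            raise ConvergenceError(
                f"{self.model_name}: no convergence within the iteration budget",
                last_params=dict(zip(self._labels(n_groups), best.x)),
            )

        rss = float(2.0 * best.cost)
        df_resid = x.size - n_params
        rse = float(np.sqrt(rss / df_resid))
        labels = self._labels(n_groups)
        se = self._wald_se(best.jac, rse)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, best.x / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

        self.n_groups_ = n_groups
        self._theta_ = best.x
        self.params_ = dict(zip(labels, map(float, best.x)))
        self.fit_result_ = NLSFit(
            model=self.model_name,
            params=self.params_,
            se=dict(zip(labels, map(float, se))),
            pvalues=dict(zip(labels, map(float, pvals))),
            rss=rss,
            residual_standard_error=rse,
            n=int(x.size),
            n_params=n_params,
            converged=True,
            n_iter=int(best.nfev),
            y=y.copy(),
        )
        return self

    @staticmethod
    def _wald_se(jac: np.ndarray, rse: float) -> np.ndarray:
        # sigma^2 (J'J)^-1 via economy SVD, tolerant of near-singular J
        _, s, vt = np.linalg.svd(jac, full_matrices=False)
        s = np.where(s > s.max() * 1e-12, s, np.inf)
        cov = (vt.T / s**2) @ vt * rse**2
        return np.sqrt(np.maximum(np.diag(cov), 0.0))

    def predict(self, X, groups=None):
        x = np.asarray(X, dtype=float).reshape(-1)
        x, _, g = _validate_xy(x, np.zeros_like(x), groups)
        if g.max() >= self.n_groups_:
            raise DomainError("predict saw more groups than fit")
        per_group = self._unpack(self._theta_, self.n_groups_)
        pred = np.empty_like(x)
        for gi in range(self.n_groups_):
            m = g == gi
            if m.any():
                pred[m] = self._curve(x[m], per_group[gi])
        return pred


class InverseComplianceModel(_GroupedCurveModel):
    """Inverse law Ca = a/(b + R), optionally sharing ``a`` across groups.

    ``b`` is kept above −min(R) + ``b_margin`` so the fitted curve stays
    finite and positive over the observed resistance range. Starts combine
    the moment-style guess a₀ = median(y)·(median(x) + 1), b₀ = 1 with a
    coarse grid over b ∈ {0.1, …, 2}, keeping the best start by RSS.
    """

    model_name = "inverse"

    def __init__(self, share_numerator: bool = True, max_iter: int = 200,
                 rss_rtol: float = 1e-10, b_margin: float = 1e-3):
        super().__init__(max_iter=max_iter, rss_rtol=rss_rtol, b_margin=b_margin)
        self.share_numerator = share_numerator

    def _shared_names(self):
        return ("a",) if self.share_numerator else ()

    def _group_names(self):
        return ("b",) if self.share_numerator else ("a", "b")

    def _curve(self, x, p):
        return p["a"] / (p["b"] + x)

    def _group_lower(self, x):
        return {"b": -float(np.min(x)) + self.b_margin}

    def _starts(self, x, y):
        a0 = float(np.median(y) * (np.median(x) + 1.0))
        starts = []
        for b0 in (1.0, 0.1, 0.5, 1.5, 2.0):
            if self.share_numerator:
                starts.append(np.array([a0, b0]))
            else:
                starts.append(np.array([a0, b0]))
        return starts


class ShiftedReciprocalModel(_GroupedCurveModel):
    """Ca = a/R + c per group (no vertical-asymptote shift)."""

    model_name = "shifted_reciprocal"

    def _group_names(self):
        return ("a", "c")

    def _curve(self, x, p):
        return p["a"] / x + p["c"]

    def _starts(self, x, y):
        a0 = float(np.median(y) * np.median(x))
        return [np.array([a0, 0.0]), np.array([a0, float(np.min(y))])]


class ExponentialDecayModel(_GroupedCurveModel):
    """Ca = a·exp(−b·R) + c per group, with decay rate b ≥ 0."""

    model_name = "exp_decay"

    def _group_names(self):
        return ("a", "b", "c")

    def _curve(self, x, p):
        return p["a"] * np.exp(-p["b"] * x) + p["c"]

    def _group_lower(self, x):
        return {"b": 0.0}

    def _starts(self, x, y):
        span = float(np.max(y) - np.min(y)) or 1.0
        scale = float(np.ptp(x)) or 1.0
        return [
            np.array([span, 1.0 / scale, float(np.min(y))]),
            np.array([span, 3.0 / scale, float(np.min(y))]),
            np.array([float(np.max(y)), 0.5, 0.0]),
        ]


def candidate_models(**kwargs) -> list[_GroupedCurveModel]:
    """The model zoo compared during selection, headline inverse form first."""
    return [
        InverseComplianceModel(share_numerator=True, **kwargs),
        InverseComplianceModel(share_numerator=False, **kwargs),
        ShiftedReciprocalModel(**kwargs),
        ExponentialDecayModel(**kwargs),
    ]


# --------------------------------------------------------------------------
# module-level wrappers


def fit_inverse_model(
    x: Sequence[float],
    y: Sequence[float],
    group: Optional[Sequence] = None,
    share_numerator: bool = True,
    **kwargs,
) -> NLSFit:
    """Fit Ca = a_g/(b_g + x) by nonlinear least squares (see
    :class:`InverseComplianceModel`) and return the fit report."""
    est = InverseComplianceModel(share_numerator=share_numerator, **kwargs)
    est.fit(np.asarray(x, dtype=float), y, groups=group)
    return est.fit_result_


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares y = intercept + slope·x.

    r² is the squared Pearson correlation; the slope p-value is the
    two-sided t-test at n − 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("x and y must have the same length")
    if x.size < 3:
        raise DomainError(f"need n >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("x is constant: degenerate design")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        residual_standard_error=float(np.sqrt(res.ssr / res.df_resid)),
        n=int(x.size),
        slope_pvalue=float(res.pvalues[1]),
        rss=float(res.ssr),
        y=y.copy(),
    )


@dataclass(frozen=True)
class GroupedLinearFit:
    """Per-group OLS lines plus the pooled-RSS bookkeeping for F-tests."""

    by_group: dict[str, LinearFit]
    rss: float
    n: int
    n_params: int
    y: np.ndarray = field(repr=False, compare=False)

    @property
    def residual_standard_error(self) -> float:
        return float(np.sqrt(self.rss / (self.n - self.n_params)))


def fit_linear_grouped(x, y, group) -> GroupedLinearFit:
    """Separate slope and intercept per group (full interaction model)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    fits: dict[str, LinearFit] = {}
    # order-preserving unique labels so reports read NPH before PAH
    seen = list(dict.fromkeys(group.tolist()))
    rss = 0.0
    for label in seen:
        m = group == label
        fits[str(label)] = f = fit_linear(x[m], y[m])
        rss += f.rss
    return GroupedLinearFit(
        by_group=fits, rss=rss, n=int(x.size), n_params=2 * len(seen), y=y.copy()
    )


# --------------------------------------------------------------------------
# nested F-test and model selection


def f_test_group_difference(pooled, grouped) -> FTestResult:
    """Extra-sum-of-squares F-test of a pooled fit against a per-group fit.

    F = ((RSS_pooled − RSS_grouped)/Δp) / (RSS_grouped/(n − p_grouped)).
    Both fits must be on the same response vector and the pooled model must
    be nested in (have fewer parameters than) the grouped model.
    """
    for f in (pooled, grouped):
        if not hasattr(f, "rss") or not hasattr(f, "n_params"):
            raise ContractError("fits must expose rss, n, n_params and y")
    if pooled.n != grouped.n:
        raise ContractError("fits are on different sample sizes")
    if pooled.y is not None and grouped.y is not None:
        if not np.array_equal(np.sort(pooled.y), np.sort(grouped.y)):
            raise ContractError("fits are on different response vectors")
    dp = grouped.n_params - pooled.n_params
    if dp <= 0:
        raise ContractError("pooled model is not nested in the grouped model")
    df_den = grouped.n - grouped.n_params
    if df_den <= 0:
        raise ContractError("grouped model leaves no residual degrees of freedom")
    num = max(pooled.rss - grouped.rss, 0.0) / dp
    den = grouped.rss / df_den
    f_stat = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f_stat, dp, df_den)) if np.isfinite(f_stat) else 0.0
    return FTestResult(float(f_stat), dp, df_den, p)


def select_model(fits: Sequence) -> object:
    """Pick the fit with the smallest residual standard error.

    Exact ties go to the model with fewer parameters; a tie on both keeps
    the first-listed candidate. All candidates must be fits of the same
    response (same n and same response vector where available).
    """
    fits = list(fits)
    if not fits:
        raise ContractError("no candidate fits supplied")
    ref = fits[0]
    for f in fits[1:]:
        if f.n != ref.n:
            raise ContractError("candidates were fit on different data (n differs)")
        if getattr(f, "y", None) is not None and getattr(ref, "y", None) is not None:
            if not np.array_equal(f.y, ref.y):
                raise ContractError("candidates were fit on different responses")
    best = fits[0]
    for f in fits[1:]:
        if f.residual_standard_error < best.residual_standard_error or (
            f.residual_standard_error == best.residual_standard_error
            and f.n_params < best.n_params
        ):
            best = f
    return best
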