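"""Zero-truncated negative-binomial regression with log link and offset.

The response is a strictly positive count; the linear predictor combines an
intercept, metric covariates standardized to mean 0 / SD 0.5 (centering and
division by two sample standard deviations, so their coefficients compare
directly with 0/1 indicators), raw binary covariates, products of the
transformed columns as interactions, region dummy intercepts against a
reference region, and a fixed log-exposure offset.

The count law is the mean-dispersion negative binomial (variance
``mu + sigma * mu**2``) conditioned on outcomes >= 1; the dispersion is
estimated on the log scale jointly with the coefficients by maximum
likelihood (BFGS with analytic gradients plus a Newton polish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigError, DegenerateInputError, DomainError, FitError

__all__ = [
    "OFFSET_POPULATION",
    "OFFSET_SP_COUNT",
    "ModelSpec",
    "DesignMatrix",
    "FitSettings",
    "ZTNBFit",
    "two_sd_standardize",
    "build_design",
    "nb_logpmf",
    "nb_pmf",
    "ztnb_logpmf",
    "neg_loglik",
    "fit",
    "predicted_density",
]

OFFSET_POPULATION = "log_inhabitants_per_10k"
OFFSET_SP_COUNT = "log_sp_count"
_OFFSETS = (OFFSET_POPULATION, OFFSET_SP_COUNT)

_ETA_MAX = 500.0  # overflow guard on the linear predictor


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression model.

    ``interactions`` are (metric, binary) pairs; the design column is the
    product of the standardized metric and the raw indicator.
    """

    response: str
    offset: str = OFFSET_POPULATION
    metric: tuple[str, ...] = ()
    binary: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    region_col: str = "region"
    reference_region: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "metric", tuple(self.metric))
        object.__setattr__(self, "binary", tuple(self.binary))
        object.__setattr__(
            self, "interactions", tuple(tuple(pair) for pair in self.interactions)
        )
        if self.offset not in _OFFSETS:
            raise ConfigError(f"offset must be one of {_OFFSETS}")
        terms = set(self.metric) | set(self.binary)
        if self.response in terms:
            raise ConfigError("response may not appear among the covariates")
        for a, b in self.interactions:
            if a not in self.metric or b not in self.binary:
                raise ConfigError(
                    f"interaction ({a}, {b}) needs a metric and a binary parent in the spec"
                )

    @property
    def term_names(self) -> tuple[str, ...]:
        """Selectable terms in entry order (intercept and regions excluded)."""
        return (
            *self.metric,
            *self.binary,
            *(f"{a}:{b}" for a, b in self.interactions),
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Built design: named columns plus the standardization records."""

    X: pd.DataFrame
    scaling: dict[str, tuple[float, float]]  # metric column -> (mean, sd)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def to_numpy(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def two_sd_standardize(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Center and divide by two sample standard deviations.

    Returns the scaled column and the (mean, sd) record needed to map
    coefficients back to the original units.  The scaled column has sample
    SD 0.5, which puts metric coefficients on the scale of a binary flip.
    """
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if not sd > 0:
        raise DegenerateInputError("cannot standardize a constant column")
    return (arr - mean) / (2.0 * sd), (mean, sd)


def _interaction_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}:{pair[1]}"


def default_reference_region(table: pd.DataFrame, spec: ModelSpec) -> str:
    """Region with the lowest mean observed density of the response."""
    if spec.offset == OFFSET_POPULATION:
        density = table[spec.response] / (table["inhabitants"] / 1e4)
    else:
        density = table[spec.response] / table["sp_count"]
    means = density.groupby(table[spec.region_col]).mean()
    return str(means.sort_index().idxmin())


def build_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[DesignMatrix, np.ndarray, np.ndarray]:
    """Assemble the design matrix, response vector and offset vector.

    Raises :class:`ConfigError` on missing columns and a rank-deficiency
    error naming the collinear columns.
    """
    needed = {spec.response, spec.region_col, *spec.metric, *spec.binary}
    if spec.offset == OFFSET_POPULATION:
        needed.add("inhabitants")
    else:
        needed.add("sp_count")
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ConfigError(f"table is missing columns: {missing}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    scaling: dict[str, tuple[float, float]] = {}
    for name in spec.metric:
        scaled, record = two_sd_standardize(table[name])
        cols[name] = scaled
        scaling[name] = record
    for name in spec.binary:
        vals = table[name].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ConfigError(f"binary column {name!r} must be 0/1")
        cols[name] = vals.astype(float)
    for pair in spec.interactions:
        cols[_interaction_name(pair)] = cols[pair[0]] * cols[pair[1]]

    regions = table[spec.region_col].astype(str)
    reference = spec.reference_region or default_reference_region(table, spec)
    labels = sorted(regions.unique())
    if reference not in labels:
        raise ConfigError(f"reference region {reference!r} not present")
    for label in labels:
        if label != reference:
            cols[f"region[{label}]"] = (regions == label).to_numpy().astype(float)

    X = pd.DataFrame(cols, index=table.index)
    _check_rank(X)

    y = table[spec.response].to_numpy(dtype=float)
    if (y < 1).any():
        raise DomainError("zero-truncated response must be >= 1 everywhere")
    if spec.offset == OFFSET_POPULATION:
        offset = np.log(table["inhabitants"].to_numpy(dtype=float) / 1e4)
    else:
        offset = np.log(table["sp_count"].to_numpy(dtype=float))
    return DesignMatrix(X=X, scaling=scaling), y, offset


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = [X.columns[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise ConfigError(f"design matrix is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# probability law
# ---------------------------------------------------------------------------


def _gammaln_ratio(y: np.ndarray, theta: float) -> np.ndarray:
    """log Gamma(y+theta) - log Gamma(theta) for integer y.

    For large theta the two gammaln values cancel catastrophically, so for
    modest count ranges the difference is accumulated directly as
    ``sum_{i<y} log(theta + i)``.
    """
    ymax = int(y.max())
    if ymax > 100_000:
        return special.gammaln(y + theta) - special.gammaln(theta)
    cs = np.concatenate([[0.0], np.cumsum(np.log(theta + np.arange(ymax)))])
    return cs[y.astype(np.int64)]


def nb_logpmf(y, mu, sigma):
    """Log pmf of the mean-dispersion negative binomial (var = mu + sigma*mu^2)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DomainError("y must be a non-negative integer")
    if np.any(mu <= 0) or sigma <= 0:
        raise DomainError("mu and sigma must be positive")
    theta = 1.0 / sigma
    return (
        _gammaln_ratio(np.atleast_1d(y), theta).reshape(y.shape)
        - special.gammaln(y + 1.0)
        - theta * np.log1p(mu / theta)
        + y * (np.log(mu) - np.log(theta + mu))
    )


def nb_pmf(y, mu, sigma):
    """Pmf of the untruncated negative binomial."""
    return np.exp(nb_logpmf(y, mu, sigma))


def _log1m_p0(mu, sigma):
    """log(1 - P(Y=0)) for the untruncated law, stable for small sigma*mu."""
    theta = 1.0 / sigma
    log_p0 = -theta * np.log1p(mu / theta)
    # log(1 - exp(x)) for x < 0
    return np.where(
        log_p0 > -0.693,
        np.log(-np.expm1(log_p0)),
        np.log1p(-np.exp(log_p0)),
    )


def ztnb_logpmf(y, mu, sigma):
    """Log pmf of the negative binomial conditioned on y >= 1."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 1):
        raise DomainError("zero-truncated law requires y >= 1")
    return nb_logpmf(y, mu, sigma) - _log1m_p0(np.asarray(mu, dtype=float), sigma)


# ---------------------------------------------------------------------------
# likelihood and gradient
# ---------------------------------------------------------------------------


def neg_loglik(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, offset: np.ndarray
) -> float:
    """Negative log likelihood; +inf outside the admissible region."""
    beta, log_sigma = params[:-1], params[-1]
    eta = X @ beta + offset
    if not np.all(np.isfinite(eta)) or np.any(np.abs(eta) > _ETA_MAX):
        return np.inf
    if np.abs(log_sigma) > 40:
        return np.inf
    mu = np.exp(eta)
    sigma = np.exp(log_sigma)
    return float(-np.sum(ztnb_logpmf(y, mu, sigma)))


def _neg_loglik_grad(
    params: np.ndarray, X: np.ndarray, y: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Analytic gradient of :func:`neg_loglik` in (beta, log_sigma)."""
    beta, log_sigma = params[:-1], params[-1]
    eta = np.clip(X @ beta + offset, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    sigma = np.exp(log_sigma)
    theta = 1.0 / sigma

    log_p0 = -theta * np.log1p(mu / theta)
    p0 = np.exp(log_p0)
    one_m_p0 = -np.expm1(log_p0)

    # d loglik / d mu : untruncated part plus the truncation correction
    dl_dmu = y / mu - (y + theta) / (theta + mu) - p0 * theta / (one_m_p0 * (theta + mu))
    grad_beta = -(X.T @ (dl_dmu * mu))

    # d loglik / d theta
    dl_dtheta = (
        special.digamma(y + theta)
        - special.digamma(theta)
        + np.log(theta)
        + 1.0
        - np.log(theta + mu)
        - (y + theta) / (theta + mu)
    )
    dlogp0_dtheta = np.log(theta / (theta + mu)) + mu / (theta + mu)
    dl_dtheta = dl_dtheta + p0 * dlogp0_dtheta / one_m_p0
    # chain rule: d/d log_sigma = -theta * d/d theta
    grad_ls = float(np.sum(dl_dtheta) * theta)
    return np.append(grad_beta, grad_ls)


def _fd_hessian(fun_grad, x: np.ndarray, step: float = 1e-6) -> np.ndarray:
    """Symmetrized central-difference Jacobian of the analytic gradient."""
    k = len(x)
    H = np.empty((k, k))
    for j in range(k):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        H[:, j] = (fun_grad(xp) - fun_grad(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitSettings:
    """Optimizer controls; all defaults documented and deterministic."""

    gtol: float = 1e-6
    max_restarts: int = 3
    restart_jitter_sd: float = 0.1
    restart_seed: int = 20150088
    maxiter: int = 1000
    newton_maxiter: int = 50


@dataclass(frozen=True)
class ZTNBFit:
    """Maximum-likelihood fit of the zero-truncated NB regression."""

    spec: ModelSpec | None
    columns: tuple[str, ...]
    coefficients: np.ndarray  # per design column
    log_sigma: float
    cov: np.ndarray  # (k+1) x (k+1), includes log_sigma
    loglik: float
    n: int
    convergence: dict
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Number of estimated parameters (coefficients plus log dispersion)."""
        return len(self.coefficients) + 1

    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def zvalues(self) -> np.ndarray:
        return np.append(self.coefficients, self.log_sigma) / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.columns.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.columns.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.columns.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        names = [*self.columns, "log_sigma"]
        est = np.append(self.coefficients, self.log_sigma)
        return pd.DataFrame(
            {"estimate": est, "se": self.se, "z": self.zvalues, "p": self.pvalues},
            index=pd.Index(names, name="term"),
        )

    def to_dict(self) -> dict:
        """JSON-ready representation with stable key order."""
        return {
            "columns": list(self.columns),
            "coefficients": [float(c) for c in self.coefficients],
            "log_sigma": float(self.log_sigma),
            "se": [float(s) for s in self.se],
            "z": [float(z) for z in self.zvalues],
            "p": [float(p) for p in self.pvalues],
            "loglik": float(self.loglik),
            "n": int(self.n),
            "k": int(self.k),
            "bic": float(self.bic),
            "convergence": {key: self.convergence[key] for key in sorted(self.convergence)},
            "scaling": {name: list(rec) for name, rec in sorted(self.scaling.items())},
        }


def _start_values(X: np.ndarray, y: np.ndarray, offset: np.ndarray) -> np.ndarray:
    k = X.shape[1]
    x0 = np.zeros(k + 1)
    x0[0] = np.log(y.sum() / np.exp(offset).sum())  # offset-adjusted mean rate
    x0[-1] = 0.0
    return x0


def fit(
    design: DesignMatrix,
    response: np.ndarray,
    offset: np.ndarray,
    settings: FitSettings = FitSettings(),
    spec: ModelSpec | None = None,
) -> ZTNBFit:
    """Maximize the zero-truncated NB likelihood.

    BFGS with analytic gradients, followed by damped Newton steps on a
    finite-difference Hessian until the gradient max-norm drops below
    ``settings.gtol``; up to ``max_restarts`` jittered restarts (seeded, so
    refits are bit-reproducible).  The covariance matrix is the inverse of
    the final Hessian.
    """
    X = design.to_numpy()
    y = np.asarray(response, dtype=float)
    off = np.asarray(offset, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise DegenerateInputError(f"need n > k+1 (n={n}, k+1={k + 1})")
    if (y < 1).any():
        raise DomainError("responses must be >= 1")

    args = (X, y, off)
    x0 = _start_values(X, y, off)
    rng = np.random.default_rng(settings.restart_seed)
    best = None
    attempts = []
    for attempt in range(settings.max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0, settings.restart_jitter_sd, len(x0))
        res = optimize.minimize(
            neg_loglik,
            start,
            args=args,
            jac=_neg_loglik_grad,
            method="BFGS",
            options={"gtol": settings.gtol * 1e-2, "maxiter": settings.maxiter},
        )
        x, nll = res.x, res.fun
        # Newton polish toward gradient max-norm <= gtol; near the optimum
        # NLL differences fall below float resolution, so steps are accepted
        # on gradient-norm decrease as well.
        for _ in range(settings.newton_maxiter):
            g = _neg_loglik_grad(x, *args)
            gmax = np.max(np.abs(g))
            if gmax <= settings.gtol:
                break
            H = _fd_hessian(lambda p: _neg_loglik_grad(p, *args), x)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            scale, accepted = 1.0, False
            for _ in range(30):
                candidate = x - scale * step
                nll_c = neg_loglik(candidate, *args)
                g_c = np.max(np.abs(_neg_loglik_grad(candidate, *args)))
                if nll_c < nll - 1e-9 or (np.isfinite(nll_c) and g_c < gmax):
                    x, nll, accepted = candidate, nll_c, True
                    break
                scale *= 0.5
            if not accepted:
                break
        g = _neg_loglik_grad(x, *args)
        gnorm = float(np.max(np.abs(g)))
        attempts.append({"restart": attempt, "nll": float(nll), "grad_max": gnorm})
        if best is None or nll < best[1]:
            best = (x, nll, gnorm, attempt)
        if gnorm <= settings.gtol:
            best = (x, nll, gnorm, attempt)
            break
    x, nll, gnorm, used = best
    converged = gnorm <= settings.gtol
    convergence = {
        "converged": bool(converged),
        "grad_max": gnorm,
        "restarts_used": used,
        "attempts": attempts,
    }
    if not converged:
        raise FitError(
            f"fit did not reach gradient tolerance (max|g|={gnorm:.3g})",
            diagnostics={"x": x.tolist(), "nll": float(nll), **convergence},
        )

    H = _fd_hessian(lambda p: _neg_loglik_grad(p, *args), x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        raise FitError("Hessian is singular at the optimum",
                       diagnostics={"x": x.tolist()}) from err
    cov = 0.5 * (cov + cov.T)
    return ZTNBFit(
        spec=spec,
        columns=tuple(design.columns),
        coefficients=x[:-1],
        log_sigma=float(x[-1]),
        cov=cov,
        loglik=-float(nll),
        n=n,
        convergence=convergence,
        scaling=dict(design.scaling),
    )


def fit_table(
    table: pd.DataFrame, spec: ModelSpec, settings: FitSettings = FitSettings()
) -> ZTNBFit:
    """Convenience wrapper: build the design from a table and fit."""
    design, y, offset = build_design(table, spec)
    return fit(design, y, offset, settings=settings, spec=spec)


def predicted_density(fit_result: ZTNBFit, row: dict | None = None, *, truncated: bool = False) -> float:
    """Expected density per 10 000 inhabitants at a design point.

    ``row`` maps design-column names to values; unnamed columns are 0 and
    the intercept is always 1, so the default is the baseline district
    (reference region, metric terms at their mean, binaries 0).  By default
    this is the untruncated mean ``exp(eta)``; set ``truncated=True`` for
    the mean of the zero-truncated law.
    """
    eta = fit_result.coef("intercept")
    if row:
        for name, value in row.items():
            if name == "intercept":
                continue
            eta += fit_result.coef(name) * value
    mu = float(np.exp(eta))
    if truncated:
        p0 = float(np.exp(-np.log1p(mu * fit_result.sigma) / fit_result.sigma))
        return mu / (1.0 - p0)
    return mu
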