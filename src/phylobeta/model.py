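"""The phylogenetic beta-regression model: design, likelihood, priors.

Proportional range decline ``y_i`` in (0, 1) is modelled as
``y_i ~ Beta(mu_i * gamma, (1 - mu_i) * gamma)`` — the mean--dispersion
parameterisation, in which ``mu_i`` is the mean and ``gamma`` controls the
concentration (small gamma = high dispersion). The mean follows a logit-linear
predictor ``logit(mu_i) = x_i' theta + u_i`` with a per-taxon species effect
``u``. The species effects carry the phylogeny: their prior is multivariate
normal with zero mean and covariance equal to the lambda-transformed
phylogenetic VCV, ``u ~ MVN(0, C_lambda)``.

Priors: theta_j ~ Normal(0, 1000) (diffuse), lambda ~ Uniform(0, 1.2), and
gamma ~ Gamma(shape 0.001, rate 0.001) by default. The gamma prior's second
parameter can alternatively be read as a scale via
``gamma_prior_parameterization="scale"``; the default follows the shape--rate
convention of the sampler software family this model class comes from.

Two model forms are supported: ``main_effects`` (7 columns: intercept,
region indicator NS, four standardised logs, habitat rank) and
``interactions`` (those 7 plus the 5 region-by-predictor products).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit, gammaln

from .phylo import PhyloCovariance, _apply_lambda
from .traits import PreparedData

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "ParameterVector",
    "build_design",
    "beta_logpdf",
    "log_prior",
    "log_likelihood",
    "log_posterior",
]

MAIN_EFFECT_COLUMNS = (
    "Intercept", "NS", "log Range", "log Female mass", "log Rainfall",
    "Habitat openness", "log Litter",
)
INTERACTION_COLUMNS = MAIN_EFFECT_COLUMNS + (
    "NS:log Range", "NS:log Female mass", "NS:log Rainfall",
    "NS:Habitat openness", "NS:log Litter",
)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ModelSpec:
    """Model form plus prior hyperparameters; serialisable for reproducibility."""

    form: str = "main_effects"  # or "interactions"
    prior_coef_sd: float = 1000.0
    lambda_lower: float = 0.0
    lambda_upper: float = 1.2
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001  # read as a *scale* under the "scale" switch
    gamma_prior_parameterization: str = "rate"  # "rate" | "scale"
    squeeze_rule: str = "smithson-verkuilen"

    def __post_init__(self) -> None:
        if self.form not in ("main_effects", "interactions"):
            raise ValueError(f"unknown model form {self.form!r}")
        if min(self.prior_coef_sd, self.gamma_shape, self.gamma_rate) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")
        if self.gamma_prior_parameterization not in ("rate", "scale"):
            raise ValueError("gamma_prior_parameterization must be 'rate' or 'scale'")
        if not (0 <= self.lambda_lower < self.lambda_upper):
            raise ValueError("lambda bounds must satisfy 0 <= lower < upper")

    @property
    def gamma_rate_effective(self) -> float:
        """Rate parameter of the gamma prior under either parameterisation."""
        if self.gamma_prior_parameterization == "rate":
            return self.gamma_rate
        return 1.0 / self.gamma_rate

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class DesignMatrix:
    """Fixed-effects design with column names matching the report tables."""

    X: np.ndarray
    names: list[str]
    form: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("design shape does not match column names")

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ParameterVector:
    """One point in parameter space: coefficients, species effects, gamma, lambda."""

    theta: np.ndarray
    u: np.ndarray
    gamma: float
    lam: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.theta, self.u, [self.gamma, self.lam]])

    @classmethod
    def unpack(cls, vec: np.ndarray, p: int, n: int) -> "ParameterVector":
        vec = np.asarray(vec, dtype=float)
        if vec.size != p + n + 2:
            raise ValueError("flat vector has wrong length")
        return cls(theta=vec[:p], u=vec[p:p + n],
                   gamma=float(vec[p + n]), lam=float(vec[p + n + 1]))

    @staticmethod
    def names(design_names: Sequence[str], taxa: Sequence[str]) -> list[str]:
        return list(design_names) + [f"u[{t}]" for t in taxa] + ["gamma", "lambda"]


def build_design(data: PreparedData, spec: ModelSpec) -> DesignMatrix:
    """Assemble the design matrix for the requested model form.

    Interaction columns are elementwise products of the NS indicator with
    each other main column. A column of zeros (e.g. an all-south table under
    the interactions form) is rejected — the corresponding coefficient would
    be unidentifiable.
    """
    P = data.predictors
    n = len(P)
    cols = [np.ones(n)] + [P[c].to_numpy(dtype=float) for c in P.columns]
    names = list(MAIN_EFFECT_COLUMNS)
    if spec.form == "interactions":
        ns = P["NS"].to_numpy(dtype=float)
        for c in ("log Range", "log Female mass", "log Rainfall",
                  "Habitat openness", "log Litter"):
            cols.append(ns * P[c].to_numpy(dtype=float))
            names.append(f"NS:{c}")
    X = np.column_stack(cols)
    zero = [names[j] for j in range(X.shape[1]) if np.all(X[:, j] == 0)]
    if zero:
        raise ValueError(f"design contains all-zero columns: {zero}")
    return DesignMatrix(X=X, names=names, form=spec.form)


def beta_logpdf(y, mu, gamma):
    """Log density of Beta(mu*gamma, (1-mu)*gamma) at y.

    Vectorised over any broadcastable combination. Values of ``y`` outside
    the open interval (0, 1) yield ``-inf`` (not an exception) so a sampler
    can reject such states; ``mu`` must lie in (0, 1) and ``gamma`` must be
    positive.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)) or np.any(gamma <= 0):
        raise ValueError("require 0 < mu < 1 and gamma > 0")
    a = mu * gamma
    b = (1.0 - mu) * gamma
    inside = (y > 0) & (y < 1)
    ysafe = np.where(inside, y, 0.5)
    lp = (gammaln(gamma) - gammaln(a) - gammaln(b)
          + (a - 1.0) * np.log(ysafe) + (b - 1.0) * np.log1p(-ysafe))
    out = np.where(inside, lp, -np.inf)
    if out.ndim == 0:
        return float(out)
    return out


def _mvn_logpdf_zero_mean(u: np.ndarray, cov: np.ndarray) -> float:
    """MVN(0, cov) log density via Cholesky; -inf if cov is not PD."""
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -math.inf
    w = solve_triangular(L, u, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    n = u.size
    return -0.5 * (n * _LOG_2PI + logdet + float(w @ w))


def log_prior(params: ParameterVector, spec: ModelSpec,
              cov: PhyloCovariance) -> float:
    """Joint log prior of (theta, u, gamma, lambda).

    Sum of independent Normal(0, prior_coef_sd) terms over the coefficients,
    the Uniform(lambda_lower, lambda_upper) density for lambda, the gamma
    prior for the dispersion, and MVN(0, C_lambda) over the species effects
    with the lambda transform recomputed at the current lambda. Out-of-support
    values and a non-positive-definite C_lambda return ``-inf``.
    """
    if cov.C.shape[0] != params.u.size:
        raise ValueError("covariance dimension does not match species effects")
    if not (spec.lambda_lower <= params.lam <= spec.lambda_upper):
        return -math.inf
    if params.gamma <= 0:
        return -math.inf
    sd = spec.prior_coef_sd
    lp = float(np.sum(-0.5 * _LOG_2PI - math.log(sd)
                      - 0.5 * (params.theta / sd) ** 2))
    lp += -math.log(spec.lambda_upper - spec.lambda_lower)
    shape, rate = spec.gamma_shape, spec.gamma_rate_effective
    lp += (shape * math.log(rate) - math.lgamma(shape)
           + (shape - 1.0) * math.log(params.gamma) - rate * params.gamma)
    C_lam = _apply_lambda(cov.C, params.lam)
    lp += _mvn_logpdf_zero_mean(params.u, C_lam)
    return lp


def log_likelihood(params: ParameterVector, X: DesignMatrix,
                   y: np.ndarray) -> float:
    """Beta log likelihood at the logit-linear mean."""
    eta = X.X @ params.theta + params.u
    mu = expit(eta)
    if np.any((mu <= 0) | (mu >= 1)):
        return -math.inf
    ll = beta_logpdf(y, mu, params.gamma)
    return float(np.sum(ll))


def log_posterior(params: ParameterVector, X: DesignMatrix, y: np.ndarray,
                  cov: PhyloCovariance, spec: ModelSpec) -> float:
    """Joint log posterior (up to the normalising constant)."""
    y = np.asarray(y, dtype=float)
    if X.X.shape[0] != y.size or params.u.size != y.size:
        raise ValueError("design, response, and species effects disagree in size")
    if X.p != params.theta.size:
        raise ValueError("coefficient vector does not match design columns")
    lp = log_prior(params, spec, cov)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(params, X, y)
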