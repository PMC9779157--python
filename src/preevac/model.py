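"""Discrete-time probit escape-decision model: hazard, likelihood, calibration.

The model treats the pre-evacuation phase as a sequence of decision periods.
In period *t* pedestrian *i* escapes when the difference between subjective
and objective risk utility exceeds a personal escape-selection threshold;
with Gaussian noise on that margin the per-period escape probability is the
probit hazard

    p_it = C + (1 - C) * Phi(eta_it / sigma)

where ``eta_it`` is a linear index in the coded pedestrian attributes (age,
gender, education, familiarity time, group size, residence distance, travel
mode) and the standardized context factors (RCS, DFD, RNC), ``Phi`` is the
standard normal CDF, and ``C`` is the natural-response rate — the baseline
fraction who respond regardless of the modelled stimulus, estimated from a
control group.  Period decisions are conditionally independent, so the first
escape follows the discrete-time survival chain

    P(T = t) = p_t * prod_{s < t} (1 - p_s),

with the never-escaping remainder as censor mass.  Calibration maximises the
resulting likelihood (censored pedestrians contribute their survival product
by default) by Newton iteration with analytic gradient and Hessian; standard
errors come from the inverse observed information.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .risk import RiskContext

__all__ = [
    "CoefficientSet",
    "RiskUtility",
    "DecisionRecord",
    "NaturalResponseEstimate",
    "FitResult",
    "DiscreteTimeProbitHazard",
    "NonIdentifiableError",
    "default_coefficients",
    "period_intercept",
    "linear_predictor",
    "hazard",
    "hazard_probability",
    "stage_probabilities",
    "first_passage",
    "FirstPassage",
    "expand_panels",
    "validate_records",
    "log_likelihood",
    "fit_mle",
    "natural_response_estimate",
]

logger = logging.getLogger(__name__)

ATTR_FIELDS = ("age", "gen", "edu", "time", "group", "zone", "mode")
CONTEXT_FIELDS = ("rcs", "dfd", "rnc")

_SCHEMA_VERSION = 1
_PCLIP = 1e-12


class NonIdentifiableError(RuntimeError):
    """Raised when the design matrix is rank-deficient (e.g. a constant covariate)."""


# ---------------------------------------------------------------------------
# Coefficients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoefficientSet:
    """Complete parameter set of the escape-decision model.

    Parameters
    ----------
    const
        Single intercept used when the model is run without per-period
        intercepts (the plain-probit special case and the simulator).
    thresholds
        Ascending per-period intercepts (one per decision period); they also
        serve as the cut points of the cumulative stage model in
        :func:`stage_probabilities`.
    attr_coeffs
        Named coefficients for the coded pedestrian attributes; a field
        absent from the mapping is excluded from the model (the calibrated
        default excludes education, which was not significant).
    context_coeffs
        Coefficients for the standardized context factors ``rcs``/``dfd``/
        ``rnc`` on their [0, 1] scales.
    sigma
        Noise scale of the threshold disturbance.  A probit only identifies
        coefficients up to this scale, so the calibrated set fixes it at 1.
    natural_rate
        Natural-response rate ``C`` in [0, 1).
    """

    const: float = 0.0
    thresholds: tuple[float, ...] = ()
    attr_coeffs: Mapping[str, float] = field(default_factory=dict)
    context_coeffs: Mapping[str, float] = field(default_factory=dict)
    sigma: float = 1.0
    natural_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma!r}")
        if not 0.0 <= self.natural_rate < 1.0:
            raise ValueError(f"natural_rate must lie in [0, 1), got {self.natural_rate!r}")
        th = tuple(float(t) for t in self.thresholds)
        if any(a > b for a, b in zip(th, th[1:])):
            raise ValueError(f"thresholds must be sorted ascending, got {th}")
        object.__setattr__(self, "thresholds", th)
        bad = set(self.attr_coeffs) - set(ATTR_FIELDS)
        if bad:
            raise ValueError(f"unknown attribute coefficients {sorted(bad)}")
        bad = set(self.context_coeffs) - set(CONTEXT_FIELDS)
        if bad:
            raise ValueError(f"unknown context coefficients {sorted(bad)}")

    # -- serialisation ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "const": self.const,
            "thresholds": list(self.thresholds),
            "attr_coeffs": dict(self.attr_coeffs),
            "context_coeffs": dict(self.context_coeffs),
            "sigma": self.sigma,
            "natural_rate": self.natural_rate,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CoefficientSet":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text, "r", encoding="utf-8") as fh:
                    payload = json.load(fh)
        version = payload.pop("schema_version", None)
        if version != _SCHEMA_VERSION:
            raise ValueError(f"unsupported coefficient schema version {version!r}")
        payload["thresholds"] = tuple(payload.get("thresholds", ()))
        return cls(**payload)


def default_coefficients() -> CoefficientSet:
    """The calibrated coefficient set shipped with the package.

    Attribute coefficients and the two period intercepts come from the
    questionnaire calibration of the model (education excluded as not
    significant); the context coefficients are documented defaults of 1.0 on
    the standardized [0, 1] scales, and the natural-response rate is the
    control-group estimate 0.1981.
    """
    return CoefficientSet(
        const=-3.212,
        thresholds=(-3.212, -3.185),
        attr_coeffs={
            "gen": 0.011,
            "age": -0.015,
            "zone": -0.013,
            "group": 0.013,
            "time": 0.004,
            "mode": 0.002,
        },
        context_coeffs={"rcs": 1.0, "dfd": 1.0, "rnc": 1.0},
        sigma=1.0,
        natural_rate=0.1981,
    )


def period_intercept(coeffs: CoefficientSet, t: int) -> float:
    """Intercept of decision period ``t`` (1-based).

    Periods beyond the last listed intercept reuse the final one; with no
    per-period intercepts the single constant applies.
    """
    if t < 1:
        raise ValueError(f"period must be >= 1, got {t}")
    if not coeffs.thresholds:
        return coeffs.const
    return coeffs.thresholds[min(t, len(coeffs.thresholds)) - 1]


# ---------------------------------------------------------------------------
# Risk-utility bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskUtility:
    """Subjective/objective risk utilities and the escape-selection threshold.

    Only the difference ``RE = subjective - objective`` and the threshold
    ``ECT`` enter the decision rule; the utilities themselves are not
    separately identifiable from choice data and are carried for
    interpretation only.
    """

    subjective: float
    objective: float
    threshold: float

    @property
    def difference(self) -> float:
        """RE: subjective minus objective risk utility."""
        return self.subjective - self.objective

    @property
    def margin(self) -> float:
        """Decision margin R = RE - ECT; escape when non-negative."""
        return self.difference - self.threshold

    @property
    def evacuation_coefficient(self) -> float:
        """lambda = ECT / subjective utility (NaN when subjective is zero)."""
        if self.subjective == 0:
            return math.nan
        return self.threshold / self.subjective

    @property
    def decision(self) -> int:
        """Deterministic decision: 1 = escape immediately, 0 = wait and see."""
        return int(self.margin >= 0)


@dataclass(frozen=True)
class DecisionRecord:
    """One respondent's observed outcome: first escape period or censoring."""

    pedestrian: int
    period: int
    response: int
    is_control: bool = False
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError(f"period must be >= 1, got {self.period}")
        if self.response not in (0, 1):
            raise ValueError(f"response must be 0 or 1, got {self.response!r}")


# ---------------------------------------------------------------------------
# Core probability machinery
# ---------------------------------------------------------------------------

def linear_predictor(ped, ctx, coeffs: CoefficientSet, period: int | None = None) -> float:
    """Deterministic part of the escape margin for one pedestrian-period.

    ``const + sum_k c_k * attr_k + c_rcs * rcs + c_dfd * dfd + c_rnc * rnc``;
    attributes without a coefficient (e.g. an excluded covariate) do not
    enter.  With ``period`` given and per-period intercepts configured, the
    period's intercept replaces the constant.
    """
    covs = ped.coded() if hasattr(ped, "coded") else dict(ped)
    total = coeffs.const if period is None else period_intercept(coeffs, period)
    for name, c in coeffs.attr_coeffs.items():
        if name not in covs:
            raise ValueError(f"covariate {name!r} required by the coefficient set is missing")
        total += c * float(covs[name])
    ctx_map = ctx.as_dict() if isinstance(ctx, RiskContext) else dict(ctx)
    for name, c in coeffs.context_coeffs.items():
        if name not in ctx_map:
            raise ValueError(f"context factor {name!r} required by the coefficient set is missing")
        total += c * float(ctx_map[name])
    return float(total)


def hazard_probability(lp, coeffs: CoefficientSet, include_natural: bool = True):
    """Vectorised per-period escape probability ``C + (1-C) * Phi(lp / sigma)``."""
    C = coeffs.natural_rate if include_natural else 0.0
    return C + (1.0 - C) * ndtr(np.asarray(lp, dtype=float) / coeffs.sigma)


def hazard(lp: float, coeffs: CoefficientSet, include_natural: bool = True) -> float:
    """Per-period escape probability for a scalar linear predictor.

    Reduces to ``Phi(lp)`` when ``C = 0`` and ``sigma = 1``; as ``lp`` falls
    the probability floors at the natural-response rate ``C``.
    """
    return float(hazard_probability(lp, coeffs, include_natural=include_natural))


def stage_probabilities(lp: float, coeffs: CoefficientSet) -> np.ndarray:
    """Cumulative shared-slope stage probabilities for one linear index.

    With K ascending cut points ``tau_1 <= ... <= tau_K`` the ordered
    categories (stay, ..., escape) have probabilities

        P_0 = Phi((tau_1 - lp)/sigma),
        P_k = Phi((tau_{k+1} - lp)/sigma) - Phi((tau_k - lp)/sigma),
        P_K = 1 - Phi((tau_K - lp)/sigma).

    K = 2 reproduces the two-intercept calibrated structure; equal cut
    points give the middle category probability zero.  ``lp`` here is the
    covariate index without intercept.
    """
    if not coeffs.thresholds:
        raise ValueError("stage_probabilities requires at least one threshold")
    taus = np.asarray(coeffs.thresholds, dtype=float)
    cum = ndtr((taus - float(lp)) / coeffs.sigma)
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    return probs


class FirstPassage(NamedTuple):
    """First-escape distribution: per-period mass and censor remainder."""

    pmf: np.ndarray
    censor: float


def first_passage(hazards: Sequence[float]) -> FirstPassage:
    """Distribution of the first escape period for a hazard sequence.

    ``P(t) = p_t * prod_{s<t}(1 - p_s)``; the censor mass is the full
    survival product, so total mass is exactly one.
    """
    p = np.asarray(hazards, dtype=float)
    if p.ndim != 1:
        raise ValueError("hazards must be a one-dimensional sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("hazards must lie in [0, 1]")
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - p)[:-1]])
    pmf = p * surv_before
    censor = float(np.prod(1.0 - p))
    return FirstPassage(pmf=pmf, censor=censor)


# ---------------------------------------------------------------------------
# Panels and likelihood
# ---------------------------------------------------------------------------

def validate_records(df: pd.DataFrame) -> None:
    """Validate a respondent-level record table.

    Each row encodes one respondent's whole panel: ``period`` is the first
    escape period when ``response`` is 1, otherwise the number of observed
    periods (right censoring).  The single-escape-at-final-period invariant
    of the expanded panel holds by construction of this format.
    """
    for col in ("response", "period"):
        if col not in df.columns:
            raise ValueError(f"record table missing column {col!r}")
    if not df["response"].isin((0, 1)).all():
        raise ValueError("response must be 0 or 1")
    if (df["period"] < 1).any():
        raise ValueError("period must be >= 1")
    if "is_control" in df.columns and not df["is_control"].isin((0, 1)).all():
        raise ValueError("is_control must be 0 or 1")


def expand_panels(df: pd.DataFrame, include_censored: bool = True) -> pd.DataFrame:
    """Expand respondent rows into person-period rows.

    A respondent escaping at period *k* contributes rows ``t = 1..k`` with
    the binary outcome ``y`` equal to one only at ``t = k``; a censored
    respondent contributes all-zero rows.  Control rows are excluded — they
    inform the natural-response rate only.
    """
    validate_records(df)
    d = df[df["is_control"] == 0] if "is_control" in df.columns else df
    if not include_censored:
        d = d[d["response"] == 1]
    if len(d) == 0:
        raise ValueError("no usable respondent rows to expand")
    periods = d["period"].to_numpy(int)
    reps = np.repeat(np.arange(len(d)), periods)
    out = d.iloc[reps].reset_index(drop=True)
    t = np.concatenate([np.arange(1, k + 1) for k in periods])
    out["t"] = t
    last = t == np.repeat(periods, periods)
    out["y"] = np.where(last, out["response"].to_numpy(int), 0)
    return out


def _row_linear_predictor(panel: pd.DataFrame, coeffs: CoefficientSet,
                          period_intercepts: bool) -> np.ndarray:
    lp = np.zeros(len(panel))
    if period_intercepts and coeffs.thresholds:
        taus = np.asarray(coeffs.thresholds)
        idx = np.minimum(panel["t"].to_numpy(int), len(taus)) - 1
        lp += taus[idx]
    else:
        lp += coeffs.const
    for name, c in coeffs.attr_coeffs.items():
        if name not in panel.columns:
            raise ValueError(f"covariate {name!r} required by the coefficient set is missing")
        lp += c * panel[name].to_numpy(float)
    for name, c in coeffs.context_coeffs.items():
        if name not in panel.columns:
            raise ValueError(f"context factor {name!r} required by the coefficient set is missing")
        lp += c * panel[name].to_numpy(float)
    return lp


def log_likelihood(
    data: pd.DataFrame,
    coeffs: CoefficientSet,
    include_censored: bool = True,
    period_intercepts: bool = True,
) -> float:
    """Log-likelihood of a respondent-level record table under ``coeffs``.

    Each escape contributes ``log P(t)`` of the first-passage chain; censored
    respondents contribute their log survival product (disable with
    ``include_censored=False``).  A zero-probability observation yields
    ``-inf`` with a diagnostic rather than an exception.
    """
    panel = expand_panels(data, include_censored=include_censored)
    eta = _row_linear_predictor(panel, coeffs, period_intercepts)
    y = panel["y"].to_numpy(float)
    C = coeffs.natural_rate
    z = eta / coeffs.sigma
    if C == 0.0:
        ll_rows = np.where(y == 1, log_ndtr(z), log_ndtr(-z))
    else:
        p = C + (1.0 - C) * ndtr(z)
        with np.errstate(divide="ignore"):
            ll_rows = np.where(y == 1, np.log(p), np.log1p(-C) + log_ndtr(-z))
    total = float(np.sum(ll_rows))
    if not np.isfinite(total):
        logger.warning("zero-probability observation: log-likelihood is -inf")
        return float("-inf")
    return total


# ---------------------------------------------------------------------------
# Maximum-likelihood core
# ---------------------------------------------------------------------------

def _bernoulli_probit_ll_grad_hess(theta, Z, y, C):
    """Log-likelihood, gradient and Hessian of the natural-response probit."""
    eta = Z @ theta
    Phi = ndtr(eta)
    phi = norm.pdf(eta)
    p = C + (1.0 - C) * Phi
    if C == 0.0:
        ll = float(np.sum(np.where(y == 1, log_ndtr(eta), log_ndtr(-eta))))
    else:
        ll = float(np.sum(np.where(y == 1, np.log(p), np.log1p(-C) + log_ndtr(-eta))))
    pc = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    g = (1.0 - C) * phi
    u = (y - pc) / (pc * (1.0 - pc))
    grad = Z.T @ (u * g)
    h = -(g ** 2) * (y / pc ** 2 + (1.0 - y) / (1.0 - pc) ** 2) - eta * g * u
    hess = Z.T @ (h[:, None] * Z)
    return ll, grad, hess


def _fit_core(Z, y, natural_rate=0.0, max_iter=500, gtol=1e-8, init=None):
    """Newton maximisation of the natural-response probit likelihood.

    Starts from zeros (deterministic tie-break), takes safeguarded Newton
    steps with step halving, and declares convergence when the sup-norm of
    the score drops below ``gtol``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = Z.shape
    if np.linalg.matrix_rank(Z) < k:
        variances = Z.var(axis=0)
        flat = [i for i, v in enumerate(variances) if v == 0]
        raise NonIdentifiableError(
            "design matrix is rank deficient"
            + (f" (constant columns at positions {flat})" if len(flat) > 1 else "")
        )
    theta = np.zeros(k) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, hess = _bernoulli_probit_ll_grad_hess(theta, Z, y, natural_rate)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.max(np.abs(grad)))
        logger.debug("newton iter %d: ll=%.10g |g|=%.3e", it, ll, gnorm)
        if gnorm < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad
        if grad @ step <= 0:  # Hessian not negative definite here; fall back
            step = grad
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            ll_new, grad_new, hess_new = _bernoulli_probit_ll_grad_hess(cand, Z, y, natural_rate)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        theta, ll, grad, hess = cand, ll_new, grad_new, hess_new
    else:
        it = max_iter
    gnorm = float(np.max(np.abs(grad)))
    if gnorm < gtol:
        converged = True
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError("observed information matrix is singular") from exc
    return {
        "params": theta,
        "cov": cov,
        "loglike": ll,
        "n_iter": it,
        "converged": converged,
        "grad_norm": gnorm,
        "n_obs": n,
    }


# ---------------------------------------------------------------------------
# scikit-learn style estimator
# ---------------------------------------------------------------------------

class DiscreteTimeProbitHazard:
    """Per-period probit hazard model with natural-response correction.

    A scikit-learn style estimator over person-period rows: each row is one
    pedestrian-period with covariate vector ``x`` and binary outcome ``y``
    (1 = escaped this period).  The hazard is
    ``p = natural_rate + (1 - natural_rate) * Phi(intercept_t + x @ coef_)``.

    Parameters
    ----------
    natural_rate : float
        Fixed natural-response rate ``C`` (estimated externally from a
        control group; not jointly maximised).
    period_intercepts : bool
        Fit one intercept per decision period (requires ``periods`` at fit
        time) instead of a single constant.
    fit_intercept : bool
        Include the single constant when ``period_intercepts`` is false.
    max_iter, gtol : int, float
        Newton iteration cap and score sup-norm convergence tolerance.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Covariate coefficients.
    intercept_ : float
        Single constant (when ``period_intercepts`` is false).
    intercepts_ : ndarray
        Per-period intercepts (when ``period_intercepts`` is true).
    se_, zvalues_, pvalues_, conf_int_, cov_params_
        Inference on the full parameter vector (intercepts first), from the
        inverse observed information.
    loglike_, n_iter_, converged_
        Fit diagnostics.
    """

    def __init__(self, natural_rate: float = 0.0, period_intercepts: bool = False,
                 fit_intercept: bool = True, max_iter: int = 500, gtol: float = 1e-8):
        self.natural_rate = natural_rate
        self.period_intercepts = period_intercepts
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.gtol = gtol

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {
            "natural_rate": self.natural_rate,
            "period_intercepts": self.period_intercepts,
            "fit_intercept": self.fit_intercept,
            "max_iter": self.max_iter,
            "gtol": self.gtol,
        }

    def set_params(self, **params) -> "DiscreteTimeProbitHazard":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for {type(self).__name__}")
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"

    # -- fitting ------------------------------------------------------------

    def _design(self, X, periods):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be two-dimensional (person-period rows)")
        blocks = []
        names = []
        if self.period_intercepts:
            if periods is None:
                raise ValueError("period_intercepts=True requires the periods argument")
            periods = np.asarray(periods, dtype=int)
            if len(periods) != len(X):
                raise ValueError("periods must align with the rows of X")
            levels = self.period_levels_
            dummies = (periods[:, None] == levels[None, :]).astype(float)
            if (dummies.sum(axis=1) != 1).any():
                raise ValueError("each row's period must be one of the fitted periods")
            blocks.append(dummies)
            names += [f"intercept_{t}" for t in levels]
        elif self.fit_intercept:
            blocks.append(np.ones((len(X), 1)))
            names.append("const")
        blocks.append(X)
        names += list(self.feature_names_in_)
        return np.hstack(blocks), names

    def fit(self, X, y, periods=None):
        """Fit by Newton maximisation of the Bernoulli person-period likelihood."""
        if not 0.0 <= self.natural_rate < 1.0:
            raise ValueError(f"natural_rate must lie in [0, 1), got {self.natural_rate!r}")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(X.shape[1])], dtype=object
            )
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary (0 = stay, 1 = escape)")
        if self.period_intercepts:
            if periods is None:
                raise ValueError("period_intercepts=True requires the periods argument")
            self.period_levels_ = np.unique(np.asarray(periods, dtype=int))
        Z, names = self._design(X, periods)
        res = _fit_core(Z, y, natural_rate=self.natural_rate,
                        max_iter=self.max_iter, gtol=self.gtol)
        self.param_names_ = names
        self.params_ = res["params"]
        self.cov_params_ = res["cov"]
        self.se_ = np.sqrt(np.diag(res["cov"]))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.zvalues_ = self.params_ / self.se_
        self.pvalues_ = 2.0 * ndtr(-np.abs(self.zvalues_))
        zc = norm.ppf(0.975)
        self.conf_int_ = np.column_stack(
            [self.params_ - zc * self.se_, self.params_ + zc * self.se_]
        )
        self.loglike_ = res["loglike"]
        self.n_iter_ = res["n_iter"]
        self.converged_ = res["converged"]
        self.n_obs_ = res["n_obs"]
        n_icpt = len(self.period_levels_) if self.period_intercepts else int(self.fit_intercept)
        self.coef_ = self.params_[n_icpt:]
        if self.period_intercepts:
            self.intercepts_ = self.params_[:n_icpt]
        else:
            self.intercept_ = float(self.params_[0]) if self.fit_intercept else 0.0
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def decision_function(self, X, periods=None):
        """Linear predictor ``intercept_t + x @ coef_`` per row."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        Z, _ = self._design(np.asarray(X, dtype=float), periods)
        return Z @ self.params_

    def predict_proba(self, X, periods=None):
        """Per-row hazard as an ``(n, 2)`` array of [stay, escape] probabilities."""
        eta = self.decision_function(X, periods)
        p = self.natural_rate + (1.0 - self.natural_rate) * ndtr(eta)
        return np.column_stack([1.0 - p, p])

    def predict(self, X, periods=None):
        """Most likely per-period outcome (escape when hazard >= 0.5)."""
        return (self.predict_proba(X, periods)[:, 1] >= 0.5).astype(int)

    def score(self, X, y, periods=None):
        """Mean Bernoulli log-likelihood per person-period row."""
        p = np.clip(self.predict_proba(X, periods)[:, 1], _PCLIP, 1 - _PCLIP)
        y = np.asarray(y, dtype=float)
        return float(np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# High-level fit on record tables
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Calibration output: estimates, inference, diagnostics, coefficient set."""

    params: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    cov_params: pd.DataFrame
    loglike: float
    n_iter: int
    converged: bool
    n_respondents: int
    n_person_periods: int
    n_events: int
    pearson_chi2: float
    pearson_df: int
    excluded: list[str]
    natural_rate: float
    natural_rate_se: float | None
    coeffs: CoefficientSet | None

    def summary(self) -> str:
        """Human-readable report: estimates, covariance, convergence, natural response."""
        lines = ["Escape-decision model fit", "=" * 60]
        tab = pd.DataFrame({
            "B": self.params, "S.E.": self.se, "Z": self.zvalues,
            "Sig.": self.pvalues,
            "CI lower": self.conf_int["lower"], "CI upper": self.conf_int["upper"],
        })
        lines.append(tab.to_string(float_format=lambda v: f"{v:10.4f}"))
        if self.excluded:
            lines.append(f"excluded (not significant): {', '.join(self.excluded)}")
        lines.append("")
        lines.append("Covariance of estimates")
        lines.append(self.cov_params.to_string(float_format=lambda v: f"{v:10.6f}"))
        lines.append("")
        lines.append(
            f"converged: {self.converged} after {self.n_iter} iterations; "
            f"log-likelihood {self.loglike:.4f}"
        )
        lines.append(
            f"Pearson-type fit statistic: {self.pearson_chi2:.3f} on {self.pearson_df} df"
        )
        if self.natural_rate_se is not None:
            lines.append(
                f"natural response rate: {100 * self.natural_rate:.2f}% "
                f"(SE {self.natural_rate_se:.3f})"
            )
        else:
            lines.append(f"natural response rate (fixed): {100 * self.natural_rate:.2f}%")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "estimates": {
                name: {
                    "B": float(self.params[name]),
                    "se": float(self.se[name]),
                    "z": float(self.zvalues[name]),
                    "sig": float(self.pvalues[name]),
                    "ci": [float(self.conf_int.loc[name, "lower"]),
                           float(self.conf_int.loc[name, "upper"])],
                }
                for name in self.params.index
            },
            "cov_params": self.cov_params.to_dict(),
            "loglike": self.loglike,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_respondents": self.n_respondents,
            "n_person_periods": self.n_person_periods,
            "n_events": self.n_events,
            "pearson_chi2": self.pearson_chi2,
            "pearson_df": self.pearson_df,
            "excluded": self.excluded,
            "natural_rate": self.natural_rate,
            "natural_rate_se": self.natural_rate_se,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _pearson_statistic(Z, y, p, k_params):
    """Pearson chi-square over unique covariate patterns (model-fit diagnostic)."""
    df = pd.DataFrame(Z)
    df["_y"] = y
    df["_p"] = p
    keys = list(df.columns[:-2])
    grouped = df.groupby(keys, sort=False).agg(n=("_y", "size"), y=("_y", "sum"), p=("_p", "first"))
    exp = grouped["n"] * grouped["p"]
    var = grouped["n"] * grouped["p"] * (1 - grouped["p"])
    ok = var > 0
    chi2 = float((((grouped["y"] - exp) ** 2)[ok] / var[ok]).sum())
    return chi2, int(ok.sum() - k_params)


def fit_mle(
    data: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    natural_rate: float | str = 0.0,
    period_intercepts: bool = True,
    include_censored: bool = True,
    screen_alpha: float | None = None,
    max_iter: int = 500,
    gtol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood calibration of the escape-decision model.

    Parameters
    ----------
    data
        Respondent-level record table (see :data:`~preevac.population.RECORD_COLUMNS`).
    covariates
        Covariate columns to enter; defaults to every attribute and context
        column present in the data.
    natural_rate
        Fixed value for ``C``, or ``"from_controls"`` to estimate it from
        the table's control rows (control rows never enter the probit part).
    period_intercepts
        One intercept per decision period (default) versus a single constant.
    screen_alpha
        One-pass significance screening: fit, drop covariates with
        ``Sig. > screen_alpha``, refit once.
    """
    validate_records(data)
    logger.info("fit_mle: %d respondent rows", len(data))

    nr_se = None
    if natural_rate == "from_controls":
        if "is_control" not in data.columns or not (data["is_control"] == 1).any():
            raise ValueError("natural_rate='from_controls' but the table has no control rows")
        ctrl = data[data["is_control"] == 1]
        est = natural_response_estimate(len(ctrl), int(ctrl["response"].sum()))
        natural_rate, nr_se = est.rate, est.se
    natural_rate = float(natural_rate)

    if covariates is None:
        covariates = [c for c in (*ATTR_FIELDS, *CONTEXT_FIELDS) if c in data.columns]
    covariates = list(covariates)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"covariates {missing!r} not present in the record table")

    panel = expand_panels(data, include_censored=include_censored)
    n_resp = int((data["is_control"] == 0).sum()) if "is_control" in data.columns else len(data)

    def _run(covs):
        X = panel[covs]
        est = DiscreteTimeProbitHazard(
            natural_rate=natural_rate,
            period_intercepts=period_intercepts,
            max_iter=max_iter,
            gtol=gtol,
        )
        est.fit(X, panel["y"], periods=panel["t"] if period_intercepts else None)
        return est

    est = _run(covariates)
    excluded: list[str] = []
    if screen_alpha is not None:
        pvals = dict(zip(est.param_names_, est.pvalues_))
        excluded = [c for c in covariates if pvals[c] > screen_alpha]
        if excluded:
            logger.info("screening excluded covariates: %s", excluded)
            kept = [c for c in covariates if c not in excluded]
            if not kept:
                raise ValueError("significance screening removed every covariate")
            covariates = kept
            est = _run(covariates)

    names = est.param_names_
    params = pd.Series(est.params_, index=names)
    se = pd.Series(est.se_, index=names)
    conf = pd.DataFrame(est.conf_int_, index=names, columns=["lower", "upper"])
    cov = pd.DataFrame(est.cov_params_, index=names, columns=names)

    Z, _ = est._design(panel[covariates].to_numpy(float),
                       panel["t"] if period_intercepts else None)
    p_hat = est.predict_proba(panel[covariates],
                              periods=panel["t"] if period_intercepts else None)[:, 1]
    chi2, chi2_df = _pearson_statistic(Z, panel["y"].to_numpy(float), p_hat, len(names))

    attr = {c: float(params[c]) for c in covariates if c in ATTR_FIELDS}
    ctx = {c: float(params[c]) for c in covariates if c in CONTEXT_FIELDS}
    coeffs = None
    icpts = sorted(n for n in names if n.startswith("intercept_"))
    try:
        if period_intercepts:
            taus = tuple(float(params[n]) for n in
                         sorted(icpts, key=lambda s: int(s.split("_")[1])))
            coeffs = CoefficientSet(const=taus[0], thresholds=taus,
                                    attr_coeffs=attr, context_coeffs=ctx,
                                    natural_rate=natural_rate)
        else:
            coeffs = CoefficientSet(const=float(params["const"]), attr_coeffs=attr,
                                    context_coeffs=ctx, natural_rate=natural_rate)
    except ValueError:
        logger.warning("fitted period intercepts are not ascending; "
                       "no CoefficientSet assembled")

    return FitResult(
        params=params, se=se,
        zvalues=pd.Series(est.zvalues_, index=names),
        pvalues=pd.Series(est.pvalues_, index=names),
        conf_int=conf, cov_params=cov,
        loglike=est.loglike_, n_iter=est.n_iter_, converged=est.converged_,
        n_respondents=n_resp, n_person_periods=len(panel),
        n_events=int(panel["y"].sum()),
        pearson_chi2=chi2, pearson_df=chi2_df,
        excluded=excluded, natural_rate=natural_rate, natural_rate_se=nr_se,
        coeffs=coeffs,
    )


# ---------------------------------------------------------------------------
# Natural response
# ---------------------------------------------------------------------------

class NaturalResponseEstimate(NamedTuple):
    """Control-group natural-response rate with its binomial standard error."""

    rate: float
    se: float
    subjects: int
    responses: int

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate


def natural_response_estimate(subjects: int, responses: int) -> NaturalResponseEstimate:
    """Estimate the natural-response rate from control-group counts.

    ``rate = responses / subjects`` with binomial standard error
    ``sqrt(rate * (1 - rate) / subjects)``.
    """
    if subjects <= 0:
        raise ValueError(f"subjects must be > 0, got {subjects}")
    if not 0 <= responses <= subjects:
        raise ValueError(f"responses must lie in [0, {subjects}], got {responses}")
    rate = responses / subjects
    se = math.sqrt(rate * (1.0 - rate) / subjects)
    return NaturalResponseEstimate(rate=rate, se=se, subjects=subjects, responses=responses)
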