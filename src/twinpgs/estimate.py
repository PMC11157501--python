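"""Maximum-likelihood fitting, likelihood-ratio tests, attenuation correction.

Models are specified by fixing a subset of the parameter vector
(b0, aL, aP, c0, e0, bc, be): fixing bc = be = 0 gives the no-interaction
model, additionally fixing aP = 0 gives the plain ACE model.  Fits minimize
the -2 log-likelihood with a box-bounded quasi-Newton optimizer; nested
fits are compared with chi-square likelihood-ratio tests.

Because the PGS captures only a proportion RA2 of the additive genetic
variance, interaction coefficients estimated against the PGS are attenuated
by sqrt(RA2) relative to the moderation by the full genetic factor;
`correct_for_RA` undoes the attenuation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .model import (
    FIELD_NAMES,
    InvalidParameterError,
    ModelParams,
    PairsLike,
    TwinData,
    _as_data,
    dataset_loglik,
)

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_ml",
    "lrt",
    "correct_for_RA",
    "estimate_RA2",
]

logger = logging.getLogger(__name__)

_BOUNDS: Dict[str, Tuple[float, float]] = {
    "b0": (-np.inf, np.inf),
    "aL": (0.0, np.inf),
    "aP": (-np.inf, np.inf),
    "c0": (0.0, np.inf),
    "e0": (1e-6, np.inf),
    "bc": (-np.inf, np.inf),
    "be": (-np.inf, np.inf),
}

_PENALTY = 1e12  # objective value at inadmissible parameter points


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free, plus censoring mode.

    `fixed` maps parameter names to fixed values; all other parameters are
    estimated.  `censored` switches the likelihood to the left-censored form
    with the given `floor`.
    """

    fixed: Dict[str, float] = field(default_factory=dict)
    censored: bool = False
    floor: Optional[float] = None
    nonneg_interactions: bool = False

    def __post_init__(self) -> None:
        for name in self.fixed:
            if name not in FIELD_NAMES:
                raise ValueError(f"unknown parameter {name!r}")
        if self.censored and self.floor is None:
            raise ValueError("censored spec requires a floor value")

    @property
    def free_names(self) -> Tuple[str, ...]:
        return tuple(n for n in FIELD_NAMES if n not in self.fixed)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def nests(self, other: "ModelSpec") -> bool:
        """True if `self` (restricted) is nested in `other` (full)."""
        if not set(other.fixed) <= set(self.fixed):
            return False
        return all(self.fixed[k] == v for k, v in other.fixed.items())

    @classmethod
    def full(cls, censored: bool = False, floor: Optional[float] = None,
             nonneg: bool = False):
        return cls({}, censored, floor, nonneg)

    @classmethod
    def no_bc(cls, censored: bool = False, floor: Optional[float] = None,
              nonneg: bool = False):
        return cls({"bc": 0.0}, censored, floor, nonneg)

    @classmethod
    def no_be(cls, censored: bool = False, floor: Optional[float] = None,
              nonneg: bool = False):
        return cls({"be": 0.0}, censored, floor, nonneg)

    @classmethod
    def no_interaction(cls, censored: bool = False, floor: Optional[float] = None,
                       nonneg: bool = False):
        return cls({"bc": 0.0, "be": 0.0}, censored, floor, nonneg)

    @classmethod
    def plain_ace(cls, censored: bool = False, floor: Optional[float] = None):
        return cls({"aP": 0.0, "bc": 0.0, "be": 0.0}, censored, floor)


@dataclass(frozen=True)
class FitResult:
    """ML estimates, -2 log-likelihood and convergence status of one fit."""

    estimates: ModelParams
    minus2LL: float
    converged: bool
    n_pairs: int
    spec: ModelSpec

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    @property
    def aic(self) -> float:
        """AIC with the degrees-of-freedom penalty: -2LL - 2*(2n - k)."""
        return self.minus2LL - 2.0 * (2 * self.n_pairs - self.n_free)


def _falconer_starts(data: TwinData) -> ModelParams:
    """Starting values from MZ/DZ phenotypic covariances.

    a2 = 2(covMZ - covDZ), c2 = 2covDZ - covMZ, e2 = var - a2 - c2, each
    clipped to an admissible range; the PGS main effect starts at the pooled
    phenotype-PGS covariance, interactions at zero.
    """
    y = np.concatenate([data.y1, data.y2])
    pgs = np.concatenate([data.pgs1, data.pgs2])
    var = float(np.var(y))
    var = max(var, 1e-3)

    def _cov(mask: np.ndarray) -> float:
        if mask.sum() < 2:
            return 0.0
        return float(np.cov(data.y1[mask], data.y2[mask])[0, 1])

    cov_mz = _cov(data.is_mz)
    cov_dz = _cov(~data.is_mz)
    a2 = float(np.clip(2.0 * (cov_mz - cov_dz), 0.01 * var, 0.95 * var))
    c2 = float(np.clip(2.0 * cov_dz - cov_mz, 0.0, 0.95 * var - a2))
    e2 = max(var - a2 - c2, 0.02 * var)
    aP = float(np.cov(y, pgs)[0, 1]) if np.var(pgs) > 0 else 0.0
    aP = float(np.clip(aP, -math.sqrt(0.9 * a2), math.sqrt(0.9 * a2)))
    aL = math.sqrt(max(a2 - aP**2, 1e-4))
    return ModelParams(
        b0=float(np.mean(y)),
        aL=aL,
        aP=aP,
        c0=math.sqrt(c2) if c2 > 0 else 0.05,
        e0=math.sqrt(e2),
        bc=0.0,
        be=0.0,
    )


def fit_ml(
    pairs: PairsLike,
    spec: ModelSpec = ModelSpec.full(),
    starts: Optional[ModelParams] = None,
    max_retries: int = 5,
    jitter_sd: float = 0.1,
) -> FitResult:
    """Fit a model specification by maximum likelihood.

    Uses L-BFGS-B on the free parameters with bounds aL, c0 >= 0 and
    e0 >= 1e-6; finite-difference gradients; convergence tolerance 1e-8 on
    -2LL.  On non-convergence the starts are jittered (SD `jitter_sd`) up to
    `max_retries` times; a still-unconverged fit is returned with
    ``converged=False`` rather than raising.
    """
    data = _as_data(pairs)
    if len(data) < 2:
        raise ValueError("need at least 2 pairs to fit")
    floor = spec.floor if spec.censored else None
    if floor is None and (data.cens1.any() or data.cens2.any()):
        # censoring flags present but an uncensored fit requested: treat the
        # floored values as ordinary observations (the distortion experiment)
        data = TwinData(data.is_mz, data.y1, data.y2, data.pgs1, data.pgs2)

    start_params = starts if starts is not None else _falconer_starts(data)
    free = spec.free_names
    fixed = dict(spec.fixed)

    def theta_to_params(theta: np.ndarray) -> ModelParams:
        kw = dict(fixed)
        kw.update({name: float(t) for name, t in zip(free, theta)})
        return ModelParams(**kw)

    def objective(theta: np.ndarray) -> float:
        try:
            return dataset_loglik(theta_to_params(theta), data, floor)
        except InvalidParameterError:
            return _PENALTY

    if not free:
        m2ll = dataset_loglik(theta_to_params(np.empty(0)), data, floor)
        return FitResult(theta_to_params(np.empty(0)), m2ll, True, len(data), spec)

    bound_map = dict(_BOUNDS)
    if spec.nonneg_interactions:
        # directional alternative: moderation amplifies variance (b >= 0)
        bound_map["bc"] = (0.0, np.inf)
        bound_map["be"] = (0.0, np.inf)
    bounds = [bound_map[name] for name in free]
    start_dict = {n: getattr(start_params, n) for n in FIELD_NAMES}
    x0 = np.array([start_dict[n] for n in free])
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_retries + 1):
        xa = x0 if attempt == 0 else np.clip(
            x0 + rng.normal(0.0, jitter_sd, size=len(x0)),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        try:
            res = optimize.minimize(
                objective,
                xa,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500},
            )
        except (InvalidParameterError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < _PENALTY:
            break

    if best is not None and best.fun < _PENALTY:
        # restart from the solution: resets the Hessian approximation and
        # recovers from line-search stalls near ridges (e.g. c0 ~ 0)
        try:
            res = optimize.minimize(
                objective,
                best.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-6, "maxiter": 500},
            )
            if res.fun < best.fun:
                best = res
        except (InvalidParameterError, FloatingPointError):
            pass

    if best is None or best.fun >= _PENALTY:
        logger.warning("fit did not reach an admissible point")
        return FitResult(start_params, float("nan"), False, len(data), spec)
    converged = bool(best.success) and best.fun < _PENALTY
    return FitResult(
        theta_to_params(best.x), float(best.fun), converged, len(data), spec
    )


def lrt(full: FitResult, restricted: FitResult) -> Tuple[float, int, float]:
    """Likelihood-ratio test of a restricted model against a full model.

    Returns (chi2, df, p) with chi2 = restricted -2LL minus full -2LL
    (floored at 0) and df the number of extra free parameters in the full
    model; p is the upper chi-square tail probability.
    """
    if not restricted.spec.nests(full.spec):
        raise ValueError("restricted model is not nested in the full model")
    df = full.n_free - restricted.n_free
    if df <= 0:
        raise ValueError("full model has no extra free parameters")
    raw = restricted.minus2LL - full.minus2LL
    if raw < -1e-6:
        warnings.warn(
            f"restricted fit beats full fit by {-raw:.3g}; refit recommended",
            RuntimeWarning,
        )
    chi2 = max(raw, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def correct_for_RA(b: float, RA2: float) -> float:
    """Undo PGS attenuation: divide an interaction estimate by sqrt(RA2).

    Valid only when the PGS is built from a GWAS of the analyzed trait; a
    cross-trait PGS understates RA2 and inflates the corrected coefficient.
    """
    if not 0.0 < RA2 <= 1.0:
        raise ValueError(
            "RA2 must lie in (0, 1]; the attenuation correction applies only "
            "when the PGS targets the analyzed trait itself"
        )
    return b / math.sqrt(RA2)


def estimate_RA2(fit: FitResult) -> float:
    """Estimated proportion of genetic variance captured by the PGS."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    aP2 = fit.estimates.aP**2
    aL2 = fit.estimates.aL**2
    if aP2 + aL2 == 0.0:
        logger.info("aP = aL = 0; RA2 reported as 0 by convention")
        return 0.0
    return aP2 / (aP2 + aL2)
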