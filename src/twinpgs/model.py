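"""Core model: twin-pair data types, PGS-moderated ACE moments and likelihoods.

The model decomposes a phenotype into additive genetic (A), common
environmental (C) and unique environmental (E) influences, with a measured
polygenic score (PGS) splitting the genetic path into an observed part
(``aP``, the PGS main effect) and a latent residual (``aL``), and moderating
the environmental paths:

    C path = c0 + bc * PGS        E path = e0 + be * PGS

The PGS is treated as a definition variable: each twin's observed score
enters the expected mean and covariance of that pair.  Conditional on the
two scores the pair is bivariate normal, optionally left-censored at a
floor value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import ndtr, owens_t

__all__ = [
    "TwinPair",
    "ModelParams",
    "ConditionalMoments",
    "TwinData",
    "InvalidParameterError",
    "expected_moments",
    "pair_loglik",
    "censored_pair_loglik",
    "dataset_loglik",
    "bvn_cdf",
]

_LOG_2PI = math.log(2.0 * math.pi)

MZ = "MZ"
DZ = "DZ"


class InvalidParameterError(ValueError):
    """Raised when a parameter point implies an inadmissible distribution.

    The ML optimizer treats this as an out-of-bounds point, not a crash.
    """


@dataclass(frozen=True)
class TwinPair:
    """One twin pair: zygosity, phenotypes, standardized PGS, censoring flags.

    MZ twins share all segregating DNA, so their polygenic scores must be
    identical; DZ scores correlate 0.5 on average but are free to differ.
    """

    zygosity: str
    y1: float
    y2: float
    pgs1: float
    pgs2: float
    cens1: bool = False
    cens2: bool = False

    def __post_init__(self) -> None:
        zyg = self.zygosity.upper()
        if zyg not in (MZ, DZ):
            raise ValueError(f"unknown zygosity {self.zygosity!r}; expected MZ or DZ")
        object.__setattr__(self, "zygosity", zyg)
        if zyg == MZ and not math.isclose(self.pgs1, self.pgs2, abs_tol=1e-6):
            raise ValueError(
                f"MZ pair with unequal PGS ({self.pgs1} != {self.pgs2}); "
                "MZ twins share all DNA so their scores must match"
            )
        if not (math.isfinite(self.pgs1) and math.isfinite(self.pgs2)):
            raise ValueError("PGS values must be finite")

    @property
    def is_mz(self) -> bool:
        return self.zygosity == MZ


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the moderated ACE model.

    b0: phenotype intercept.
    aL: residual additive genetic path (latent part not captured by the PGS), >= 0.
    aP: PGS main-effect path.
    c0: baseline common-environment path, >= 0.
    e0: baseline unique-environment path, > 0.
    bc: C-by-PGS interaction coefficient.
    be: E-by-PGS interaction coefficient.

    The sign constraints on aL, c0, e0 resolve the reflection
    non-identifiability (c0, bc) -> (-c0, -bc) etc.
    """

    b0: float = 0.0
    aL: float = 0.0
    aP: float = 0.0
    c0: float = 0.0
    e0: float = 1.0
    bc: float = 0.0
    be: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.b0, self.aL, self.aP, self.c0, self.e0, self.bc, self.be)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite parameter in {vals}")
        if self.aL < 0 or self.c0 < 0:
            raise InvalidParameterError("aL and c0 must be non-negative")
        if self.e0 <= 0:
            raise InvalidParameterError("e0 must be positive")

    @property
    def a2(self) -> float:
        """Total additive genetic variance aL^2 + aP^2."""
        return self.aL**2 + self.aP**2

    @property
    def RA2(self) -> float:
        """Proportion of genetic variance captured by the PGS, aP^2 / a2."""
        a2 = self.a2
        return 0.0 if a2 == 0.0 else self.aP**2 / a2

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.b0, self.aL, self.aP, self.c0, self.e0, self.bc, self.be]
        )

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "ModelParams":
        return cls(*(float(t) for t in theta))


FIELD_NAMES = ("b0", "aL", "aP", "c0", "e0", "bc", "be")


@dataclass(frozen=True)
class ConditionalMoments:
    """Expected phenotype moments of one pair conditional on its PGS values."""

    mu1: float
    mu2: float
    v1: float
    v2: float
    cov12: float


class TwinData:
    """Column-oriented view of a twin dataset for vectorized likelihoods."""

    def __init__(
        self,
        is_mz: np.ndarray,
        y1: np.ndarray,
        y2: np.ndarray,
        pgs1: np.ndarray,
        pgs2: np.ndarray,
        cens1: Optional[np.ndarray] = None,
        cens2: Optional[np.ndarray] = None,
    ):
        n = len(y1)
        self.is_mz = np.asarray(is_mz, dtype=bool)
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        self.pgs1 = np.asarray(pgs1, dtype=float)
        self.pgs2 = np.asarray(pgs2, dtype=float)
        zeros = np.zeros(n, dtype=bool)
        self.cens1 = zeros if cens1 is None else np.asarray(cens1, dtype=bool)
        self.cens2 = zeros.copy() if cens2 is None else np.asarray(cens2, dtype=bool)

    def __len__(self) -> int:
        return len(self.y1)

    @property
    def n_mz(self) -> int:
        return int(self.is_mz.sum())

    @property
    def n_dz(self) -> int:
        return len(self) - self.n_mz

    @classmethod
    def from_pairs(cls, pairs: Iterable[TwinPair]) -> "TwinData":
        pairs = list(pairs)
        return cls(
            is_mz=np.array([p.is_mz for p in pairs]),
            y1=np.array([p.y1 for p in pairs]),
            y2=np.array([p.y2 for p in pairs]),
            pgs1=np.array([p.pgs1 for p in pairs]),
            pgs2=np.array([p.pgs2 for p in pairs]),
            cens1=np.array([p.cens1 for p in pairs]),
            cens2=np.array([p.cens2 for p in pairs]),
        )

    def to_pairs(self) -> list:
        return [
            TwinPair(
                MZ if self.is_mz[i] else DZ,
                float(self.y1[i]),
                float(self.y2[i]),
                float(self.pgs1[i]),
                float(self.pgs2[i]),
                bool(self.cens1[i]),
                bool(self.cens2[i]),
            )
            for i in range(len(self))
        ]


PairsLike = Union[TwinData, Sequence[TwinPair]]


def _as_data(pairs: PairsLike) -> TwinData:
    if isinstance(pairs, TwinData):
        return pairs
    return TwinData.from_pairs(pairs)


def _moment_arrays(params: ModelParams, data: TwinData):
    """Vectorized conditional moments (mu1, mu2, v1, v2, cov12) per pair.

    mu_i  = b0 + aP*pgs_i
    v_i   = aL^2 + (c0 + bc*pgs_i)^2 + (e0 + be*pgs_i)^2
    cov12 = rho_AL*aL^2 + (c0 + bc*pgs1)(c0 + bc*pgs2),
            rho_AL = 1 (MZ) or 0.5 (DZ).
    """
    c1 = params.c0 + params.bc * data.pgs1
    c2 = params.c0 + params.bc * data.pgs2
    e1 = params.e0 + params.be * data.pgs1
    e2 = params.e0 + params.be * data.pgs2
    aL2 = params.aL**2
    mu1 = params.b0 + params.aP * data.pgs1
    mu2 = params.b0 + params.aP * data.pgs2
    v1 = aL2 + c1**2 + e1**2
    v2 = aL2 + c2**2 + e2**2
    rho_al = np.where(data.is_mz, 1.0, 0.5)
    cov12 = rho_al * aL2 + c1 * c2
    return mu1, mu2, v1, v2, cov12


def expected_moments(params: ModelParams, pair: TwinPair) -> ConditionalMoments:
    """Model-implied phenotype moments for one pair given its PGS values.

    Conditioning on the observed scores moves the aP*PGS genetic main effect
    into the mean; the cross-twin covariance keeps the latent-genetic term
    rho_AL*aL^2 and the moderated shared-environment product.  Marginalizing
    back over a unit-variance PGS (with pgs1 == pgs2) recovers the familiar
    aL^2 + aP^2 + (c0+bc*PGS)^2 + (e0+be*PGS)^2 variance decomposition.
    """
    data = TwinData.from_pairs([pair])
    mu1, mu2, v1, v2, cov12 = _moment_arrays(params, data)
    return ConditionalMoments(
        float(mu1[0]), float(mu2[0]), float(v1[0]), float(v2[0]), float(cov12[0])
    )


def _check_admissible(v1, v2, cov12) -> None:
    det = v1 * v2 - cov12**2
    if np.any(v1 <= 0) or np.any(v2 <= 0) or np.any(det <= 0):
        raise InvalidParameterError(
            "implied pair covariance matrix is not positive definite"
        )


def _bvn_logpdf(d1, d2, v1, v2, cov12):
    det = v1 * v2 - cov12**2
    quad = (v2 * d1**2 - 2.0 * cov12 * d1 * d2 + v1 * d2**2) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def pair_loglik(params: ModelParams, pair: TwinPair) -> float:
    """Bivariate-normal log-density of one uncensored pair at its moments."""
    if pair.cens1 or pair.cens2:
        raise ValueError("pair has censoring flags set; use censored_pair_loglik")
    m = expected_moments(params, pair)
    _check_admissible(np.array(m.v1), np.array(m.v2), np.array(m.cov12))
    return float(
        _bvn_logpdf(pair.y1 - m.mu1, pair.y2 - m.mu2, m.v1, m.v2, m.cov12)
    )


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) with correlation rho.

    Uses Owen's T-function identity, vectorized over all arguments.  Exact
    zeros in h or k are nudged by 1e-12 to avoid the removable singularity
    of the a-ratios (error far below the 1e-6 level the likelihood needs).
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.clip(np.asarray(rho, dtype=float), -1.0 + 1e-12, 1.0 - 1e-12)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    r = np.sqrt(1.0 - rho**2)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    beta = np.where(h * k < 0, 0.5, 0.0)
    p = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return np.clip(p, 0.0, 1.0)


_TINY = 1e-300


def censored_pair_loglik(
    params: ModelParams, pair: TwinPair, floor: float
) -> float:
    """Left-censored pair log-likelihood.

    Both twins observed: bivariate density.  One censored: marginal density
    of the observed twin times the conditional normal CDF of the censored
    twin below the floor.  Both censored: bivariate normal CDF at
    (floor, floor).
    """
    data = TwinData.from_pairs([pair])
    ll = _loglik_vector(params, data, floor)
    return float(ll[0])


def _loglik_vector(
    params: ModelParams, data: TwinData, floor: Optional[float]
) -> np.ndarray:
    mu1, mu2, v1, v2, cov12 = _moment_arrays(params, data)
    _check_admissible(v1, v2, cov12)
    d1 = data.y1 - mu1
    d2 = data.y2 - mu2
    ll = _bvn_logpdf(d1, d2, v1, v2, cov12)

    if floor is None:
        return ll

    c1, c2 = data.cens1, data.cens2
    one = c1 ^ c2
    if np.any(one):
        # conditional distribution of the censored twin given the observed one
        yo = np.where(c1[one], data.y2[one], data.y1[one])
        mo = np.where(c1[one], mu2[one], mu1[one])
        vo = np.where(c1[one], v2[one], v1[one])
        mc = np.where(c1[one], mu1[one], mu2[one])
        vc = np.where(c1[one], v1[one], v2[one])
        cv = cov12[one]
        mu_cond = mc + cv / vo * (yo - mo)
        v_cond = vc - cv**2 / vo
        if np.any(v_cond <= 0):
            raise InvalidParameterError("degenerate conditional variance")
        lo = -0.5 * (_LOG_2PI + np.log(vo) + (yo - mo) ** 2 / vo)
        phi = ndtr((floor - mu_cond) / np.sqrt(v_cond))
        ll[one] = lo + np.log(np.maximum(phi, _TINY))

    both = c1 & c2
    if np.any(both):
        h = (floor - mu1[both]) / np.sqrt(v1[both])
        k = (floor - mu2[both]) / np.sqrt(v2[both])
        rho = cov12[both] / np.sqrt(v1[both] * v2[both])
        p = bvn_cdf(h, k, rho)
        ll[both] = np.log(np.maximum(p, _TINY))

    return ll


def dataset_loglik(
    params: ModelParams, pairs: PairsLike, floor: Optional[float] = None
) -> float:
    """-2 * total log-likelihood of a dataset under `params`.

    Pairs with censoring flags use the censored contribution (requires
    `floor`); all others use the plain bivariate-normal density.
    """
    data = _as_data(pairs)
    if len(data) == 0:
        raise ValueError("empty dataset")
    if floor is None and (data.cens1.any() or data.cens2.any()):
        raise ValueError("dataset has censoring flags but no floor was given")
    ll = _loglik_vector(params, data, floor)
    return float(-2.0 * ll.sum())
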