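"""Synthetic twin-pair generator with true moderation by the total genetic factor.

The generating process draws, per pair, a PGS genetic component (variance
RA2, correlated 1 in MZ and 0.5 in DZ pairs), a residual genetic component
(variance 1 - RA2, same correlation structure), one shared C and two
independent E factors, and builds the phenotype as

    y_i = sqrt(a2) * A_i + (sqrt(c02) + beta_c * A_i) * C
                         + (sqrt(e02) + beta_e * A_i) * E_i

where A is the standardized total genetic factor.  The *observed* polygenic
score is only the PGS component (standardized), so a model fitted with the
PGS as moderator recovers the attenuated coefficients beta * sqrt(RA2).

The interaction coefficients are parameterized through effect sizes
delta = b^2 + 2*b*base, the increase in environmental variance per SD of
the moderator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import PairsLike, TwinData, _as_data

__all__ = ["Scenario", "effect_size_to_coef", "simulate_pairs", "apply_floor"]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition.

    a2, c02, e02: generating variance components (phenotype scaled so they
    sum to ~1 in the standard grid).  RA2: proportion of genetic variance
    the PGS captures.  delta_c, delta_e: interaction effect sizes (variance
    change per SD of the moderator).  floor_prop: fraction of phenotype
    values collapsed onto a left floor (0 disables).
    """

    a2: float = 0.55
    c02: float = 0.10
    e02: float = 0.35
    RA2: float = 0.10
    delta_c: float = 0.10
    delta_e: float = 0.10
    nMZ: int = 2000
    nDZ: int = 2000
    floor_prop: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a2 < 0 or self.c02 < 0:
            raise ValueError("a2 and c02 must be non-negative")
        if self.e02 <= 0:
            raise ValueError("e02 must be positive")
        if not 0.0 <= self.RA2 <= 1.0:
            raise ValueError("RA2 must lie in [0, 1]")
        if self.delta_c < 0 or self.delta_e < 0:
            raise ValueError("effect sizes must be non-negative")
        if not 0.0 <= self.floor_prop < 1.0:
            raise ValueError("floor_prop must lie in [0, 1)")
        if self.nMZ < 0 or self.nDZ < 0 or self.nMZ + self.nDZ == 0:
            raise ValueError("need a positive number of pairs")

    @property
    def beta_c(self) -> float:
        """True C-by-A interaction coefficient implied by delta_c."""
        return effect_size_to_coef(self.delta_c, math.sqrt(self.c02))

    @property
    def beta_e(self) -> float:
        """True E-by-A interaction coefficient implied by delta_e."""
        return effect_size_to_coef(self.delta_e, math.sqrt(self.e02))

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)


def effect_size_to_coef(delta: float, base_path: float) -> float:
    """Interaction coefficient b solving delta = b^2 + 2*b*base_path.

    delta is the phenotypic variance explained by the interaction per SD of
    the moderator; the positive root is returned.
    """
    if delta < 0:
        raise ValueError("effect size delta must be non-negative")
    if base_path < 0:
        raise ValueError("base path coefficient must be non-negative")
    return math.sqrt(base_path**2 + delta) - base_path


def _correlated_pairs(rng: np.random.Generator, n: int, rho: float, var: float):
    """Draw n bivariate normal pairs with common variance and correlation."""
    z = rng.standard_normal((n, 2))
    x1 = z[:, 0]
    x2 = rho * z[:, 0] + math.sqrt(1.0 - rho**2) * z[:, 1]
    s = math.sqrt(var)
    return s * x1, s * x2


def simulate_pairs(scenario: Scenario) -> TwinData:
    """Generate a twin dataset under `scenario` (deterministic per seed).

    Returns the pairs with observed phenotypes and standardized PGS values;
    the floor transform is applied afterwards when floor_prop > 0.
    """
    if scenario.RA2 == 0.0:
        raise ValueError(
            "RA2 = 0 leaves the polygenic score undefined (degenerate scenario)"
        )
    rng = np.random.default_rng(scenario.seed)
    bc, be = scenario.beta_c, scenario.beta_e
    sa = math.sqrt(scenario.a2)
    sc = math.sqrt(scenario.c02)
    se = math.sqrt(scenario.e02)
    s_pgs = math.sqrt(scenario.RA2)

    blocks = []
    for is_mz, n in ((True, scenario.nMZ), (False, scenario.nDZ)):
        if n == 0:
            continue
        rho = 1.0 if is_mz else 0.5
        ap1, ap2 = _correlated_pairs(rng, n, rho, scenario.RA2)
        al1, al2 = _correlated_pairs(rng, n, rho, 1.0 - scenario.RA2)
        if is_mz:
            ap2, al2 = ap1, al1  # exact sharing, not merely correlation 1
        a1, a2_ = ap1 + al1, ap2 + al2
        c = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        y1 = sa * a1 + (sc + bc * a1) * c + (se + be * a1) * e1
        y2 = sa * a2_ + (sc + bc * a2_) * c + (se + be * a2_) * e2
        # standardize by the generating SD so MZ equality stays exact
        blocks.append(
            (np.full(n, is_mz), y1, y2, ap1 / s_pgs, ap2 / s_pgs)
        )

    cols = [np.concatenate([b[j] for b in blocks]) for j in range(5)]
    data = TwinData(is_mz=cols[0], y1=cols[1], y2=cols[2], pgs1=cols[3], pgs2=cols[4])
    if scenario.floor_prop > 0:
        data, _ = apply_floor(data, scenario.floor_prop)
    return data


def apply_floor(data: PairsLike, floor_prop: float):
    """Collapse the lowest `floor_prop` fraction of phenotypes onto a floor.

    The floor is the empirical floor_prop-quantile of the pooled phenotype
    values (both twins, both zygosity groups); every value below it is
    replaced by it and flagged as censored.  Returns (new data, floor value).
    """
    data = _as_data(data)
    if not 0.0 <= floor_prop < 1.0:
        raise ValueError("floor_prop must lie in [0, 1)")
    if floor_prop == 0.0:
        return data, None
    pooled = np.concatenate([data.y1, data.y2])
    floor = float(np.quantile(pooled, floor_prop))
    cens1 = data.y1 < floor
    cens2 = data.y2 < floor
    y1 = np.where(cens1, floor, data.y1)
    y2 = np.where(cens2, floor, data.y2)
    return (
        TwinData(
            is_mz=data.is_mz,
            y1=y1,
            y2=y2,
            pgs1=data.pgs1,
            pgs2=data.pgs2,
            cens1=cens1,
            cens2=cens2,
        ),
        floor,
    )
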