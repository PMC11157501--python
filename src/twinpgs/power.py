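"""Monte-Carlo power, false-positive-rate and conditional-variance analyses.

Each replicate simulates a twin dataset under a scenario, fits the full
moderated model plus the three nested restrictions (bc = 0, be = 0,
bc = be = 0) and records rejections of the 1-df and 2-df (omnibus)
likelihood-ratio tests.  Replication r of a scenario uses seed + r, so
results do not depend on execution order or worker count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .estimate import FitResult, ModelSpec, fit_ml, lrt
from .model import ModelParams
from .simulate import Scenario, simulate_pairs

__all__ = [
    "PowerResult",
    "run_scenario",
    "false_positive_rate",
    "conditional_variance_profile",
    "required_n",
]

logger = logging.getLogger(__name__)

TESTS = ("bc", "be", "om")
_TEST_DF = {"bc": 1, "be": 1, "om": 2}


@dataclass(frozen=True)
class PowerResult:
    """Aggregated Monte-Carlo results for one scenario."""

    scenario: Scenario
    n_reps: int
    alpha: float
    reject: Dict[str, float]  # rejection rate per test (bc, be, om)
    mc_se: Dict[str, float]  # binomial Monte-Carlo SE per rate
    mean_chi2: Dict[str, float]
    mean_bc: float
    sd_bc: float
    mean_be: float
    sd_be: float
    convergence_rate: float
    flagged: bool  # convergence rate below 90%

    def row(self) -> Dict[str, float]:
        """Flat dict mirroring one row of a power-table report."""
        s = self.scenario
        return {
            "RA2": s.RA2,
            "a2": s.a2,
            "c02": s.c02,
            "e02": s.e02,
            "beta_c": s.beta_c,
            "beta_e": s.beta_e,
            "nMZ": s.nMZ,
            "nDZ": s.nDZ,
            "mean_bc": self.mean_bc,
            "mean_be": self.mean_be,
            "power_bc": self.reject["bc"],
            "power_be": self.reject["be"],
            "power_om": self.reject["om"],
            "n_reps": self.n_reps,
            "convergence": self.convergence_rate,
        }


def chibar2_crit(alpha: float, df: int) -> float:
    """Critical value of the one-sided (chi-bar-square) interaction LRT.

    With the interaction coefficients constrained to be non-negative, the
    null distribution of the LRT statistic is the boundary mixture
    (1/2)chi2_0 + (1/2)chi2_1 for one coefficient and
    (1/4)chi2_0 + (1/2)chi2_1 + (1/4)chi2_2 for both, giving an exact
    alpha-level test of directional (variance-amplifying) moderation.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if df == 1:
        return float(stats.chi2.isf(2.0 * alpha, 1))
    if df == 2:
        from scipy.optimize import brentq

        def size(c: float) -> float:
            return 0.5 * stats.chi2.sf(c, 1) + 0.25 * stats.chi2.sf(c, 2)

        return float(brentq(lambda c: size(c) - alpha, 1e-6, 50.0))
    raise ValueError("df must be 1 or 2")


def _crits(alpha: float, one_sided: bool) -> Dict[str, float]:
    if one_sided:
        c1, c2 = chibar2_crit(alpha, 1), chibar2_crit(alpha, 2)
    else:
        c1, c2 = float(stats.chi2.isf(alpha, 1)), float(stats.chi2.isf(alpha, 2))
    return {"bc": c1, "be": c1, "om": c2}


def _one_replicate(
    scenario: Scenario,
    rep_seed: int,
    crits: Dict[str, float],
    censored_fit: bool,
    nonneg: bool,
):
    data = simulate_pairs(scenario.with_seed(rep_seed))
    floor = None
    if censored_fit:
        vals = np.concatenate([data.y1, data.y2])
        floor = float(vals.min())
    full_spec = ModelSpec.full(censored_fit, floor, nonneg)
    full = fit_ml(data, full_spec)
    warm = full.estimates if full.converged else None
    fits = {
        "om": fit_ml(data, ModelSpec.no_interaction(censored_fit, floor, nonneg), warm),
        "bc": fit_ml(data, ModelSpec.no_bc(censored_fit, floor, nonneg), warm),
        "be": fit_ml(data, ModelSpec.no_be(censored_fit, floor, nonneg), warm),
    }
    # a restricted optimum is a feasible point of the full model: if any
    # restriction beats the full fit, the full fit stalled -- refit from there
    for restricted in fits.values():
        if restricted.converged and restricted.minus2LL < full.minus2LL - 1e-6:
            refit = fit_ml(data, full_spec, starts=restricted.estimates)
            if refit.converged and refit.minus2LL < full.minus2LL:
                full = refit
    ok = full.converged and all(f.converged for f in fits.values())
    if not ok:
        return None
    out = {}
    for name, restricted in fits.items():
        chi2, _, _ = lrt(full, restricted)
        out[name] = (chi2, chi2 > crits[name])
    return out, full.estimates.bc, full.estimates.be


def run_scenario(
    scenario: Scenario,
    n_reps: int = 1000,
    alpha: float = 0.05,
    censored_fit: bool = False,
    one_sided: bool = True,
    n_jobs: int = 1,
) -> PowerResult:
    """Monte-Carlo power (or size) of the three interaction LRTs.

    By default the engine tests directional moderation: the interaction
    coefficients are constrained to be non-negative (the alternative is
    variance amplification) and the LRT statistics are referred to the
    chi-bar-square boundary mixture, an exact alpha-level test.
    `one_sided=False` switches to unconstrained fits with plain two-sided
    chi-square critical values.

    Non-converged replicates are excluded from every rate denominator; a
    convergence rate below 90% flags the result instead of discarding it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    crits = _crits(alpha, one_sided)
    seeds = [scenario.seed + r for r in range(n_reps)]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        raw = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(scenario, s, crits, censored_fit, one_sided)
            for s in seeds
        )
    else:
        raw = [
            _one_replicate(scenario, s, crits, censored_fit, one_sided)
            for s in seeds
        ]

    results = [r for r in raw if r is not None]
    n_ok = len(results)
    conv = n_ok / n_reps
    if conv < 0.9:
        logger.warning("convergence rate %.2f below 0.90; result flagged", conv)
    if n_ok == 0:
        raise RuntimeError("no replicate converged")

    reject, mc_se, mean_chi2 = {}, {}, {}
    for t in TESTS:
        hits = np.array([res[0][t][1] for res in results])
        chi2s = np.array([res[0][t][0] for res in results])
        p = float(hits.mean())
        reject[t] = p
        mc_se[t] = math.sqrt(p * (1.0 - p) / n_ok)
        mean_chi2[t] = float(chi2s.mean())
    bcs = np.array([res[1] for res in results])
    bes = np.array([res[2] for res in results])
    return PowerResult(
        scenario=scenario,
        n_reps=n_reps,
        alpha=alpha,
        reject=reject,
        mc_se=mc_se,
        mean_chi2=mean_chi2,
        mean_bc=float(bcs.mean()),
        sd_bc=float(bcs.std(ddof=1)) if n_ok > 1 else 0.0,
        mean_be=float(bes.mean()),
        sd_be=float(bes.std(ddof=1)) if n_ok > 1 else 0.0,
        convergence_rate=conv,
        flagged=conv < 0.9,
    )


def false_positive_rate(
    scenario: Scenario,
    floor_prop: float = 0.0,
    n_reps: int = 1000,
    alpha: float = 0.05,
    censored_fit: bool = False,
    one_sided: bool = True,
    n_jobs: int = 1,
) -> PowerResult:
    """Rejection rates under a no-interaction generating model.

    With floor_prop > 0 the lowest fraction of phenotype values is collapsed
    onto a floor before fitting; the default fit ignores the censoring (the
    distortion experiment), `censored_fit=True` models it.
    """
    if scenario.delta_c != 0.0 or scenario.delta_e != 0.0:
        raise ValueError("false-positive scenarios require delta_c = delta_e = 0")
    sc = replace(scenario, floor_prop=floor_prop)
    return run_scenario(
        sc, n_reps, alpha, censored_fit=censored_fit, one_sided=one_sided,
        n_jobs=n_jobs,
    )


def conditional_variance_profile(
    params: ModelParams, pgs_grid: np.ndarray
) -> pd.DataFrame:
    """Variance components as a function of the PGS.

    Per grid point: a2 = aL^2 + aP^2 (constant), c2 = (c0 + bc*pgs)^2,
    e2 = (e0 + be*pgs)^2, total = a2 + c2 + e2.
    """
    pgs = np.asarray(pgs_grid, dtype=float)
    if not np.all(np.isfinite(pgs)):
        raise ValueError("pgs grid must be finite")
    a2 = np.full_like(pgs, params.aL**2 + params.aP**2)
    c2 = (params.c0 + params.bc * pgs) ** 2
    e2 = (params.e0 + params.be * pgs) ** 2
    return pd.DataFrame(
        {"pgs": pgs, "a2": a2, "c2": c2, "e2": e2, "total": a2 + c2 + e2}
    )


def required_n(
    scenario: Scenario,
    target_power: float,
    pilot: PowerResult,
    test: str = "bc",
) -> int:
    """Approximate pair count reaching `target_power`, by NCP extrapolation.

    The mean LRT statistic of the pilot minus its df estimates the
    non-centrality parameter at the pilot's n; the NCP scales linearly in n,
    so the n at which the non-central chi-square test attains the target
    power is pilot_n * (target NCP / pilot NCP).  A rough guide, not an
    exact sample-size calculation.
    """
    if test not in TESTS:
        raise ValueError(f"test must be one of {TESTS}")
    power = pilot.reject[test]
    if power >= 0.999 or power <= pilot.alpha:
        raise ValueError(
            "pilot power too close to 1 or to the significance level for a "
            "reliable extrapolation"
        )
    df = _TEST_DF[test]
    ncp_pilot = pilot.mean_chi2[test] - df
    if ncp_pilot <= 0:
        raise ValueError("pilot mean chi-square at or below its df")
    crit = stats.chi2.isf(pilot.alpha, df)

    def power_at(ncp: float) -> float:
        return float(stats.ncx2.sf(crit, df, ncp))

    from scipy.optimize import brentq

    ncp_target = brentq(lambda l: power_at(l) - target_power, 1e-9, 1e4)
    n_pilot = scenario.nMZ + scenario.nDZ
    return int(round(n_pilot * ncp_target / ncp_pilot))
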