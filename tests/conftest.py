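import numpy as np
import pytest

from twinpgs import ModelParams, Scenario, TwinData, TwinPair, simulate_pairs


@pytest.fixture(scope="session")
def params_mid() -> ModelParams:
    """A representative admissible parameter point with active moderation."""
    return ModelParams(b0=0.1, aL=0.70, aP=0.23, c0=0.32, e0=0.59, bc=0.05, be=0.03)


@pytest.fixture(scope="session")
def scenario1() -> Scenario:
    """The reference simulation condition: RA2=.1, a2=.55, c02=.10, e02=.35."""
    return Scenario(
        a2=0.55, c02=0.10, e02=0.35, RA2=0.10,
        delta_c=0.10, delta_e=0.10, nMZ=2000, nDZ=2000, seed=100,
    )


@pytest.fixture(scope="session")
def small_dataset(scenario1) -> TwinData:
    """A 600-pair dataset under the reference condition (fast fits)."""
    from dataclasses import replace

    return simulate_pairs(replace(scenario1, nMZ=300, nDZ=300, seed=11))


def random_pairs(rng: np.random.Generator, n: int) -> list:
    """Random valid twin pairs with mixed zygosity (helper, not a fixture)."""
    out = []
    for _ in range(n):
        mz = bool(rng.random() < 0.5)
        p1 = float(rng.normal())
        p2 = p1 if mz else float(rng.normal(0.5 * p1, np.sqrt(0.75)))
        out.append(
            TwinPair("MZ" if mz else "DZ", float(rng.normal()), float(rng.normal()),
                     p1, p2)
        )
    return out
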