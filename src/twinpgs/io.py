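"""Twin-table CSV reading/writing and scenario configuration files.

The twin table is a wide, one-row-per-pair CSV with columns
family_id, zygosity, y1, y2, pgs1, pgs2 (header required).  A left-censoring
floor may be declared as a leading comment line ``# floor=<value>``; rows
whose phenotype equals the floor get their censoring flag set on read.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import TwinData
from .simulate import Scenario

__all__ = [
    "read_twin_table",
    "write_twin_table",
    "infer_floor",
    "read_scenario",
]

logger = logging.getLogger(__name__)

COLUMNS = ["family_id", "zygosity", "y1", "y2", "pgs1", "pgs2"]

_MZ_PGS_TOL = 1e-6


def read_twin_table(
    path: Union[str, Path], floor: Optional[float] = None
) -> TwinData:
    """Read a twin-pair CSV; returns the dataset with censoring flags set.

    A floor declared in the file header is used unless overridden by the
    `floor` argument.  Raises on missing phenotypes, non-finite PGS values,
    unknown zygosity codes, or MZ rows whose two PGS values differ.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    declared = _parse_floor_header(text)
    if floor is None:
        floor = declared

    df = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"twin table is missing columns {missing}")

    zyg = df["zygosity"].astype(str).str.upper()
    bad = ~zyg.isin(["MZ", "DZ"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unknown zygosity {df['zygosity'].iloc[row]!r} in row {row}")
    num = df[["y1", "y2", "pgs1", "pgs2"]].apply(pd.to_numeric, errors="coerce")
    if num[["y1", "y2"]].isna().any().any():
        raise ValueError("missing phenotype values; only complete pairs are supported")
    if not np.isfinite(num[["pgs1", "pgs2"]].to_numpy()).all():
        raise ValueError("PGS columns must be finite")

    is_mz = (zyg == "MZ").to_numpy()
    pgs_diff = np.abs(num["pgs1"].to_numpy() - num["pgs2"].to_numpy())
    bad_mz = is_mz & (pgs_diff > _MZ_PGS_TOL)
    if bad_mz.any():
        row = int(np.flatnonzero(bad_mz)[0])
        raise ValueError(
            f"row {row}: MZ pair with unequal PGS values "
            f"({num['pgs1'].iloc[row]} vs {num['pgs2'].iloc[row]}); "
            "MZ twins share all DNA so their scores must match"
        )

    y1 = num["y1"].to_numpy(float)
    y2 = num["y2"].to_numpy(float)
    cens1 = cens2 = None
    if floor is not None:
        cens1 = y1 == floor
        cens2 = y2 == floor
    data = TwinData(
        is_mz=is_mz,
        y1=y1,
        y2=y2,
        pgs1=num["pgs1"].to_numpy(float),
        pgs2=num["pgs2"].to_numpy(float),
        cens1=cens1,
        cens2=cens2,
    )
    logger.info(
        "read %d pairs (%d MZ, %d DZ) from %s", len(data), data.n_mz, data.n_dz, path
    )
    return data


def write_twin_table(
    data: TwinData, path: Union[str, Path], floor: Optional[float] = None
) -> None:
    """Write a twin dataset as CSV, with the floor in a header comment."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "family_id": np.arange(1, len(data) + 1),
            "zygosity": np.where(data.is_mz, "MZ", "DZ"),
            "y1": data.y1,
            "y2": data.y2,
            "pgs1": data.pgs1,
            "pgs2": data.pgs2,
        }
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        if floor is not None:
            fh.write(f"# floor={floor!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # lossless round trip


def _parse_floor_header(text: str) -> Optional[float]:
    for line in text.splitlines():
        if not line.startswith("#"):
            return None
        body = line.lstrip("#").strip()
        if body.startswith("floor="):
            return float(body.split("=", 1)[1])
    return None


def infer_floor(data: TwinData, min_tie_frac: float = 0.01) -> Optional[float]:
    """Dataset minimum, if at least `min_tie_frac` of values tie there.

    A mass of observations at the scale minimum is the signature of a floor
    effect; with fewer ties there is no evidence of censoring and None is
    returned.
    """
    pooled = np.concatenate([data.y1, data.y2])
    lo = pooled.min()
    frac = float((pooled == lo).mean())
    if frac >= min_tie_frac:
        logger.info("inferred floor %.6g (%.1f%% of values tie there)", lo, 100 * frac)
        return float(lo)
    return None


def read_scenario(path: Union[str, Path]) -> Scenario:
    """Load a Scenario from a YAML/JSON mapping with Scenario field names."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of scenario fields")
    return Scenario(**raw)


def write_truth_sidecar(scenario: Scenario, path: Union[str, Path]) -> None:
    """Record the generating truth of a simulated dataset as JSON."""
    payload = {
        "a2": scenario.a2,
        "c02": scenario.c02,
        "e02": scenario.e02,
        "RA2": scenario.RA2,
        "delta_c": scenario.delta_c,
        "delta_e": scenario.delta_e,
        "beta_c": scenario.beta_c,
        "beta_e": scenario.beta_e,
        "attenuated_bc": scenario.beta_c * scenario.RA2**0.5,
        "attenuated_be": scenario.beta_e * scenario.RA2**0.5,
        "nMZ": scenario.nMZ,
        "nDZ": scenario.nDZ,
        "floor_prop": scenario.floor_prop,
        "seed": scenario.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
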