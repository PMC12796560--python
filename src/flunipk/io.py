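"""Dataset and configuration I/O.

Datasets travel as a NONMEM-style CSV (ID, TIME, EVID, AMT, DV, MATRIX, LOQ,
AGE, BW, SEX, BREED, COUNTRY; EVID 1 = dose with AMT in ng/kg, EVID 0 =
observation with DV in ng/mL; MDV is implied by EVID).  Synthetic ground
truth travels in a JSON sidecar so a round trip preserves recovery tests.
Priors and screening-limit scenarios are JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DATASET_COLUMNS, ConcentrationDataset, StudyArmDesign
from .model import DispositionParams, PopulationParams

logger = logging.getLogger(__name__)

_MANDATORY = ["ID", "TIME", "EVID", "AMT", "DV", "MATRIX", "LOQ"]


class DatasetFormatError(ValueError):
    pass


def write_dataset(data: ConcentrationDataset, path) -> None:
    """Write the canonical CSV; ground truth (if any) goes to ``<path>.truth.json``."""
    path = Path(path)
    data.records.to_csv(path, index=False)
    if data.truths:
        sidecar = {str(k): list(v.as_array()) for k, v in data.truths.items()}
        path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(path) -> ConcentrationDataset:
    """Read the canonical CSV (and truth sidecar if present), validating the dialect."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in frame.columns]
    if missing:
        raise DatasetFormatError(
            f"{path}: missing mandatory column(s) {missing}; expected at least {_MANDATORY}")
    for col in ("ARM", "AGE", "BW", "SEX", "BREED", "COUNTRY"):
        if col not in frame.columns:
            frame[col] = "" if col in ("ARM", "SEX", "BREED", "COUNTRY") else np.nan
    for col in ("MATRIX", "ARM", "SEX", "BREED", "COUNTRY"):
        frame[col] = frame[col].fillna("")
    if "BELOW_LOQ" not in frame.columns:
        frame["BELOW_LOQ"] = (frame["EVID"] == 0) & (frame["DV"] < frame["LOQ"])
    bad_time = frame.index[frame["TIME"] < 0].tolist()
    if bad_time:
        raise DatasetFormatError(f"{path}: negative TIME at row(s) {[i + 2 for i in bad_time]}")
    bad_dv = frame.index[(frame["EVID"] == 0) & (frame["DV"] < 0)].tolist()
    if bad_dv:
        raise DatasetFormatError(f"{path}: negative DV at row(s) {[i + 2 for i in bad_dv]}")
    dose_with_dv = frame.index[(frame["EVID"] == 1) & frame["DV"].notna()].tolist()
    if dose_with_dv:
        logger.warning("%s: DV present on dose row(s) %s; ignored",
                       path, [i + 2 for i in dose_with_dv])
        frame.loc[dose_with_dv, "DV"] = np.nan
    frame = frame[DATASET_COLUMNS]
    truths = {}
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        ids = dict(zip(frame["ID"].astype(str), frame["ID"]))
        truths = {ids[k]: DispositionParams.from_array(v) for k, v in raw.items() if k in ids}
    return ConcentrationDataset(frame, truths)


def read_prior(path) -> PopulationParams:
    """Load a population prior (theta/omega/sigmas) from JSON."""
    raw = json.loads(Path(path).read_text())
    return PopulationParams(
        theta=np.array(raw["theta"]), omega=np.array(raw["omega"]),
        sigma_plasma_prop=raw["sigma_plasma_prop"], sigma_plasma_add=raw["sigma_plasma_add"],
        sigma_urine_prop=raw["sigma_urine_prop"], sigma_urine_add=raw["sigma_urine_add"],
    )


def write_prior(pop: PopulationParams, path) -> None:
    payload = dict(
        parameter_names=list(pop.parameter_names),
        theta=pop.theta.tolist(), omega=pop.omega.tolist(),
        sigma_plasma_prop=pop.sigma_plasma_prop, sigma_plasma_add=pop.sigma_plasma_add,
        sigma_urine_prop=pop.sigma_urine_prop, sigma_urine_add=pop.sigma_urine_add,
    )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_arm_designs(path) -> list:
    raw = json.loads(Path(path).read_text())
    return [StudyArmDesign.from_dict(a) for a in raw["arms"]]


@dataclass
class PipelineConfig:
    """Run configuration; the seed is stamped into every artifact."""

    seed: int = 0
    out_dir: Path = Path("results")
    prior_path: Path = None
    arms_path: Path = None
    sl_path: Path = None
    mcs_n: int = 5000
    bootstrap_n: int = 50
    extra: dict = field(default_factory=dict)

    def stamp(self) -> dict:
        payload = {k: str(v) for k, v in self.__dict__.items() if k != "extra"}
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
        return {"seed": self.seed, "config_hash": digest}


def write_report(payload: dict, path, config: PipelineConfig = None) -> None:
    """Write a JSON report stamped with seed and config hash."""
    if config is not None:
        payload = {**payload, **config.stamp()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)
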