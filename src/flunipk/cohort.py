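"""Synthetic multi-country cohort generation, LOQ censoring and sampling scenarios.

Stands in for the unreleased 65-horse multi-country dataset: each study arm
defines a dose (mg/kg or mg/horse), regimen, per-country LOQs, covariate
ranges and sampling schedules; horses are drawn from the log-normal
population distribution and observed through the combined
proportional+additive residual-error model.  The generating ("true")
parameters of every horse are retained for recovery experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .model import (
    DosingRegimen,
    PopulationParams,
    URINE_EQUILIBRIUM_TIME,
    apply_residual_error,
    plasma_concentration,
    sample_individual,
)

logger = logging.getLogger(__name__)

DATASET_COLUMNS = [
    "ID", "ARM", "TIME", "EVID", "AMT", "MATRIX", "DV", "LOQ", "BELOW_LOQ",
    "AGE", "BW", "SEX", "BREED", "COUNTRY",
]

REGIMENS = {
    "single": (1, 24.0),
    "q24hx5": (5, 24.0),
    "q12hx5": (10, 12.0),
}


@dataclass(frozen=True)
class StudyArmDesign:
    """One study arm: dose, regimen, assay LOQs, covariates and schedules.

    ``dose`` is interpreted per ``dose_unit``: "mg/kg" (body-weight scaled)
    or "mg/horse" (converted to ng/kg via each horse's drawn body weight).
    Schedules are hours after the LAST dose.
    """

    label: str
    country: str
    n_horses: int
    dose: float
    dose_unit: str
    regimen: str
    plasma_loq: float
    urine_loq: float
    age_range: tuple
    bw_range: tuple
    sexes: tuple
    breed: str
    plasma_schedule: tuple
    urine_schedule: tuple

    def __post_init__(self) -> None:
        if self.n_horses < 1:
            raise ValueError("n_horses must be >= 1")
        if self.plasma_loq <= 0 or self.urine_loq <= 0:
            raise ValueError("LOQs must be positive")
        for sched in (self.plasma_schedule, self.urine_schedule):
            if np.any(np.diff(sched) <= 0):
                raise ValueError("sampling schedules must be strictly increasing")
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}; one of {sorted(REGIMENS)}")
        if self.dose_unit not in ("mg/kg", "mg/horse"):
            raise ValueError(f"unknown dose unit {self.dose_unit!r}")

    def regimen_for(self, bw_kg: float) -> DosingRegimen:
        mg_per_kg = self.dose if self.dose_unit == "mg/kg" else self.dose / bw_kg
        n_doses, interval = REGIMENS[self.regimen]
        return DosingRegimen.repeated(mg_per_kg, interval, n_doses)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyArmDesign":
        return cls(
            label=raw["label"], country=raw["country"], n_horses=raw["n_horses"],
            dose=raw["dose"], dose_unit=raw["dose_unit"], regimen=raw["regimen"],
            plasma_loq=raw["plasma_loq"], urine_loq=raw["urine_loq"],
            age_range=tuple(raw["age_range"]), bw_range=tuple(raw["bw_range"]),
            sexes=tuple(raw["sexes"]), breed=raw["breed"],
            plasma_schedule=tuple(raw["plasma_schedule"]),
            urine_schedule=tuple(raw["urine_schedule"]),
        )


def load_published_arms() -> list:
    """The six study-arm designs of the multi-country dataset (packaged JSON)."""
    with resources.files("flunipk.data").joinpath("study_arms.json").open() as fh:
        raw = json.load(fh)
    return [StudyArmDesign.from_dict(a) for a in raw["arms"]]


@dataclass
class ConcentrationDataset:
    """Longitudinal dosing + observation records with per-horse ground truth.

    ``records`` is a DataFrame in a NONMEM-style dialect (EVID 1 = dose with
    AMT in ng/kg, EVID 0 = observation with DV/LOQ in ng/mL).  For synthetic
    data ``truths`` maps horse ID to its generating parameters.
    """

    records: pd.DataFrame
    truths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.records["TIME"] < 0).any():
            raise ValueError("negative times in dataset")
        for hid, grp in self.records.groupby("ID"):
            if not (grp["EVID"] == 1).any():
                raise ValueError(f"horse {hid} has no dose record")

    @property
    def horse_ids(self) -> list:
        return list(dict.fromkeys(self.records["ID"]))

    def observations(self, horse_id=None) -> pd.DataFrame:
        obs = self.records[self.records["EVID"] == 0]
        if horse_id is not None:
            obs = obs[obs["ID"] == horse_id]
        return obs

    def regimen_for(self, horse_id) -> DosingRegimen:
        doses = self.records[(self.records["ID"] == horse_id) & (self.records["EVID"] == 1)]
        amounts = doses["AMT"].to_numpy(dtype=float)
        if not np.allclose(amounts, amounts[0]):
            raise ValueError(f"horse {horse_id}: unequal dose amounts are not supported")
        return DosingRegimen(float(amounts[0]), tuple(doses["TIME"].to_numpy(dtype=float)))

    def covariates(self) -> pd.DataFrame:
        """One row per horse: AGE, BW, SEX, BREED, COUNTRY, ARM."""
        first = self.records.groupby("ID", sort=False).first()
        return first[["AGE", "BW", "SEX", "BREED", "COUNTRY", "ARM"]]

    def fit_mask(self) -> pd.Series:
        """Observation rows usable in a likelihood: not below-LOQ-flagged and,
        for urine, at or after the pseudo-equilibrium time."""
        r = self.records
        return (
            (r["EVID"] == 0)
            & ~r["BELOW_LOQ"].astype(bool)
            & ((r["MATRIX"] == "plasma") | (r["TIME"] >= URINE_EQUILIBRIUM_TIME))
        )

    def subset(self, row_mask) -> "ConcentrationDataset":
        keep = self.records[row_mask | (self.records["EVID"] == 1)].reset_index(drop=True)
        ids = set(keep["ID"])
        return ConcentrationDataset(keep, {k: v for k, v in self.truths.items() if k in ids})

    def copy(self) -> "ConcentrationDataset":
        return ConcentrationDataset(self.records.copy(), dict(self.truths))


@dataclass(frozen=True)
class LoqExclusionReport:
    """Per-matrix below-LOQ accounting and the action taken."""

    n_total: dict
    n_below_loq: dict
    fraction: dict
    action: dict


def generate_cohort(designs, pop: PopulationParams, seed) -> ConcentrationDataset:
    """Simulate a cohort: one horse per ID with parameters drawn from ``pop``,
    covariates drawn uniformly from the arm ranges, observations generated at
    the arm schedules through the residual-error model, and LOQ flags set.
    """
    if not designs:
        raise ValueError("empty design list")
    rng = np.random.default_rng(seed)
    rows = []
    truths = {}
    hid = 0
    for design in designs:
        n_doses, interval = REGIMENS[design.regimen]
        last_dose_time = interval * (n_doses - 1)
        for _ in range(design.n_horses):
            hid += 1
            params = sample_individual(pop, rng)
            truths[hid] = params
            age = round(float(rng.uniform(*design.age_range)), 1)
            bw = round(float(rng.uniform(*design.bw_range)), 1)
            sex = design.sexes[rng.integers(len(design.sexes))]
            regimen = design.regimen_for(bw)
            cov = dict(AGE=age, BW=bw, SEX=sex,
                       BREED=design.breed, COUNTRY=design.country)
            for td in regimen.dose_times:
                rows.append(dict(ID=hid, ARM=design.label, TIME=td, EVID=1,
                                 AMT=regimen.dose_amount, MATRIX="", DV=np.nan,
                                 LOQ=np.nan, BELOW_LOQ=False, **cov))
            for matrix, schedule, loq in (
                ("plasma", design.plasma_schedule, design.plasma_loq),
                ("urine", design.urine_schedule, design.urine_loq),
            ):
                times = last_dose_time + np.asarray(schedule, dtype=float)
                pred = plasma_concentration(params, regimen, times)
                if matrix == "urine":
                    pred = params.Rss * pred
                obs = apply_residual_error(pred, matrix, pop, rng)
                for t, dv in zip(times, obs):
                    rows.append(dict(ID=hid, ARM=design.label, TIME=float(t), EVID=0,
                                     AMT=np.nan, MATRIX=matrix, DV=float(dv), LOQ=loq,
                                     BELOW_LOQ=bool(dv < loq), **cov))
    records = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    records = records.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                                  kind="stable").reset_index(drop=True)
    return ConcentrationDataset(records, truths)


def censor_loq(data: ConcentrationDataset, threshold: float = 0.05):
    """Apply the below-LOQ rule: per matrix, drop below-LOQ observations when
    they make up less than ``threshold`` of that matrix's observations;
    otherwise retain them flagged (with a warning) since the exclusion rule
    only covers the sparse-censoring case.
    """
    obs = data.observations()
    n_total, n_below, fraction, action = {}, {}, {}, {}
    drop_index = []
    for matrix, grp in obs.groupby("MATRIX"):
        below = grp["BELOW_LOQ"].astype(bool)
        n_total[matrix] = int(len(grp))
        n_below[matrix] = int(below.sum())
        fraction[matrix] = n_below[matrix] / n_total[matrix] if n_total[matrix] else 0.0
        if n_below[matrix] == 0:
            action[matrix] = "none"
        elif fraction[matrix] < threshold:
            action[matrix] = "excluded"
            drop_index.extend(grp.index[below])
        else:
            action[matrix] = "retained-flagged (>=5%)"
            logger.warning(
                "%s: %.1f%% of observations below LOQ; retained with flags",
                matrix, 100 * fraction[matrix],
            )
    records = data.records.drop(index=drop_index).reset_index(drop=True)
    report = LoqExclusionReport(n_total, n_below, fraction, action)
    return ConcentrationDataset(records, dict(data.truths)), report


RICH_PLASMA_TIMES = (9.0, 24.0, 48.0)
RICH_URINE_TIME = 48.0
SPARSE_PLASMA_TIME = 24.0


def scenario_sampling(data: ConcentrationDataset, scenario: str,
                      tolerance: float = 0.5, rich_plasma_times=RICH_PLASMA_TIMES,
                      rich_urine_time=RICH_URINE_TIME) -> ConcentrationDataset:
    """Thin a dataset to a clinical sampling scenario.

    ``rich``: plasma at 9, 24 and 48 h plus urine at 48 h after the last
    dose; ``sparse``: a single plasma sample 24 h after the last dose.
    Horses lacking an observation within ``tolerance`` h of a required time
    are excluded (logged).  ``rich_plasma_times`` may be overridden, e.g. to
    compare a 72 h third sample against the 48 h default.
    """
    if scenario == "rich":
        wanted = [("plasma", t) for t in rich_plasma_times] + [("urine", rich_urine_time)]
    elif scenario == "sparse":
        wanted = [("plasma", SPARSE_PLASMA_TIME)]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected 'rich' or 'sparse'")

    keep_idx = []
    kept_horses = []
    for hid in data.horse_ids:
        last_dose = data.regimen_for(hid).last_dose_time
        obs = data.observations(hid)
        horse_rows = []
        ok = True
        for matrix, rel_t in wanted:
            cand = obs[obs["MATRIX"] == matrix]
            if cand.empty:
                ok = False
                break
            dt = (cand["TIME"] - (last_dose + rel_t)).abs()
            if dt.min() > tolerance:
                ok = False
                break
            horse_rows.append(dt.idxmin())
        if ok:
            keep_idx.extend(horse_rows)
            kept_horses.append(hid)
        else:
            logger.warning("horse %s excluded from %s scenario: required time missing", hid, scenario)
    r = data.records
    mask = r.index.isin(keep_idx) | ((r["EVID"] == 1) & r["ID"].isin(kept_horses))
    keep = r[mask].reset_index(drop=True)
    return ConcentrationDataset(keep, {k: v for k, v in data.truths.items() if k in kept_horses})
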