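"""Regulatory concentration thresholds: EPC, IPC and IUC, plus screening-limit scenarios.

The effective plasma concentration (EPC) follows the dose-rate/clearance
argument: EPC = dose per 24 h / clearance per 24 h.  Dividing by an
uncertainty factor (default 500) yields the irrelevant plasma concentration
(IPC); multiplying the IPC by the typical urine-to-plasma ratio tvRss yields
the irrelevant urine concentration (IUC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .model import PopulationParams

DEFAULT_UNCERTAINTY_FACTOR = 500.0


@dataclass(frozen=True)
class ScreeningLimitPair:
    """A plasma/urine screening-limit pair (ng/mL)."""

    plasma_sl: float
    urine_sl: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.plasma_sl <= 0 or self.urine_sl <= 0:
            raise ValueError("screening limits must be positive")

    @property
    def operational_rss(self) -> float:
        return self.urine_sl / self.plasma_sl


@dataclass(frozen=True)
class RegulatoryLimits:
    """EPC/IPC/IUC (ng/mL) with the inputs they were derived from."""

    EPC: float
    IPC: float
    IUC: float
    uncertainty_factor: float
    dose_per_24h: float
    clearance_per_24h: float
    tvRss: float


def load_screening_limits() -> list:
    """The packaged screening-limit scenario set (IFHA, candidates, HISA, RMTC)."""
    with resources.files("flunipk.data").joinpath("screening_limits.json").open() as fh:
        raw = json.load(fh)
    return [ScreeningLimitPair(p["plasma_sl"], p["urine_sl"], p["label"]) for p in raw["pairs"]]


def compute_epc(tv_cl: float, dose_per_24h: float) -> float:
    """EPC = dose per 24 h (ng/kg) / clearance per 24 h (tvCl * 24, mL/kg)."""
    return dose_per_24h / (tv_cl * 24.0)


def compute_ipc(epc: float, uncertainty_factor: float = DEFAULT_UNCERTAINTY_FACTOR) -> float:
    if uncertainty_factor <= 0:
        raise ValueError("uncertainty factor must be positive")
    return epc / uncertainty_factor


def compute_iuc(ipc: float, tv_rss: float) -> float:
    return ipc * tv_rss


def derive_limits(pop: PopulationParams, dose_mg_per_kg_per_24h: float = 1.1,
                  uncertainty_factor: float = DEFAULT_UNCERTAINTY_FACTOR) -> RegulatoryLimits:
    """Full EPC -> IPC -> IUC chain from a population model's typical values."""
    names = list(pop.parameter_names)
    tv_cl = float(pop.theta[names.index("Cl")])
    tv_rss = float(pop.theta[names.index("Rss")])
    dose = dose_mg_per_kg_per_24h * 1e6  # ng/kg per 24 h
    epc = compute_epc(tv_cl, dose)
    ipc = compute_ipc(epc, uncertainty_factor)
    return RegulatoryLimits(
        EPC=epc, IPC=ipc, IUC=compute_iuc(ipc, tv_rss),
        uncertainty_factor=uncertainty_factor, dose_per_24h=dose,
        clearance_per_24h=tv_cl * 24.0, tvRss=tv_rss,
    )


def candidate_screening_limits(limits: RegulatoryLimits) -> ScreeningLimitPair:
    """Round IPC/IUC to whole ng/mL as a proposed screening-limit pair.

    Rounding applies only at the proposal step, never inside computations.
    """
    return ScreeningLimitPair(
        plasma_sl=float(np.round(limits.IPC)),
        urine_sl=float(np.round(limits.IUC)),
        label="candidate",
    )


def bootstrap_limit_cis(theta_table, parameter_names, dose_mg_per_kg_per_24h: float = 1.1,
                        uncertainty_factor: float = DEFAULT_UNCERTAINTY_FACTOR) -> dict:
    """Propagate bootstrap replicates of theta through the EPC/IPC/IUC chain.

    ``theta_table``: (n_boot, n_params) array of bootstrap typical values.
    Returns percentile CIs per limit.
    """
    names = list(parameter_names)
    theta_table = np.asarray(theta_table, dtype=float)
    cl = theta_table[:, names.index("Cl")]
    rss = theta_table[:, names.index("Rss")]
    dose = dose_mg_per_kg_per_24h * 1e6
    epc = dose / (cl * 24.0)
    ipc = epc / uncertainty_factor
    iuc = ipc * rss
    out = {}
    for name, vals in (("EPC", epc), ("IPC", ipc), ("IUC", iuc)):
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[name] = {"2.5%": float(lo), "97.5%": float(hi),
                     "se": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
    return out
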