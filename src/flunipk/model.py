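"""Three-compartment IV-bolus disposition model with a proportional urine channel.

The structural model is the standard mammillary three-compartment system
dosed as an IV bolus into the central compartment, parameterized in terms of
plasma clearance: volumes V1 (central), V2 (superficial peripheral), V3 (deep
peripheral) in mL/kg, plasma clearance Cl and intercompartmental clearances
Cl2, Cl3 in mL/kg/h.  The plasma concentration after a single bolus is the
tri-exponential

    C(t) = (Dose/V1) * (A e^{-alpha t} + B e^{-beta t} + G e^{-gamma t})

where alpha > beta > gamma are the negated roots of the characteristic cubic
of the micro-constant matrix and A + B + G = 1.  Multiple dosing is handled
by superposition.  Urine concentration is modeled as proportional to plasma,
C_u(t) = Rss * C_p(t), with Rss the pseudo-equilibrium urine-to-plasma ratio;
the proportional relation is only trusted 24 h or more after the first dose
(pseudo-distribution equilibrium).

Between-subject variability is log-normal: parameter_i = theta * exp(eta_i)
with eta ~ MVN(0, Omega) (full covariance).  Residual error is combined
proportional + additive per matrix: y = f*(1+eps1) + eps2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

PARAM_NAMES = ("V1", "V2", "V3", "Cl", "Cl2", "Cl3", "Rss")

#: urine records earlier than this (h after first dose) are outside
#: pseudo-distribution equilibrium and are flagged invalid for fitting.
URINE_EQUILIBRIUM_TIME = 24.0


class InvalidParameterError(ValueError):
    """A structural parameter violates its positivity constraint."""


class NumericDegeneracyError(RuntimeError):
    """The characteristic cubic failed to yield distinct positive rates."""


@dataclass(frozen=True)
class DispositionParams:
    """One horse's structural parameters.

    Volumes in mL/kg, clearances in mL/kg/h, Rss dimensionless.
    """

    V1: float
    V2: float
    V3: float
    Cl: float
    Cl2: float
    Cl3: float
    Rss: float

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "Cl", "Rss"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("Cl2", "Cl3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V1, self.V2, self.V3, self.Cl, self.Cl2, self.Cl3, self.Rss])

    @classmethod
    def from_array(cls, values) -> "DispositionParams":
        return cls(*(float(v) for v in values))


@dataclass(frozen=True)
class MacroDisposition:
    """Exponential rates (1/h, descending) and unit-bolus coefficients.

    ``rates`` and ``coefs`` have matching length 1-3: degenerate models
    (Cl2 and/or Cl3 zero) collapse analytically to fewer exponentials.
    Coefficients are fractions of C(0) = Dose/V1 and sum to 1.
    """

    rates: np.ndarray
    coefs: np.ndarray

    @property
    def alpha(self) -> float:
        return float(self.rates[0])

    @property
    def beta(self) -> float:
        return float(self.rates[1])

    @property
    def gamma(self) -> float:
        return float(self.rates[-1])

    @property
    def coefA(self) -> float:
        return float(self.coefs[0])

    @property
    def coefB(self) -> float:
        return float(self.coefs[1])

    @property
    def coefC(self) -> float:
        return float(self.coefs[-1])


@dataclass(frozen=True)
class SecondaryParams:
    """Derived parameters: half-lives (h), Vss (mL/kg), MRT (h)."""

    t_half_alpha: float
    t_half_beta: float
    t_half_gamma: float
    Vss: float
    MRT: float


@dataclass
class PopulationParams:
    """Typical values, between-subject covariance and residual sigmas.

    ``theta`` follows :data:`PARAM_NAMES` order; ``omega`` is the full 7x7
    covariance of log-scale random effects.  Residual SDs: proportional terms
    are dimensionless (CV fractions), additive terms in ng/mL.
    """

    theta: np.ndarray
    omega: np.ndarray
    sigma_plasma_prop: float
    sigma_plasma_add: float
    sigma_urine_prop: float
    sigma_urine_add: float
    parameter_names: tuple = PARAM_NAMES

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = len(self.theta)
        if self.omega.shape != (n, n):
            raise ValueError(f"omega must be {n}x{n}, got {self.omega.shape}")
        if not np.allclose(self.omega, self.omega.T, atol=1e-12):
            raise ValueError("omega must be symmetric")
        if np.any(self.theta <= 0):
            raise ValueError("all theta entries must be positive")
        for name in ("sigma_plasma_prop", "sigma_plasma_add", "sigma_urine_prop", "sigma_urine_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def typical_individual(self) -> DispositionParams:
        return DispositionParams.from_array(self.theta)

    def residual_sigmas(self, matrix: str) -> tuple:
        if matrix == "plasma":
            return self.sigma_plasma_prop, self.sigma_plasma_add
        if matrix == "urine":
            return self.sigma_urine_prop, self.sigma_urine_add
        raise ValueError(f"unknown matrix {matrix!r}; expected 'plasma' or 'urine'")

    def copy(self) -> "PopulationParams":
        return PopulationParams(
            self.theta.copy(), self.omega.copy(),
            self.sigma_plasma_prop, self.sigma_plasma_add,
            self.sigma_urine_prop, self.sigma_urine_add,
            self.parameter_names,
        )


@dataclass(frozen=True)
class DosingRegimen:
    """IV bolus dosing: amount per administration (ng/kg) at given times (h)."""

    dose_amount: float
    dose_times: tuple = (0.0,)

    def __post_init__(self) -> None:
        if not self.dose_amount > 0:
            raise InvalidParameterError("dose_amount must be positive")
        times = np.asarray(self.dose_times, dtype=float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise InvalidParameterError("dose_times must start at 0 and be strictly increasing")
        object.__setattr__(self, "dose_times", tuple(float(t) for t in times))

    @property
    def n_doses(self) -> int:
        return len(self.dose_times)

    @property
    def last_dose_time(self) -> float:
        return self.dose_times[-1]

    @classmethod
    def single(cls, dose_mg_per_kg: float = 1.1) -> "DosingRegimen":
        return cls(dose_mg_per_kg * 1e6, (0.0,))

    @classmethod
    def repeated(cls, dose_mg_per_kg: float, interval_h: float, n_doses: int) -> "DosingRegimen":
        return cls(dose_mg_per_kg * 1e6, tuple(interval_h * i for i in range(n_doses)))


def load_published_prior() -> PopulationParams:
    """The published typical values, full omega and residual sigmas (packaged JSON)."""
    with resources.files("flunipk.data").joinpath("priors_published.json").open() as fh:
        raw = json.load(fh)
    return PopulationParams(
        theta=np.array(raw["theta"]),
        omega=np.array(raw["omega"]),
        sigma_plasma_prop=raw["sigma_plasma_prop"],
        sigma_plasma_add=raw["sigma_plasma_add"],
        sigma_urine_prop=raw["sigma_urine_prop"],
        sigma_urine_add=raw["sigma_urine_add"],
    )


def micro_to_macro(params: DispositionParams) -> MacroDisposition:
    """Macro-constants (rates and unit-bolus coefficients) from micro-constants.

    Solves the characteristic cubic of the mammillary system.  When Cl2
    and/or Cl3 is zero the corresponding exponential is dropped analytically
    (two- or one-compartment collapse) instead of perturbing the input.
    """
    k10 = params.Cl / params.V1
    if params.Cl2 == 0.0 and params.Cl3 == 0.0:
        return MacroDisposition(np.array([k10]), np.array([1.0]))
    if params.Cl2 == 0.0 or params.Cl3 == 0.0:
        # two-compartment collapse with the single active peripheral compartment
        if params.Cl3 == 0.0:
            kin, kout = params.Cl2 / params.V1, params.Cl2 / params.V2
        else:
            kin, kout = params.Cl3 / params.V1, params.Cl3 / params.V3
        s = k10 + kin + kout
        disc = s * s - 4.0 * k10 * kout
        if disc < 0:
            raise NumericDegeneracyError(f"negative discriminant for {params}")
        root = np.sqrt(disc)
        alpha, beta = (s + root) / 2.0, (s - root) / 2.0
        coefA = (kout - alpha) / (beta - alpha)
        return MacroDisposition(np.array([alpha, beta]), np.array([coefA, 1.0 - coefA]))

    k12 = params.Cl2 / params.V1
    k21 = params.Cl2 / params.V2
    k13 = params.Cl3 / params.V1
    k31 = params.Cl3 / params.V3
    a2 = k10 + k12 + k13 + k21 + k31
    a1 = k10 * k21 + k10 * k31 + k12 * k31 + k13 * k21 + k21 * k31
    a0 = k10 * k21 * k31
    roots = np.roots([1.0, a2, a1, a0])
    if np.any(np.abs(roots.imag) > 1e-9 * np.abs(roots.real).max()):
        raise NumericDegeneracyError(f"complex cubic roots for {params}")
    rates = np.sort(-roots.real)[::-1]
    if np.any(rates <= 0):
        raise NumericDegeneracyError(f"non-positive disposition rate for {params}")
    coefs = np.empty(3)
    for i in range(3):
        others = np.delete(rates, i)
        coefs[i] = (k21 - rates[i]) * (k31 - rates[i]) / np.prod(others - rates[i])
    return MacroDisposition(rates, coefs)


def plasma_concentration(params: DispositionParams, regimen: DosingRegimen, t) -> np.ndarray | float:
    """Plasma concentration (ng/mL) at time(s) ``t`` (h since first dose).

    Multiple doses are superposed; times before the first dose return 0.
    """
    macro = micro_to_macro(params)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    c0 = regimen.dose_amount / params.V1
    out = np.zeros_like(t_arr)
    for td in regimen.dose_times:
        dt = t_arr - td
        active = dt >= 0
        if not np.any(active):
            continue
        out[active] += c0 * (macro.coefs[None, :] * np.exp(-macro.rates[None, :] * dt[active, None])).sum(axis=1)
    return out if np.ndim(t) else float(out[0])


def urine_concentration(params: DispositionParams, regimen: DosingRegimen, t):
    """Urine concentration Rss * C_plasma, with a pseudo-equilibrium validity flag.

    Returns ``(concentration, valid)``; ``valid`` is False before 24 h after
    the first dose, where the proportional urine model is not trusted.
    """
    conc = plasma_concentration(params, regimen, t)
    t_arr = np.asarray(t, dtype=float)
    valid = t_arr >= URINE_EQUILIBRIUM_TIME
    if np.ndim(t):
        return params.Rss * conc, valid
    return params.Rss * conc, bool(valid)


def secondary_parameters(params: DispositionParams) -> SecondaryParams:
    """Half-lives, steady-state volume and mean residence time."""
    macro = micro_to_macro(params)
    ln2 = np.log(2.0)
    halves = ln2 / macro.rates  # ascending since rates descend
    vss = params.V1 + params.V2 + params.V3
    return SecondaryParams(
        t_half_alpha=float(halves[0]),
        t_half_beta=float(halves[1]) if len(halves) > 1 else float("nan"),
        t_half_gamma=float(halves[-1]),
        Vss=vss,
        MRT=vss / params.Cl,
    )


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone by clipping eigenvalues at 0."""
    vals, vecs = np.linalg.eigh((matrix + matrix.T) / 2.0)
    if np.all(vals >= 0):
        return matrix
    logger.warning("omega not positive semidefinite (min eigenvalue %.3g); clipping", vals.min())
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def sample_etas(pop: PopulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n log-scale random-effect vectors eta ~ MVN(0, omega)."""
    omega = nearest_psd(pop.omega)
    vals, vecs = np.linalg.eigh(omega)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n, len(pop.theta)))
    return z @ factor.T


def individual_params(pop: PopulationParams, eta: np.ndarray) -> DispositionParams:
    """theta * exp(eta); eta = 0 recovers the typical horse exactly."""
    return DispositionParams.from_array(pop.theta * np.exp(np.asarray(eta, dtype=float)))


def sample_individual(pop: PopulationParams, rng: np.random.Generator) -> DispositionParams:
    """Draw one horse's parameters from the log-normal population distribution."""
    return individual_params(pop, sample_etas(pop, 1, rng)[0])


def apply_residual_error(pred, matrix: str, pop: PopulationParams, rng: np.random.Generator):
    """Observed = pred*(1+eps1) + eps2 with matrix-specific sigmas; clamped at 0."""
    sigma_prop, sigma_add = pop.residual_sigmas(matrix)
    pred_arr = np.atleast_1d(np.asarray(pred, dtype=float))
    if np.any(pred_arr < 0):
        raise ValueError("predicted concentrations must be non-negative")
    obs = pred_arr * (1.0 + sigma_prop * rng.standard_normal(pred_arr.shape))
    obs += sigma_add * rng.standard_normal(pred_arr.shape)
    n_neg = int(np.sum(obs < 0))
    if n_neg:
        logger.info("clamped %d negative simulated concentrations to 0", n_neg)
        obs = np.clip(obs, 0.0, None)
    return obs if np.ndim(pred) else float(obs[0])


def residual_variance(pred, matrix: str, pop: PopulationParams) -> np.ndarray:
    """Observation variance sigma_prop^2 * pred^2 + sigma_add^2 for the matrix."""
    sigma_prop, sigma_add = pop.residual_sigmas(matrix)
    pred_arr = np.asarray(pred, dtype=float)
    return (sigma_prop * pred_arr) ** 2 + sigma_add**2


def bsv_cv_percent(omega_sq) -> np.ndarray | float:
    """Convert a log-scale variance to between-subject CV%: 100*sqrt(exp(w2)-1)."""
    return 100.0 * np.sqrt(np.expm1(np.asarray(omega_sq, dtype=float)))
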