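"""Kinetic ODE model of upper E. coli glycolysis.

Four metabolites (G6P, FBP, PEP, PYR) connected by six reactions (PTS,
PFK, FBPase, FBA, PYK, PDH).  Michaelis-Menten and Hill rate laws are
decorated with power-law factors encoding three allosteric interactions:
PEP inhibition of PFK (exponent ``a1``), PEP activation of FBPase
(``a2``) and FBP feed-forward activation of PYK (``a3``).  An ensemble
of models is built by sampling kinetic constants log-uniformly,
calibrating every maximal rate so that the all-ones metabolite state is
a steady state carrying the measured glucose uptake flux, and keeping
only parameter sets whose steady state is linearly stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GLUCOSE_UPTAKE_RATE",
    "SPECIFIC_VOLUME",
    "glucose_uptake_flux",
    "MetaboliteState",
    "ModelParameters",
    "FeedbackStructure",
    "ReactionRates",
    "Trajectory",
    "InvalidStateError",
    "CalibrationError",
    "IntegrationError",
    "EnsembleExhaustedError",
    "reaction_rates",
    "mass_balance",
    "jacobian",
    "sample_parameter_set",
    "calibrate_vmax",
    "is_stable",
    "sample_stable_ensemble",
    "simulate_perturbation",
    "UNIT_STATE",
]

#: Glucose uptake rate, mmol per gram dry weight per hour.
GLUCOSE_UPTAKE_RATE = 8.0
#: Specific cell volume of E. coli, litre per gram dry weight.
SPECIFIC_VOLUME = 0.002

#: Stability threshold: all Jacobian eigenvalue real parts must lie below it.
STABILITY_THRESHOLD = -1e-5

METABOLITES = ("g6p", "fbp", "pep", "pyr")
REACTIONS = ("pts", "pfk", "fbpase", "fba", "pyk", "pdh")

#: Stoichiometric matrix of d(G6P,FBP,PEP,PYR)/dt in terms of
#: (PTS, PFK, FBPase, FBA, PYK, PDH).  Note the factor 2 on FBA in the
#: PEP balance: one FBP yields two triose units.
STOICHIOMETRY = np.array(
    [
        [1.0, -1.0, 1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0, -1.0, -1.0, 0.0, 0.0],
        [-1.0, 0.0, 0.0, 2.0, -1.0, 0.0],
        [1.0, 0.0, 0.0, 0.0, 1.0, -1.0],
    ]
)


def glucose_uptake_flux(
    uptake_rate: float = GLUCOSE_UPTAKE_RATE,
    specific_volume: float = SPECIFIC_VOLUME,
) -> float:
    """Intracellular glucose uptake flux in mmol l^-1 min^-1.

    Converts a specific uptake rate (mmol g^-1 h^-1) to a volumetric
    flux using the specific cell volume (l g^-1); the default values
    give 8 / 0.002 / 60 = 66.66... mmol l^-1 min^-1.
    """
    return uptake_rate / specific_volume / 60.0


class InvalidStateError(ValueError):
    """A metabolite concentration is zero or negative."""


class CalibrationError(ValueError):
    """Maximal rates cannot be calibrated (degenerate flux ratio)."""


class IntegrationError(RuntimeError):
    """ODE integration failed or left the positive orthant."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class EnsembleExhaustedError(RuntimeError):
    """Rejection sampling exceeded its cap without reaching the target."""


@dataclass(frozen=True)
class MetaboliteState:
    """Concentrations of the four state metabolites, mmol l^-1."""

    g6p: float
    fbp: float
    pep: float
    pyr: float

    def __post_init__(self):
        for name in METABOLITES:
            if not getattr(self, name) > 0:
                raise InvalidStateError(
                    f"{name.upper()} must be strictly positive, got {getattr(self, name)}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.g6p, self.fbp, self.pep, self.pyr])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "MetaboliteState":
        return cls(*map(float, x))


#: The calibration reference state: every metabolite at 1 mmol l^-1.
UNIT_STATE = MetaboliteState(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class FeedbackStructure:
    """Which of the three allosteric interactions are present.

    The 8 on/off combinations define the model variants screened in the
    ensemble experiment; switching a feedback off forces its power-law
    exponent to zero.
    """

    pfk_inhibition_active: bool = True
    fbpase_activation_active: bool = True
    pyk_activation_active: bool = True

    @property
    def label(self) -> str:
        bits = (
            "a1" if self.pfk_inhibition_active else "--",
            "a2" if self.fbpase_activation_active else "--",
            "a3" if self.pyk_activation_active else "--",
        )
        return "+".join(bits)

    @classmethod
    def all_structures(cls) -> list["FeedbackStructure"]:
        return [
            cls(bool(i), bool(j), bool(k))
            for i in (1, 0)
            for j in (1, 0)
            for k in (1, 0)
        ]


FULL_STRUCTURE = FeedbackStructure(True, True, True)
NO_FEEDBACK_STRUCTURE = FeedbackStructure(False, False, False)

#: Sampled parameter fields, in the order the RNG stream draws them.
SAMPLED_FIELDS = (
    "k1", "k2", "k3",
    "Km1", "Km2", "Km3", "Km4", "Km5",
    "n1", "n2", "n3",
    "a1", "a2", "a3",
    "flux_ratio",
)
VMAX_FIELDS = ("Vmax1", "Vmax2", "Vmax3", "Vmax4", "Vmax5", "Vmax6")


@dataclass(frozen=True)
class ModelParameters:
    """One glycolysis model instance.

    Binding constants ``k1..k3`` (PTS, dimensionless) and ``Km1..Km5``
    (mmol l^-1), Hill coefficients ``n1..n3``, power-law exponents
    ``a1..a3`` and the sampled PFK/FBPase cycle flux ratio are drawn by
    :func:`sample_parameter_set`; the maximal rates ``Vmax1..Vmax6``
    (mmol l^-1 min^-1) are ``None`` until :func:`calibrate_vmax` pins
    the unit state to a steady state.
    """

    k1: float
    k2: float
    k3: float
    Km1: float
    Km2: float
    Km3: float
    Km4: float
    Km5: float
    n1: float
    n2: float
    n3: float
    a1: float
    a2: float
    a3: float
    flux_ratio: float
    Vmax1: float | None = None
    Vmax2: float | None = None
    Vmax3: float | None = None
    Vmax4: float | None = None
    Vmax5: float | None = None
    Vmax6: float | None = None

    @property
    def calibrated(self) -> bool:
        return all(getattr(self, f) is not None for f in VMAX_FIELDS)

    @property
    def structure(self) -> FeedbackStructure:
        return FeedbackStructure(self.a1 != 0, self.a2 != 0, self.a3 != 0)

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in SAMPLED_FIELDS + VMAX_FIELDS}


@dataclass(frozen=True)
class ReactionRates:
    """The six reaction fluxes, mmol l^-1 min^-1."""

    pts: float
    pfk: float
    fbpase: float
    fba: float
    pyk: float
    pdh: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pts, self.pfk, self.fbpase, self.fba, self.pyk, self.pdh])


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course on a uniform output grid."""

    times: np.ndarray          # min
    states: np.ndarray         # shape (len(times), 4): G6P, FBP, PEP, PYR
    perturbation_time: float   # min
    perturbation_factor: float

    @property
    def pyruvate(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times,
             "g6p": self.states[:, 0], "fbp": self.states[:, 1],
             "pep": self.states[:, 2], "pyr": self.states[:, 3]}
        )


def _require_calibrated(params: ModelParameters) -> None:
    if not params.calibrated:
        raise CalibrationError("parameters lack Vmax values; run calibrate_vmax first")


def _rates_raw(g6p, fbp, pep, pyr, p: ModelParameters):
    """Six rates from scalar concentrations; no validation."""
    ratio = pyr / pep
    pts = p.Vmax1 / (p.k1 * ratio + p.k2 + p.k3 * ratio + 1.0)
    pfk = p.Vmax2 / (1.0 + p.Km1 / g6p) ** p.n1 * pep ** (-p.a1)
    fbpase = p.Vmax3 * fbp / (fbp + p.Km2) * pep ** p.a2
    fba = p.Vmax4 * fbp / (fbp + p.Km3)
    pyk = p.Vmax5 / (1.0 + p.Km4 / pep) ** p.n2 * fbp ** p.a3
    pdh = p.Vmax6 / (1.0 + p.Km5 / pyr) ** p.n3
    return pts, pfk, fbpase, fba, pyk, pdh


def reaction_rates(state: MetaboliteState, params: ModelParameters) -> ReactionRates:
    """Evaluate the six rate laws at a metabolite state."""
    _require_calibrated(params)
    return ReactionRates(*_rates_raw(state.g6p, state.fbp, state.pep, state.pyr, params))


def mass_balance(state: MetaboliteState, params: ModelParameters) -> np.ndarray:
    """Time derivatives d(G6P, FBP, PEP, PYR)/dt, mmol l^-1 min^-1."""
    r = reaction_rates(state, params)
    return STOICHIOMETRY @ r.as_array()


def jacobian(state: MetaboliteState, params: ModelParameters) -> np.ndarray:
    """Analytic 4x4 Jacobian of :func:`mass_balance` w.r.t. the metabolites."""
    _require_calibrated(params)
    p = params
    g6p, fbp, pep, pyr = state.g6p, state.fbp, state.pep, state.pyr
    pts, pfk, fbpase, fba, pyk, pdh = _rates_raw(g6p, fbp, pep, pyr, p)

    # Per-reaction partial derivatives; each rate is a product of factors
    # so logarithmic derivatives keep the algebra compact.
    denom = (p.k1 + p.k3) * (pyr / pep) + p.k2 + 1.0
    dpts_du = -p.Vmax1 * (p.k1 + p.k3) / denom**2   # u = pyr/pep
    dpts_dpyr = dpts_du / pep
    dpts_dpep = dpts_du * (-pyr / pep**2)

    dpfk_dg6p = pfk * p.n1 * p.Km1 / (g6p * (g6p + p.Km1))
    dpfk_dpep = -p.a1 * pfk / pep

    dfbpase_dfbp = fbpase * p.Km2 / (fbp * (fbp + p.Km2))
    dfbpase_dpep = p.a2 * fbpase / pep

    dfba_dfbp = fba * p.Km3 / (fbp * (fbp + p.Km3))

    dpyk_dpep = pyk * p.n2 * p.Km4 / (pep * (pep + p.Km4))
    dpyk_dfbp = p.a3 * pyk / fbp

    dpdh_dpyr = pdh * p.n3 * p.Km5 / (pyr * (pyr + p.Km5))

    # rows: reactions; columns: g6p, fbp, pep, pyr
    drates = np.array(
        [
            [0.0, 0.0, dpts_dpep, dpts_dpyr],
            [dpfk_dg6p, 0.0, dpfk_dpep, 0.0],
            [0.0, dfbpase_dfbp, dfbpase_dpep, 0.0],
            [0.0, dfba_dfbp, 0.0, 0.0],
            [0.0, dpyk_dfbp, dpyk_dpep, 0.0],
            [0.0, 0.0, 0.0, dpdh_dpyr],
        ]
    )
    return STOICHIOMETRY @ drates


def sample_parameter_set(
    structure: FeedbackStructure,
    rng: np.random.Generator | int,
) -> ModelParameters:
    """Draw one uncalibrated parameter set.

    Binding constants are log-uniform on [0.1, 10]; Hill coefficients
    and active power-law exponents log-uniform on [1, 4]; inactive
    exponents are 0; the flux ratio is log-uniform on [0.01, 0.99].
    All values are drawn regardless of the structure (inactive exponents
    are zeroed afterwards) so that paired-seed comparisons across
    structures share common random numbers.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def loguniform(lo, hi, size=None):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size))

    k = loguniform(0.1, 10.0, 3)
    Km = loguniform(0.1, 10.0, 5)
    n = loguniform(1.0, 4.0, 3)
    a = loguniform(1.0, 4.0, 3)
    flux_ratio = float(loguniform(0.01, 0.99))
    active = (
        structure.pfk_inhibition_active,
        structure.fbpase_activation_active,
        structure.pyk_activation_active,
    )
    a = [float(ai) if on else 0.0 for ai, on in zip(a, active)]
    return ModelParameters(
        k1=float(k[0]), k2=float(k[1]), k3=float(k[2]),
        Km1=float(Km[0]), Km2=float(Km[1]), Km3=float(Km[2]),
        Km4=float(Km[3]), Km5=float(Km[4]),
        n1=float(n[0]), n2=float(n[1]), n3=float(n[2]),
        a1=a[0], a2=a[1], a3=a[2],
        flux_ratio=flux_ratio,
    )


def calibrate_vmax(
    params: ModelParameters,
    uptake_flux: float | None = None,
) -> ModelParameters:
    """Set the six maximal rates so the unit state is a steady state.

    The net flux through every balance is pinned to the glucose uptake
    flux F_glc: PTS, FBA and PYK carry F_glc, PDH carries 2 F_glc, and
    the PFK/FBPase cycle carries F_FBPase = rho/(1-rho) F_glc and
    F_PFK = F_FBPase + F_glc where rho is the sampled flux ratio
    (FBPase flux as a fraction of PFK flux).  Each Vmax is then the
    target flux divided by the rest of its rate law evaluated at the
    all-ones state, where every power-law factor is 1.
    """
    if uptake_flux is None:
        uptake_flux = glucose_uptake_flux()
    rho = params.flux_ratio
    if not 0.0 < rho < 1.0:
        raise CalibrationError(
            f"flux_ratio must lie strictly inside (0, 1), got {rho}; "
            "a ratio of 1 makes the PFK/FBPase cycle flux diverge"
        )
    f_glc = uptake_flux
    f_fbpase = rho / (1.0 - rho) * f_glc
    f_pfk = f_fbpase + f_glc
    p = params
    return replace(
        params,
        Vmax1=f_glc * (p.k1 + p.k2 + p.k3 + 1.0),
        Vmax2=f_pfk * (1.0 + p.Km1) ** p.n1,
        Vmax3=f_fbpase * (1.0 + p.Km2),
        Vmax4=f_glc * (1.0 + p.Km3),
        Vmax5=f_glc * (1.0 + p.Km4) ** p.n2,
        Vmax6=2.0 * f_glc * (1.0 + p.Km5) ** p.n3,
    )


def is_stable(params: ModelParameters, threshold: float = STABILITY_THRESHOLD) -> bool:
    """Linear stability of the calibrated unit steady state.

    True iff every eigenvalue of the Jacobian at the all-ones state has
    real part below the threshold (default -1e-5; marginal modes with
    real part in (-1e-5, 0) count as unstable).
    """
    eig = np.linalg.eigvals(jacobian(UNIT_STATE, params))
    return bool(np.all(eig.real < threshold))


def sample_stable_ensemble(
    structure: FeedbackStructure,
    n: int,
    rng: np.random.Generator | int,
    max_rejections: int = 10_000_000,
) -> tuple[list[ModelParameters], int]:
    """Rejection-sample ``n`` calibrated, stable parameter sets.

    Unstable draws are discarded and redrawn.  Returns the accepted sets
    and the number of rejected draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    accepted: list[ModelParameters] = []
    rejected = 0
    while len(accepted) < n:
        candidate = calibrate_vmax(sample_parameter_set(structure, rng))
        if is_stable(candidate):
            accepted.append(candidate)
        else:
            rejected += 1
            if rejected > max_rejections:
                raise EnsembleExhaustedError(
                    f"{rejected} rejections without reaching {n} stable sets"
                )
    return accepted, rejected


def _rhs_factory(p: ModelParameters):
    """Closure evaluating the mass balances on plain floats (solver hot path)."""
    k1, k2, k3 = p.k1, p.k2, p.k3
    Km1, Km2, Km3, Km4, Km5 = p.Km1, p.Km2, p.Km3, p.Km4, p.Km5
    n1, n2, n3 = p.n1, p.n2, p.n3
    a1, a2, a3 = p.a1, p.a2, p.a3
    V1, V2, V3, V4, V5, V6 = p.Vmax1, p.Vmax2, p.Vmax3, p.Vmax4, p.Vmax5, p.Vmax6

    def rhs(t, y):
        g6p, fbp, pep, pyr = y
        if g6p <= 0.0 or fbp <= 0.0 or pep <= 0.0 or pyr <= 0.0:
            raise _NonPositive(t)
        u = pyr / pep
        pts = V1 / (k1 * u + k2 + k3 * u + 1.0)
        pfk = V2 / (1.0 + Km1 / g6p) ** n1 * pep ** (-a1)
        fbpase = V3 * fbp / (fbp + Km2) * pep**a2
        fba = V4 * fbp / (fbp + Km3)
        pyk = V5 / (1.0 + Km4 / pep) ** n2 * fbp**a3
        pdh = V6 / (1.0 + Km5 / pyr) ** n3
        return (
            pts + fbpase - pfk,
            pfk - fbpase - fba,
            2.0 * fba - pyk - pts,
            pts + pyk - pdh,
        )

    return rhs


class _NonPositive(Exception):
    def __init__(self, t):
        self.t = t


def simulate_perturbation(
    params: ModelParameters,
    factor: float = 0.95,
    t_perturb: float = 50.0,
    t_end: float = 250.0,
    dt_out: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_state: MetaboliteState = UNIT_STATE,
) -> Trajectory:
    """Integrate the model through a step change in glucose uptake.

    The system starts at the (steady) initial state; at ``t_perturb``
    the PTS maximal rate Vmax1 is multiplied by ``factor`` permanently
    and the integration continues to ``t_end``.  Output is sampled on a
    uniform grid of step ``dt_out`` using the solver's dense output.
    """
    _require_calibrated(params)
    if not 0.0 < t_perturb < t_end:
        raise ValueError("require 0 < t_perturb < t_end")

    times = np.round(np.arange(0.0, t_end + dt_out / 2, dt_out), 10)
    t_pre = times[times <= t_perturb]
    t_post = times[times > t_perturb]

    def integrate(p, t0, t1, y0, t_eval):
        try:
            sol = solve_ivp(
                _rhs_factory(p), (t0, t1), y0,
                method="LSODA", rtol=rtol, atol=atol,
                t_eval=t_eval, dense_output=False,
            )
        except _NonPositive as exc:
            raise IntegrationError(
                f"metabolite became non-positive near t = {exc.t:.3f} min", exc.t
            ) from None
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}", t1)
        return sol

    y0 = initial_state.as_array()
    pre_eval = t_pre if t_pre[-1] == t_perturb else np.append(t_pre, t_perturb)
    sol_pre = integrate(params, 0.0, t_perturb, y0, pre_eval)
    y_perturb = sol_pre.y[:, -1]
    states_pre = sol_pre.y[:, : len(t_pre)].T

    perturbed = replace(params, Vmax1=params.Vmax1 * factor)
    sol_post = integrate(perturbed, t_perturb, t_end, y_perturb, t_post)
    states = np.vstack([states_pre, sol_post.y.T])

    if np.any(states <= 0):
        bad = np.argwhere(states <= 0)[0]
        raise IntegrationError(
            f"metabolite became non-positive at t = {times[bad[0]]:.3f} min",
            float(times[bad[0]]),
        )
    return Trajectory(
        times=times,
        states=states,
        perturbation_time=t_perturb,
        perturbation_factor=factor,
    )
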