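"""Bundled example models and protocols.

Provides the IVGTT sampling protocol (0.33 g/kg glucose bolus, 32 samples
over 240 min), closed-form one- and two-compartment IV-bolus PK models with
log-normal inter-individual variability, a paired truth/misspecification
scenario for exercising the diagnostics, and the two-compartment glucose
minimal sub-model ODE with net hepatic glucose balance.

Scenario parameter values are implementation choices picked to be
physiologically plausible for glucose-scale kinetics and to make the
one-compartment misspecification clearly detectable at 50-100 subjects; they
are not estimates from any study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .engine import simulate_dataset
from .models import Dataset, Design, Dose, ErrorModel, NLMEModel

__all__ = [
    "get_model",
    "IVGTT_SAMPLE_TIMES",
    "IVGTTProtocol",
    "make_ivgtt_protocol",
    "one_compartment_model",
    "two_compartment_model",
    "PKScenario",
    "make_pk_scenario",
    "MinimalGlucoseParams",
    "minimal_glucose_rhs",
    "simulate_minimal_glucose",
    "biexponential_insulin_action",
]

def get_model(name: str, **kwargs) -> NLMEModel:
    """Look up a bundled model by name ("one_compartment"/"pk1" or
    "two_compartment"/"pk2"); keyword arguments override the defaults."""
    registry = {
        "one_compartment": one_compartment_model,
        "pk1": one_compartment_model,
        "two_compartment": two_compartment_model,
        "pk2": two_compartment_model,
    }
    try:
        factory = registry[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(set(registry))}")
    return factory(**kwargs)


#: standard IVGTT blood-sampling schedule (minutes after the glucose bolus)
IVGTT_SAMPLE_TIMES = (
    0, 2, 3, 4, 5, 6, 8, 10, 12, 15, 18, 20, 22, 24, 26, 28, 30, 35, 40,
    45, 50, 55, 60, 70, 80, 100, 120, 140, 160, 180, 210, 240,
)


@dataclass(frozen=True)
class IVGTTProtocol:
    """Standard intravenous glucose tolerance test design."""

    dose_g_per_kg: float = 0.33
    body_weight_kg: float = 70.0
    sample_times: tuple = IVGTT_SAMPLE_TIMES

    def __post_init__(self):
        times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def dose_mg(self) -> float:
        return self.dose_g_per_kg * self.body_weight_kg * 1000.0

    def to_design(self, dv_index: int = 0) -> Design:
        times = np.asarray(self.sample_times, dtype=float)
        return Design(
            times=times,
            dvid=np.full(times.size, dv_index),
            doses=(Dose(time=0.0, amt=self.dose_mg),),
        )


def make_ivgtt_protocol(**kwargs) -> IVGTTProtocol:
    """The printed IVGTT protocol: 0.33 g/kg bolus, 32 samples to 240 min."""
    return IVGTTProtocol(**kwargs)


# ---------------------------------------------------------------------------
# closed-form PK models
# ---------------------------------------------------------------------------

def _bolus_amount(design: Design) -> float:
    if not design.doses:
        raise ValueError("design has no dose event")
    return sum(d.amt for d in design.doses)


def one_compartment_model(
    cl: float = 0.3,
    v: float = 12.0,
    base: float = 900.0,
    omega: tuple[float, float, float] = (0.09, 0.04, 0.01),
    prop_var: float = 0.01,
    dv_label: str = "glucose",
) -> NLMEModel:
    """One-compartment IV bolus above a basal level.

    C(t) = B + D/V * exp(-CL/V * t), mimicking glucose returning to its basal
    concentration after an IVGTT bolus.  CL (L/min), V (L) and the basal
    level B (mg/L) carry log-normal inter-individual variability with
    variances ``omega``; residual error is proportional.
    """

    def pred(theta, eta, design):
        eta = np.asarray(eta, dtype=float)
        dose = _bolus_amount(design)
        cl_i = theta[0] * np.exp(eta[..., 0])
        v_i = theta[1] * np.exp(eta[..., 1])
        b_i = theta[2] * np.exp(eta[..., 2])
        t = design.times
        return b_i[..., None] + (dose / v_i)[..., None] * np.exp(
            -(cl_i / v_i)[..., None] * t
        )

    return NLMEModel(
        name="pk1",
        pred=pred,
        theta=np.array([cl, v, base]),
        omega=np.diag(omega),
        errors=(ErrorModel(prop_var=prop_var),),
        dv_labels=(dv_label,),
        theta_names=("CL", "V", "BASE"),
        eta_names=("eta_CL", "eta_V", "eta_BASE"),
    )


def two_compartment_model(
    cl: float = 0.3,
    v1: float = 12.0,
    q: float = 0.3,
    v2: float = 8.0,
    base: float = 900.0,
    omega: tuple[float, float, float] = (0.09, 0.04, 0.01),
    prop_var: float = 0.01,
    dv_label: str = "glucose",
) -> NLMEModel:
    """Two-compartment IV bolus (biexponential) above a basal level.

    IIV on CL, V1 and the basal level; distribution half-life about 9 min,
    terminal half-life about 55 min with the default rates.
    """

    def pred(theta, eta, design):
        eta = np.asarray(eta, dtype=float)
        dose = _bolus_amount(design)
        cl_i = theta[0] * np.exp(eta[..., 0])
        v1_i = theta[1] * np.exp(eta[..., 1])
        base_i = theta[4] * np.exp(eta[..., 2])
        q_i, v2_i = theta[2], theta[3]
        k10 = cl_i / v1_i
        k12 = q_i / v1_i
        k21 = q_i / v2_i
        s = k10 + k12 + k21
        disc = np.sqrt(np.square(s) - 4.0 * k10 * k21)
        lam1 = 0.5 * (s + disc)
        lam2 = 0.5 * (s - disc)
        t = design.times
        a = (lam1 - k21) / (lam1 - lam2)
        b = (k21 - lam2) / (lam1 - lam2)
        return base_i[..., None] + (dose / v1_i)[..., None] * (
            a[..., None] * np.exp(-lam1[..., None] * t)
            + b[..., None] * np.exp(-lam2[..., None] * t)
        )

    return NLMEModel(
        name="pk2",
        pred=pred,
        theta=np.array([cl, v1, q, v2, base]),
        omega=np.diag(omega),
        errors=(ErrorModel(prop_var=prop_var),),
        dv_labels=(dv_label,),
        theta_names=("CL", "V1", "Q", "V2", "BASE"),
        eta_names=("eta_CL", "eta_V1", "eta_BASE"),
    )


@dataclass(frozen=True)
class PKScenario:
    """Paired truth/misspecification scenario with a simulated dataset."""

    true_model: NLMEModel
    misspec_model: NLMEModel
    dataset: Dataset
    protocol: IVGTTProtocol
    seed: int


def make_pk_scenario(n_subjects: int = 100, seed: int = 20190227) -> PKScenario:
    """Simulate an IVGTT-style dataset from a two-compartment truth.

    The fitted (misspecified) alternative is a one-compartment model with the
    same error family; both share the IVGTT sampling grid.  The distribution
    phase of the truth (half-life about 6 min across the dense early samples)
    is what the one-compartment model cannot describe.
    """
    protocol = make_ivgtt_protocol()
    truth = two_compartment_model()
    misspec = one_compartment_model(cl=0.3, v=20.0)
    dataset = simulate_dataset(truth, protocol.to_design(), n_subjects, seed)
    return PKScenario(
        true_model=truth,
        misspec_model=misspec,
        dataset=dataset,
        protocol=protocol,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# glucose minimal sub-model (demo ODE)
# ---------------------------------------------------------------------------

def biexponential_insulin_action(
    peak: float = 0.01, rise: float = 0.15, decay: float = 0.02
) -> Callable[[float], float]:
    """Insulin-action forcing X(t): a bi-exponential pulse peaking at ``peak`` (1/min)."""
    if decay >= rise:
        raise ValueError("decay rate must be smaller than rise rate")
    t_max = np.log(rise / decay) / (rise - decay)
    scale = peak / (np.exp(-decay * t_max) - np.exp(-rise * t_max))

    def x(t):
        return scale * (np.exp(-decay * np.asarray(t)) - np.exp(-rise * np.asarray(t)))

    return x


@dataclass(frozen=True)
class MinimalGlucoseParams:
    """Parameters of the two-compartment glucose minimal sub-model.

    Rates in 1/min; ``g_b`` is the basal glucose amount.  Glucose
    effectiveness S_G is the sum of hepatic (k_5) and peripheral (k_1) uptake
    parameters.  ``insulin_action`` supplies X(t), the remote insulin effect
    on glucose disappearance, as a forcing function of time.
    """

    k1: float = 0.005
    k5: float = 0.02
    k21: float = 0.05
    k12: float = 0.07
    g_b: float = 900.0
    insulin_action: Callable[[float], float] = field(
        default_factory=biexponential_insulin_action
    )

    def __post_init__(self):
        for name in ("k1", "k5", "k21", "k12"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.g_b <= 0:
            raise ValueError("basal glucose amount must be positive")

    @property
    def s_g(self) -> float:
        """Glucose effectiveness S_G = k_1 + k_5 (1/min)."""
        return self.k1 + self.k5


def minimal_glucose_rhs(state, t, params: MinimalGlucoseParams):
    """Right-hand side of the glucose minimal sub-model.

    dG1/dt = S_G*G_b - (S_G + X(t) + k21)*G1 + k12*G2
    dG2/dt = k21*G1 - k12*G2

    Net hepatic glucose balance (production minus hepatic uptake) is lumped
    into the S_G*G_b - S_G*G1 terms; X(t) is the insulin effect.
    """
    g1, g2 = state
    sg = params.s_g
    x = float(np.asarray(params.insulin_action(t)))
    dg1 = sg * params.g_b - (sg + x + params.k21) * g1 + params.k12 * g2
    dg2 = params.k21 * g1 - params.k12 * g2
    return np.array([dg1, dg2])


def simulate_minimal_glucose(
    params: MinimalGlucoseParams,
    times,
    dose: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
):
    """Integrate the minimal glucose system over ``times``.

    Initial state is the basal steady state G1(0) = G_b (plus an optional
    bolus ``dose`` added to the central compartment) with the peripheral
    compartment at its basal equilibrium.
    """
    times = np.asarray(times, dtype=float)
    g2_0 = params.k21 / params.k12 * params.g_b if params.k12 > 0 else 0.0
    y0 = np.array([params.g_b + dose, g2_0])
    sol = solve_ivp(
        lambda t, y: minimal_glucose_rhs(y, t, params),
        (times[0], times[-1]),
        y0,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"glucose ODE integration failed: {sol.message}")
    return sol.y.T  # (n_times, 2): columns G1, G2
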