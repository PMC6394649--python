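"""Core data containers: NLME model specifications and longitudinal datasets.

An :class:`NLMEModel` bundles a structural prediction function ``f(theta, eta,
design)`` with the random-effect covariance Omega (inter-individual
variability), a residual-error model per dependent variable (DV) and the
population fixed effects theta.  Observations follow

    y = h(f(theta, eta), eps),    eta ~ N(0, Omega),  eps ~ N(0, Sigma)

where ``h`` is additive, proportional or combined per DV and Sigma is
diagonal.  Datasets use the NONMEM column dialect (ID, TIME, AMT, DV, DVID,
EVID, MDV) so that simulated and externally produced data interchange freely.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._linalg import ensure_psd

__all__ = [
    "ErrorModel",
    "Design",
    "Dose",
    "SubjectData",
    "Dataset",
    "NLMEModel",
]


@dataclass(frozen=True)
class ErrorModel:
    """Residual error model for one DV: ``y = f*(1+eps_p) + eps_a``.

    ``add_var`` and ``prop_var`` are the variances of the additive and
    proportional error components.  Both may be zero for noise-free
    simulation, but estimation and CWRES require a positive residual
    variance.
    """

    add_var: float = 0.0
    prop_var: float = 0.0

    def __post_init__(self):
        if self.add_var < 0 or self.prop_var < 0:
            raise ValueError("error variances must be non-negative")

    @property
    def kind(self) -> str:
        if self.add_var > 0 and self.prop_var > 0:
            return "combined"
        return "additive" if self.add_var > 0 else "proportional"

    def variance(self, f: np.ndarray) -> np.ndarray:
        """Residual variance diag(dh/deps . Sigma . dh/deps') at eps = 0."""
        return self.add_var + self.prop_var * np.square(f)

    def apply(self, f: np.ndarray, eps_add: np.ndarray, eps_prop: np.ndarray) -> np.ndarray:
        return f * (1.0 + eps_prop) + eps_add


@dataclass(frozen=True)
class Dose:
    time: float
    amt: float


@dataclass(frozen=True)
class Design:
    """Observation design shared by the prediction function.

    ``times`` are observation times (min), ``dvid`` the 0-based DV index per
    observation row, ``doses`` the dosing events.
    """

    times: np.ndarray
    dvid: np.ndarray
    doses: tuple[Dose, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "dvid", np.asarray(self.dvid, dtype=int))
        if self.times.ndim != 1 or self.dvid.shape != self.times.shape:
            raise ValueError("times and dvid must be matching 1-d arrays")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("observation times must be non-decreasing")

    @property
    def n_obs(self) -> int:
        return self.times.size

    @property
    def key(self) -> tuple:
        """Hashable signature used to batch subjects with identical designs."""
        return (
            tuple(self.times.tolist()),
            tuple(self.dvid.tolist()),
            tuple((d.time, d.amt) for d in self.doses),
        )


@dataclass(frozen=True)
class SubjectData:
    """One subject's design and observation vector (missing rows removed)."""

    id: int | str
    design: Design
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.y.shape != (self.design.n_obs,):
            raise ValueError(
                f"subject {self.id}: {self.y.size} observations for "
                f"{self.design.n_obs} design rows"
            )

    @property
    def n_obs(self) -> int:
        return self.design.n_obs


@dataclass(frozen=True)
class Dataset:
    subjects: tuple[SubjectData, ...]

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)


PredFn = Callable[[np.ndarray, np.ndarray, Design], np.ndarray]


@dataclass(frozen=True)
class NLMEModel:
    """Nonlinear mixed-effects model specification.

    ``pred(theta, eta, design)`` must broadcast over leading dimensions of
    ``eta``: for ``eta`` of shape ``(..., k)`` it returns predictions of shape
    ``(..., n_obs)``.  This lets the engine evaluate whole batches of subjects
    (or finite-difference stencils) in single vectorised calls.
    """

    name: str
    pred: PredFn
    theta: np.ndarray
    omega: np.ndarray
    errors: tuple[ErrorModel, ...]
    dv_labels: tuple[str, ...] = ("dv1",)
    theta_names: tuple[str, ...] = ()
    theta_positive: tuple[bool, ...] = ()
    eta_names: tuple[str, ...] = ()

    def __post_init__(self):
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        omega = ensure_psd(np.atleast_2d(np.asarray(self.omega, dtype=float)), "Omega")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "errors", tuple(self.errors))
        object.__setattr__(self, "dv_labels", tuple(self.dv_labels))
        if len(self.errors) != len(self.dv_labels):
            raise ValueError("one ErrorModel required per DV label")
        if not self.theta_names:
            object.__setattr__(
                self, "theta_names", tuple(f"theta{i+1}" for i in range(theta.size))
            )
        if not self.theta_positive:
            object.__setattr__(self, "theta_positive", (True,) * theta.size)
        if not self.eta_names:
            object.__setattr__(
                self, "eta_names", tuple(f"eta{i+1}" for i in range(omega.shape[0]))
            )

    @property
    def n_eta(self) -> int:
        return self.omega.shape[0]

    @property
    def n_theta(self) -> int:
        return self.theta.size

    def residual_variance(self, f: np.ndarray, dvid: np.ndarray) -> np.ndarray:
        """Per-observation residual variance given predictions ``f``."""
        add = np.array([e.add_var for e in self.errors])[dvid]
        prop = np.array([e.prop_var for e in self.errors])[dvid]
        return add + prop * np.square(f)

    def replace(self, **changes) -> "NLMEModel":
        return dataclasses.replace(self, **changes)

    def dv_index(self, dv_label: str) -> int:
        try:
            return self.dv_labels.index(dv_label)
        except ValueError:
            raise KeyError(f"unknown DV label {dv_label!r}; have {self.dv_labels}")
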