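"""FOCE machinery: simulation, empirical Bayes estimates, CWRES and fitting.

The engine implements the first-order conditional estimation (FOCE)
approximation used throughout pharmacometrics.  For subject *i* with empirical
Bayes estimates (EBEs) eta_hat_i, the model is linearized around eta_hat_i:

    E(Y_i)   = f(theta, eta_hat_i) - F_i . eta_hat_i
    COV(Y_i) = F_i . Omega . F_i' + diag(H_i . Sigma . H_i')
    CWRES_i  = COV(Y_i)^(-1/2) (y_i - E(Y_i))

with F_i = df/deta at eta_hat_i and H_i = dh/deps at eps = 0.  With
interaction (the default, FOCE-I) the residual-error derivatives use the
individual prediction f(theta, eta_hat_i); without it they use the population
prediction f(theta, 0).  The FOCE objective function value (OFV) is the sum
over subjects of log|COV| + (y-E)' COV^-1 (y-E); the n*log(2*pi) constant is
excluded (NONMEM convention), which leaves all OFV differences unchanged.

Subjects sharing an identical design are evaluated in vectorised batches: the
joint EBE objective is separable across subjects, so one L-BFGS-B run on the
stacked eta vector with batched finite-difference gradients estimates all
EBEs of a batch at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._linalg import apply_jitter, sym_sqrt_pair, sym_sqrt_psd
from .models import Dataset, Design, NLMEModel, SubjectData

__all__ = [
    "IndividualConditional",
    "CWRESResult",
    "PopulationFit",
    "simulate_dataset",
    "estimate_ebes",
    "conditional_moments",
    "estimate_conditionals",
    "compute_cwres",
    "foce_ofv",
    "fit_population",
]

#: relative step for central finite differences on eta and eps
FD_REL_STEP = 1e-4


class SubjectConvergenceWarning(UserWarning):
    """EBE optimisation failed to converge for one or more subjects."""


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    model: NLMEModel,
    protocol: Design,
    n_subjects: int,
    seed: int | np.random.Generator,
    return_etas: bool = False,
) -> Dataset:
    """Simulate ``n_subjects`` subjects sharing the sampling ``protocol``.

    Each subject draws eta ~ N(0, Omega) and per-observation residual errors
    from the DV-specific error models; observations are h(f(theta, eta), eps).
    Reproducible given the seed.  With ``return_etas`` the drawn
    individual random effects are returned alongside the dataset.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = model.n_eta
    etas = rng.multivariate_normal(np.zeros(k), model.omega, size=n_subjects, method="eigh")
    f = np.atleast_2d(model.pred(model.theta, etas, protocol))
    dvid = protocol.dvid
    add_sd = np.sqrt(np.array([e.add_var for e in model.errors]))[dvid]
    prop_sd = np.sqrt(np.array([e.prop_var for e in model.errors]))[dvid]
    eps_add = rng.standard_normal(f.shape) * add_sd
    eps_prop = rng.standard_normal(f.shape) * prop_sd
    y = f * (1.0 + eps_prop) + eps_add
    subjects = [
        SubjectData(id=i + 1, design=protocol, y=y[i]) for i in range(n_subjects)
    ]
    dataset = Dataset(subjects=tuple(subjects))
    return (dataset, etas) if return_etas else dataset


# ---------------------------------------------------------------------------
# EBE estimation (batched over identical designs)
# ---------------------------------------------------------------------------

def _group_subjects(dataset: Iterable[SubjectData]):
    """Group subjects by identical design so they can be batch-evaluated."""
    groups: dict[tuple, list[SubjectData]] = {}
    for s in dataset:
        groups.setdefault(s.design.key, []).append(s)
    return list(groups.values())


def _batch_objective(model, design, Y, interaction):
    """Per-subject FOCE-I individual objective, vectorised over subjects."""
    theta = model.theta
    dvid = design.dvid
    omega_d = np.diag(model.omega)
    active = omega_d > 1e-12
    if active.any():
        oinv = np.linalg.inv(model.omega[np.ix_(active, active)])
    else:
        oinv = np.zeros((0, 0))
    if not interaction:
        f_pop = model.pred(theta, np.zeros(model.n_eta), design)
        v_pop = model.residual_variance(f_pop, dvid)

    def per_subject(etas):
        f = np.atleast_2d(model.pred(theta, etas, design))
        if interaction:
            v = model.residual_variance(f, dvid)
        else:
            v = np.broadcast_to(v_pop, f.shape)
        q = np.sum(np.log(v) + np.square(Y - f) / v, axis=-1)
        if active.any():
            ea = etas[..., active]
            q = q + np.einsum("...i,ij,...j->...", ea, oinv, ea)
        return q

    return per_subject, active


def _estimate_ebes_batch(
    model: NLMEModel,
    subjects: Sequence[SubjectData],
    *,
    interaction: bool = True,
    restarts: int = 1,
    rng: np.random.Generator | None = None,
    x0: np.ndarray | None = None,
    maxiter: int = 200,
):
    """Estimate EBEs for subjects sharing one design.

    Returns ``(etas, q, flagged)``: the (S, k) EBE matrix, per-subject
    objective values and indices of subjects whose optimisation is suspect.
    """
    design = subjects[0].design
    Y = np.stack([s.y for s in subjects])
    S, k = len(subjects), model.n_eta
    per_subject, active = _batch_objective(model, design, Y, interaction)
    ka = int(active.sum())
    etas_out = np.zeros((S, k))
    if ka == 0:
        return etas_out, per_subject(etas_out), []

    def embed(e_act):
        full = np.zeros((S, k))
        full[:, active] = e_act
        return full

    def fun_grad(x):
        e = x.reshape(S, ka)
        q = per_subject(embed(e))
        g = np.empty((S, ka))
        for j in range(ka):
            h = FD_REL_STEP * (1.0 + np.abs(e[:, j]))
            ep = e.copy()
            ep[:, j] += h
            em = e.copy()
            em[:, j] -= h
            g[:, j] = (per_subject(embed(ep)) - per_subject(embed(em))) / (2.0 * h)
        return float(q.sum()), g.ravel()

    def run(start):
        res = minimize(
            fun_grad,
            start.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        e = res.x.reshape(S, ka)
        return e, per_subject(embed(e))

    start0 = np.zeros((S, ka)) if x0 is None else np.asarray(x0)[:, active]
    best_e, best_q = run(start0)
    if restarts > 0:
        rng = rng if rng is not None else np.random.default_rng(12345)
        omega_act = model.omega[np.ix_(active, active)]
        for _ in range(restarts):
            e0 = rng.multivariate_normal(np.zeros(ka), omega_act, size=S, method="eigh")
            e1, q1 = run(e0)
            better = q1 < best_q
            best_e[better] = e1[better]
            best_q = np.minimum(best_q, q1)

    # flag subjects whose final gradient is still large
    _, g = fun_grad(best_e.ravel())
    gnorm = np.abs(g.reshape(S, ka)).max(axis=1)
    flagged = [i for i in range(S) if not np.isfinite(best_q[i]) or gnorm[i] > 1e-2 * (1.0 + abs(best_q[i]))]
    return embed(best_e), best_q, flagged


def estimate_ebes(
    model: NLMEModel,
    subject: SubjectData,
    *,
    interaction: bool = True,
    restarts: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Empirical Bayes estimates for one subject.

    Minimises the FOCE individual objective
    ``sum_j [log v_j + (y_j - f_j)^2 / v_j] + eta' Omega^-1 eta``
    by quasi-Newton from eta = 0 plus ``restarts`` random restarts drawn from
    N(0, Omega); the best objective wins.
    """
    etas, _, flagged = _estimate_ebes_batch(
        model, [subject], interaction=interaction, restarts=restarts, rng=rng
    )
    if flagged:
        warnings.warn(
            f"EBE optimisation did not fully converge for subject {subject.id}",
            SubjectConvergenceWarning,
        )
    return etas[0]


# ---------------------------------------------------------------------------
# conditional moments
# ---------------------------------------------------------------------------

@dataclass
class IndividualConditional:
    """FOCE conditional moments for one subject.

    ``expectation``/``covariance`` are the mean and covariance of the
    conditional predictions; ``jac_eta`` is df/deta at eta_hat; ``jac_eps``
    holds the residual-error derivatives (columns: additive, proportional
    component) at eps = 0; ``var_res`` the resulting residual variance diag.
    """

    subject_id: int | str
    eta_hat: np.ndarray
    f_ind: np.ndarray
    jac_eta: np.ndarray
    jac_eps: np.ndarray
    var_res: np.ndarray
    expectation: np.ndarray
    omega: np.ndarray
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def covariance(self) -> np.ndarray:
        if self._cov is None:
            F = self.jac_eta
            cov = F @ self.omega @ F.T + np.diag(self.var_res)
            self._cov = apply_jitter(0.5 * (cov + cov.T))
        return self._cov


def _moments_batch(model, subjects, etas, interaction):
    design = subjects[0].design
    theta, dvid = model.theta, design.dvid
    S, k = etas.shape
    f_ind = np.atleast_2d(model.pred(theta, etas, design))
    n = f_ind.shape[1]
    F = np.empty((S, n, k))
    for j in range(k):
        h = FD_REL_STEP * (1.0 + np.abs(etas[:, j]))
        ep = etas.copy()
        ep[:, j] += h
        em = etas.copy()
        em[:, j] -= h
        F[:, :, j] = (
            np.atleast_2d(model.pred(theta, ep, design))
            - np.atleast_2d(model.pred(theta, em, design))
        ) / (2.0 * h)[:, None]
    expectation = f_ind - np.einsum("snk,sk->sn", F, etas)
    fv = f_ind if interaction else np.broadcast_to(
        model.pred(theta, np.zeros(k), design), f_ind.shape
    )
    var_res = model.residual_variance(fv, dvid)
    conds = []
    for i, s in enumerate(subjects):
        jac_eps = np.column_stack([np.ones(n), fv[i]])
        conds.append(
            IndividualConditional(
                subject_id=s.id,
                eta_hat=etas[i],
                f_ind=f_ind[i],
                jac_eta=F[i],
                jac_eps=jac_eps,
                var_res=var_res[i],
                expectation=expectation[i],
                omega=model.omega,
            )
        )
    return conds, f_ind, F, var_res, expectation


def conditional_moments(
    model: NLMEModel,
    subject: SubjectData,
    eta_hat: np.ndarray,
    *,
    interaction: bool = True,
) -> IndividualConditional:
    """Linearized conditional expectation and covariance for one subject."""
    eta_hat = np.atleast_1d(np.asarray(eta_hat, dtype=float))
    if not np.all(np.isfinite(eta_hat)):
        raise ValueError(f"subject {subject.id}: non-finite eta_hat")
    conds, *_ = _moments_batch(model, [subject], eta_hat[None, :], interaction)
    return conds[0]


# ---------------------------------------------------------------------------
# CWRES
# ---------------------------------------------------------------------------

@dataclass
class CWRESResult:
    """CWRES table plus the per-subject conditional moments behind it."""

    table: pd.DataFrame
    conds: dict
    flagged_subjects: tuple = ()

    def __iter__(self):  # allow tuple-unpacking (table, conds)
        return iter((self.table, self.conds))


def estimate_conditionals(
    model: NLMEModel,
    dataset: Dataset,
    *,
    interaction: bool = True,
    restarts: int = 1,
    rng: np.random.Generator | None = None,
):
    """EBEs and conditional moments for every subject.

    Returns ``(conds, flagged_ids)`` where ``conds`` maps subject id to an
    :class:`IndividualConditional` and ``flagged_ids`` lists subjects whose
    EBE optimisation is suspect.
    """
    rng = rng if rng is not None else np.random.default_rng(12345)
    conds_out: dict = {}
    flagged_ids: list = []
    for subjects in _group_subjects(dataset):
        etas, _, flagged = _estimate_ebes_batch(
            model, subjects, interaction=interaction, restarts=restarts, rng=rng
        )
        conds, *_ = _moments_batch(model, subjects, etas, interaction)
        for i, s in enumerate(subjects):
            if i in flagged:
                flagged_ids.append(s.id)
            else:
                conds_out[s.id] = conds[i]
    return conds_out, flagged_ids


def compute_cwres(
    model: NLMEModel,
    dataset: Dataset,
    *,
    interaction: bool = True,
    restarts: int = 1,
    rng: np.random.Generator | None = None,
    sqrt_method: str = "sym",
) -> CWRESResult:
    """Compute CWRES for every subject of ``dataset`` under ``model``.

    The table has one row per observation with columns ID, ROW, DVID, TIME,
    one population-prediction column PRED_<dv> per DV (computed at eta = 0
    and repeated across all rows, so any DV's CWRES can be binned on any DV's
    PRED) and CWRES.  Subjects whose EBE optimisation or covariance
    factorisation fails are excluded with a warning.
    """
    conds, flagged_ids = estimate_conditionals(
        model, dataset, interaction=interaction, restarts=restarts, rng=rng
    )
    rows = []
    row_counter = 0
    pred_cache: dict = {}
    for s in dataset:
        if s.id not in conds:
            row_counter += s.n_obs
            continue
        cond = conds[s.id]
        design = s.design
        if design.key not in pred_cache:
            cols = {}
            for d, dv in enumerate(model.dv_labels):
                dsn = Design(design.times, np.full(design.n_obs, d), design.doses)
                cols[f"PRED_{dv}"] = np.asarray(
                    model.pred(model.theta, np.zeros(model.n_eta), dsn), dtype=float
                )
            pred_cache[design.key] = cols
        pred_cols = pred_cache[design.key]
        try:
            _, neg_half = sym_sqrt_pair(cond.covariance, method=sqrt_method)
        except np.linalg.LinAlgError:
            flagged_ids.append(s.id)
            del conds[s.id]
            row_counter += s.n_obs
            continue
        r = neg_half @ (s.y - cond.expectation)
        for j in range(s.n_obs):
            row = {
                "ID": s.id,
                "ROW": row_counter + j,
                "DVID": model.dv_labels[design.dvid[j]],
                "TIME": design.times[j],
                "CWRES": r[j],
            }
            for name, col in pred_cols.items():
                row[name] = col[j]
            rows.append(row)
        row_counter += s.n_obs
    if flagged_ids:
        warnings.warn(
            f"excluded {len(flagged_ids)} subject(s) from CWRES table: {flagged_ids}",
            SubjectConvergenceWarning,
        )
    cols = ["ID", "ROW", "DVID", "TIME"] + [f"PRED_{dv}" for dv in model.dv_labels] + ["CWRES"]
    table = pd.DataFrame(rows, columns=cols)
    if not np.all(np.isfinite(table["CWRES"].to_numpy())):
        raise FloatingPointError("non-finite CWRES values produced")
    return CWRESResult(table=table, conds=conds, flagged_subjects=tuple(flagged_ids))


# ---------------------------------------------------------------------------
# FOCE objective and population fitting
# ---------------------------------------------------------------------------

def _group_ofv(model, subjects, etas, interaction):
    """FOCE -2LL contributions for one design group via Woodbury identities."""
    _, f_ind, F, v, E = _moments_batch(model, subjects, etas, interaction)
    Y = np.stack([s.y for s in subjects])
    r = Y - E
    ohalf = sym_sqrt_psd(model.omega)
    G = F @ ohalf  # (S, n, k)
    Ginv = G / v[:, :, None]
    k = model.n_eta
    A = np.eye(k) + np.einsum("snk,snl->skl", Ginv, G)
    sign, logdetA = np.linalg.slogdet(A)
    if np.any(sign <= 0):
        raise FloatingPointError("non-PD linearized covariance in OFV")
    logdet = np.sum(np.log(v), axis=1) + logdetA
    t = np.einsum("snk,sn->sk", Ginv, r)
    sol = np.linalg.solve(A, t[..., None])[..., 0]
    quad = np.sum(r * r / v, axis=1) - np.einsum("sk,sk->s", t, sol)
    return logdet + quad


def foce_ofv(
    model: NLMEModel,
    dataset: Dataset,
    *,
    interaction: bool = True,
    restarts: int = 0,
    rng: np.random.Generator | None = None,
    etas_cache: dict | None = None,
) -> float:
    """FOCE objective function value (sum of -2 log-likelihood contributions).

    EBEs are re-estimated at the current parameters (warm-started from
    ``etas_cache`` when given, which is updated in place).  The n*log(2*pi)
    constant is excluded.
    """
    total = 0.0
    for subjects in _group_subjects(dataset):
        key = subjects[0].design.key
        x0 = etas_cache.get(key) if etas_cache is not None else None
        if x0 is not None and x0.shape != (len(subjects), model.n_eta):
            x0 = None
        etas, _, _ = _estimate_ebes_batch(
            model, subjects, interaction=interaction, restarts=restarts, rng=rng, x0=x0
        )
        if etas_cache is not None:
            etas_cache[key] = etas
        contribs = _group_ofv(model, subjects, etas, interaction)
        if not np.all(np.isfinite(contribs)):
            bad = [s.id for s, c in zip(subjects, contribs) if not np.isfinite(c)]
            raise FloatingPointError(f"non-finite OFV contribution for subject(s) {bad}")
        total += float(contribs.sum())
    return total


@dataclass
class PopulationFit:
    model: NLMEModel
    ofv: float
    converged: bool
    n_evals: int
    message: str
    inits_ofv: float


def _pack(model: NLMEModel):
    """Map (theta, diag Omega, error variances) to an unconstrained vector."""
    x = []
    for val, pos in zip(model.theta, model.theta_positive):
        x.append(np.log(val) if pos else val)
    x.extend(np.log(np.maximum(np.diag(model.omega), 1e-10)))
    err_layout = []
    for d, e in enumerate(model.errors):
        comps = []
        if e.add_var > 0:
            comps.append("add")
            x.append(np.log(e.add_var))
        if e.prop_var > 0:
            comps.append("prop")
            x.append(np.log(e.prop_var))
        err_layout.append(tuple(comps))
    return np.array(x, dtype=float), err_layout


def _unpack(model: NLMEModel, x: np.ndarray, err_layout):
    nt, ne = model.n_theta, model.n_eta
    theta = np.array(
        [np.exp(v) if pos else v for v, pos in zip(x[:nt], model.theta_positive)]
    )
    omega = np.diag(np.exp(x[nt : nt + ne]))
    errors = []
    i = nt + ne
    from .models import ErrorModel

    for comps in err_layout:
        kw = {"add_var": 0.0, "prop_var": 0.0}
        for c in comps:
            kw[f"{c}_var"] = float(np.exp(x[i]))
            i += 1
        errors.append(ErrorModel(**kw))
    return model.replace(theta=theta, omega=omega, errors=tuple(errors))


def fit_population(
    model: NLMEModel,
    dataset: Dataset,
    inits: NLMEModel | None = None,
    *,
    interaction: bool = True,
    maxiter: int | None = None,
    fatol: float = 1e-3,
    xatol: float = 1e-4,
) -> PopulationFit:
    """Fit (theta, diag Omega, Sigma) by minimising the FOCE objective.

    Positive parameters are optimised on the log scale with Nelder-Mead
    (robust against the small numerical noise of the nested EBE step); EBEs
    are warm-started across objective evaluations.  Off-diagonal Omega terms
    are held at zero.
    """
    start = inits if inits is not None else model
    x0, err_layout = _pack(start)
    cache: dict = {}
    n_evals = 0

    def objective(x):
        nonlocal n_evals
        n_evals += 1
        try:
            m = _unpack(model, x, err_layout)
            return foce_ofv(m, dataset, interaction=interaction, etas_cache=cache)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e12

    ofv0 = objective(x0)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter if maxiter is not None else 400 * x0.size,
            "fatol": fatol,
            "xatol": xatol,
            "adaptive": True,
        },
    )
    best_x, best_ofv = (res.x, res.fun) if res.fun <= ofv0 else (x0, ofv0)
    fitted = _unpack(model, best_x, err_layout)
    converged = bool(res.success) and res.fun <= ofv0 + fatol
    return PopulationFit(
        model=fitted,
        ofv=float(best_ofv),
        converged=converged,
        n_evals=n_evals,
        message=str(res.message),
        inits_ofv=float(ofv0),
    )
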