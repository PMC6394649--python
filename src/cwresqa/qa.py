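"""End-to-end structural-bias QA pipeline.

``run_qa`` strings the stages together: (optionally simulate) -> fit the
candidate model -> CWRES -> per-DV, per-IDV bias tests -> bias back-correction
-> reports.  The pipeline is a pure function of (dataset, config): rerunning
with the same config and seed reproduces every number.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biasmodel import CWRESGrouped, bias_test, fit_base, fit_extended
from .binning import (
    DEFAULT_MIN_PER_BIN,
    DEFAULT_N_PRED,
    DEFAULT_N_TIME,
    density_bins,
    random_binning_study,
)
from .correction import correct_predictions, expand_bias, known_bias
from .engine import compute_cwres, estimate_conditionals, fit_population, simulate_dataset
from .io import read_dataset, write_cwres_table, write_dataset, write_json_report
from .models import Dataset
from .scenarios import get_model, make_ivgtt_protocol

log = logging.getLogger("cwresqa")

__all__ = ["RunConfig", "QAReport", "run_qa"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one QA run.

    ``idvs`` may contain "TIME" and/or "PRED"; "PRED" expands to one analysis
    per DV's population-prediction column.  ``truth_model`` (when the data
    are simulated and the generating model is known) enables the % known-bias
    reference.  ``df_convention`` is "n_bins" (test at chi-square(N)) or
    "n_bins_minus_1".
    """

    fit_model: str = "one_compartment"
    dataset: str | None = None
    simulate_from: str | None = "two_compartment"
    truth_model: str | None = "two_compartment"
    n_subjects: int = 100
    seed: int = 20190227
    idvs: tuple[str, ...] = ("TIME", "PRED")
    n_bins_time: int = DEFAULT_N_TIME
    n_bins_pred: int = DEFAULT_N_PRED
    min_per_bin: int = DEFAULT_MIN_PER_BIN
    random_reps: int = 0
    df_convention: str = "n_bins"
    interaction: bool = True
    do_fit: bool = True
    fit_maxiter: int | None = 300
    outdir: str | None = None

    def __post_init__(self):
        if self.n_bins_time < 1 or self.n_bins_pred < 1 or self.min_per_bin < 1:
            raise ValueError("N and M must be >= 1")
        if self.random_reps < 0:
            raise ValueError("random_reps must be >= 0")
        if self.df_convention not in ("n_bins", "n_bins_minus_1"):
            raise ValueError("df_convention must be 'n_bins' or 'n_bins_minus_1'")
        if self.dataset is None and self.simulate_from is None:
            raise ValueError("either a dataset path or a simulation model is required")


@dataclass
class QAReport:
    config: RunConfig
    summary: pd.DataFrame
    fitted_model: object
    cwres_table: pd.DataFrame
    bias_fits: dict
    corrections: dict
    known_bias_results: dict
    random_studies: dict
    fit_ofv: float | None

    @property
    def any_significant(self) -> bool:
        return bool(self.summary["significant"].any())


def _idv_columns(config: RunConfig, model) -> list[str]:
    cols = []
    for idv in config.idvs:
        if idv.upper() == "TIME":
            cols.append("TIME")
        elif idv.upper() == "PRED":
            cols.extend(f"PRED_{dv}" for dv in model.dv_labels)
        else:
            cols.append(idv)
    return cols


def run_qa(config: RunConfig) -> QAReport:
    """Execute the full QA workflow and (optionally) write its reports."""
    rng_seed = config.seed
    fit_model = get_model(config.fit_model)

    if config.dataset is not None:
        log.info("loading dataset from %s", config.dataset)
        dataset = read_dataset(config.dataset, dv_labels=fit_model.dv_labels)
        simulated = False
    else:
        truth = get_model(config.simulate_from)
        log.info("simulating %d subjects from %s", config.n_subjects, truth.name)
        dataset = simulate_dataset(
            truth, make_ivgtt_protocol().to_design(), config.n_subjects, rng_seed
        )
        simulated = True

    fit_ofv = None
    if config.do_fit:
        log.info("fitting %s by FOCE", fit_model.name)
        fit = fit_population(
            fit_model, dataset, interaction=config.interaction,
            maxiter=config.fit_maxiter,
        )
        if not fit.converged:
            log.warning("population fit did not fully converge: %s", fit.message)
        fitted = fit.model
        fit_ofv = fit.ofv
    else:
        fitted = fit_model

    log.info("computing CWRES")
    cw = compute_cwres(
        fitted, dataset, interaction=config.interaction,
        rng=np.random.default_rng(rng_seed + 1),
    )

    truth_conds = None
    if config.truth_model is not None:
        truth = get_model(config.truth_model)
        truth_conds, _ = estimate_conditionals(
            truth, dataset, interaction=config.interaction,
            rng=np.random.default_rng(rng_seed + 2),
        )

    rows = []
    bias_fits: dict = {}
    corrections: dict = {}
    known: dict = {}
    random_studies: dict = {}
    for dv in fitted.dv_labels:
        if not (cw.table["DVID"] == dv).any():
            continue
        for idv_col in _idv_columns(config, fitted):
            grouped = CWRESGrouped.from_table(cw.table, dv, idv_col)
            n_bins = (
                config.n_bins_time if idv_col == "TIME" else config.n_bins_pred
            )
            bins = density_bins(
                grouped.all_idv, n_bins, config.min_per_bin, idv_name=idv_col
            )
            base = fit_base(grouped)
            ext = fit_extended(grouped, bins)
            df = n_bins if config.df_convention == "n_bins" else n_bins - 1
            test = bias_test(base, ext, df=df)
            key = (dv, idv_col)
            bias_fits[key] = {"base": base, "extended": ext, "test": test}
            rows.append(
                {
                    "DV": dv,
                    "IDV": idv_col,
                    "n_bins": n_bins,
                    "delta_ofv": test.delta_ofv,
                    "df": test.df,
                    "critical_value": test.critical_value,
                    "significant": test.significant,
                }
            )
            expanded = expand_bias(ext.means, bins, grouped.all_idv)
            corr = correct_predictions(grouped, cw.conds, expanded, bins)
            corrections[key] = corr
            if truth_conds is not None:
                y_sim, y_est = [], []
                for sid, obs_idx in zip(grouped.subject_ids, grouped.obs_index):
                    idx = np.asarray(obs_idx, int)
                    y_sim.append(truth_conds[sid].expectation[idx])
                    y_est.append(cw.conds[sid].expectation[idx])
                known[key] = known_bias(
                    np.concatenate(y_sim), np.concatenate(y_est), bins, grouped.all_idv
                )
            if config.random_reps > 0:
                random_studies[key] = random_binning_study(
                    grouped,
                    n_bins,
                    config.min_per_bin,
                    reps=config.random_reps,
                    seed=np.random.default_rng(rng_seed + 3),
                    conds=cw.conds,
                )

    summary = pd.DataFrame(
        rows,
        columns=["DV", "IDV", "n_bins", "delta_ofv", "df", "critical_value", "significant"],
    )
    report = QAReport(
        config=config,
        summary=summary,
        fitted_model=fitted,
        cwres_table=cw.table,
        bias_fits=bias_fits,
        corrections=corrections,
        known_bias_results=known,
        random_studies=random_studies,
        fit_ofv=fit_ofv,
    )
    if config.outdir is not None:
        _write_outputs(report, dataset, simulated)
    return report


def _write_outputs(report: QAReport, dataset: Dataset, simulated: bool) -> None:
    out = Path(report.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if simulated:
        write_dataset(dataset, out / "dataset.csv")
    write_cwres_table(report.cwres_table, out / "cwres.csv")
    report.summary.to_csv(out / "summary.csv", index=False)
    detail = {
        "version": __version__,
        "config": dataclasses.asdict(report.config),
        "fit_ofv": report.fit_ofv,
        "fitted_theta": getattr(report.fitted_model, "theta", None),
        "analyses": {},
    }
    for (dv, idv), fits in report.bias_fits.items():
        ext, test = fits["extended"], fits["test"]
        entry = {
            "base_ofv": fits["base"].ofv,
            "extended_ofv": ext.ofv,
            "delta_ofv": test.delta_ofv,
            "df": test.df,
            "critical_value": test.critical_value,
            "significant": test.significant,
            "b": ext.means,
            "omega": ext.omega,
            "sigma": ext.sigma,
            "bins": ext.bins.to_dict() if ext.bins is not None else None,
        }
        corr = report.corrections.get((dv, idv))
        if corr is not None:
            entry["binned_delta"] = corr.binned_delta
            entry["binned_pct_delta"] = corr.binned_pct_delta
            corr.to_frame().to_csv(out / f"correction_{dv}_{idv}.csv", index=False)
        kb = report.known_bias_results.get((dv, idv))
        if kb is not None:
            entry["binned_pct_known_bias"] = kb.binned_percent
        detail["analyses"][f"{dv}|{idv}"] = entry
    write_json_report(detail, out / "report.json")
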