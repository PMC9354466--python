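"""End-to-end orchestration: reconstruct -> fit -> model -> economics -> SA.

``run_base_case`` executes the deterministic pipeline for the entire
population and every configured subgroup; ``run_full_analysis`` adds the
one-way DSA with tornado ordering, threshold searches on the configured
parameters, and the PSA with its acceptability curve.  Reports carry a
provenance block (config hash, seed, library versions) and can be written
to a directory as CSV/JSON files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .econ_valuation import ledgers_to_frame
from .errors import CEAError, NoCrossingError
from .km_reconstruct import ReconstructedIPD, reconstruct_ipd
from .model import CEAModel, StrategyPair
from .sensitivity import (
    CEACPoint,
    PSAResult,
    TornadoEntry,
    ceac,
    ceac_to_frame,
    default_distributions,
    default_ranges,
    one_way_dsa,
    run_psa,
    threshold_search,
    tornado_to_frame,
)
from .survival_fit import FittedSurvival, fit_candidates, fits_to_frame, select_best_fit
from .synthetic_trial import (
    KMCurve,
    RiskTable,
    digitize_km,
    filter_records,
    read_km_csv,
    read_risk_csv,
    simulate_ipd,
)

logger = logging.getLogger(__name__)

ENDPOINTS = ("PFS", "OS")


@dataclass
class RunReport:
    """Everything one analysis run produced."""

    base: StrategyPair | None
    subgroups: dict[str, StrategyPair]
    fits: dict[str, list[FittedSurvival]]
    selected: dict[str, FittedSurvival]
    reconstruction_diagnostics: dict[str, float]
    provenance: dict[str, Any]
    tornado: list[TornadoEntry] | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)
    psa: PSAResult | None = None
    ceac_points: list[CEACPoint] | None = None

    def summary(self) -> dict[str, Any]:
        """JSON-serializable headline numbers."""
        comp = self.base.comparison

        def _strategy(res):
            return {
                "total_cost": round(res.total_cost, 2),
                "total_qalys": round(res.total_qalys, 4),
                "total_life_years": round(res.total_life_years, 4),
            }

        out = {
            "intervention": _strategy(self.base.intervention),
            "control": _strategy(self.base.control),
            "delta_cost": round(comp.delta_cost, 2),
            "delta_qalys": round(comp.delta_qalys, 4),
            "icer": None if comp.icer is None else round(comp.icer, 2),
            "dominance": comp.dominance.value,
            "wtp": comp.wtp,
            "decision": "cost-effective" if comp.cost_effective else "not cost-effective",
            "selected_families": {ep: f.family for ep, f in self.selected.items()},
            "subgroups": {
                name: {
                    "delta_cost": round(p.comparison.delta_cost, 2),
                    "delta_qalys": round(p.comparison.delta_qalys, 4),
                    "icer": None if p.comparison.icer is None else round(p.comparison.icer, 2),
                    "cost_effective": p.comparison.cost_effective,
                }
                for name, p in self.subgroups.items()
            },
            "thresholds": self.thresholds,
            "provenance": self.provenance,
        }
        if self.ceac_points is not None:
            at_wtp = [p for p in self.ceac_points if abs(p.wtp - comp.wtp) < 1e-9]
            if at_wtp:
                out["probability_cost_effective_at_wtp"] = at_wtp[0].probability
        return out


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except CEAError as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        raise CEAError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def prepare_curves(config: AnalysisConfig) -> dict[str, tuple[KMCurve, RiskTable]]:
    """Digitized control-arm KM inputs per endpoint (synthetic or from files)."""
    out: dict[str, tuple[KMCurve, RiskTable]] = {}
    if config.trial is not None:
        records = simulate_ipd(config.trial)
        control_records = filter_records(records, arm=config.control)
        for i, endpoint in enumerate(ENDPOINTS):
            recs = filter_records(control_records, endpoint=endpoint)
            t_max = config.trial.censor_time
            grid = np.arange(0.0, t_max + config.digitize_grid_step, config.digitize_grid_step)
            risk_times = np.arange(0.0, t_max + config.risk_table_step, config.risk_table_step)
            out[endpoint] = digitize_km(
                recs,
                grid,
                jitter=config.digitize_jitter,
                seed=config.seed + 1 + i,
                risk_times=risk_times,
            )
    else:
        for endpoint in ENDPOINTS:
            entry = config.km_files[endpoint]
            out[endpoint] = (
                read_km_csv(entry["curve"], endpoint=endpoint, arm=config.control),
                read_risk_csv(entry["risk"]),
            )
    return out


def build_model(config: AnalysisConfig) -> tuple[CEAModel, RunReport]:
    """Run the survival stages and assemble the configured model.

    Returns the model plus a report skeleton holding fits and diagnostics
    (base-case economics are filled in by the caller).
    """
    with _stage("prepare-curves"):
        curves = prepare_curves(config)

    recon: dict[str, ReconstructedIPD] = {}
    with _stage("reconstruct-ipd"):
        for endpoint, (curve, risk) in curves.items():
            recon[endpoint] = reconstruct_ipd(curve, risk)

    fits: dict[str, list[FittedSurvival]] = {}
    selected: dict[str, FittedSurvival] = {}
    with _stage("fit-and-select"):
        for endpoint, r in recon.items():
            fits[endpoint] = fit_candidates(r.records, config.families)
            selected[endpoint] = select_best_fit(fits[endpoint])
            logger.info(
                "%s: selected %s (AIC %.1f)",
                endpoint,
                selected[endpoint].family,
                selected[endpoint].aic,
            )

    with _stage("build-model"):
        model = CEAModel(
            pfs_control=selected["PFS"].survival,
            os_control=selected["OS"].survival,
            hr_pfs=config.hr_pfs.value,
            hr_os=config.hr_os.value,
            ae_disc=config.ae_disc,
            costs=config.costs,
            utils=config.utilities,
            settings=config.settings,
            intervention=config.intervention,
            control=config.control,
            wtp=config.wtp,
        )

    report = RunReport(
        base=None,  # filled by run_base_case
        subgroups={},
        fits=fits,
        selected=selected,
        reconstruction_diagnostics={ep: r.diagnostics for ep, r in recon.items()},
        provenance=_provenance(config),
    )
    return model, report


def run_base_case(config: AnalysisConfig) -> RunReport:
    """Deterministic pipeline for the entire population and all subgroups."""
    model, report = build_model(config)
    with _stage("base-case"):
        report.base = model.evaluate()
    with _stage("subgroups"):
        for sg in config.subgroups:
            report.subgroups[sg.name] = model.evaluate({"hr_pfs": sg.hr_pfs})
    report.provenance["model"] = "base-case"
    return report


def run_full_analysis(config: AnalysisConfig) -> RunReport:
    """Base case plus DSA tornado, threshold searches, PSA and CEAC."""
    model, report = build_model(config)
    with _stage("base-case"):
        report.base = model.evaluate()
    with _stage("subgroups"):
        for sg in config.subgroups:
            report.subgroups[sg.name] = model.evaluate({"hr_pfs": sg.hr_pfs})

    hr_cis = config.hr_cis()
    ranges = default_ranges(model, rel=config.dsa_rel_range, hr_cis=hr_cis)
    with _stage("one-way-dsa"):
        report.tornado = one_way_dsa(model, ranges)

    with _stage("threshold"):
        for param in config.threshold_parameters:
            bracket = _threshold_bracket(param, model.base_params[param])
            try:
                value, icer_at = threshold_search(model, param, config.wtp, bracket)
                report.thresholds[param] = {
                    "value": value,
                    "icer": icer_at,
                    "bracket": list(bracket),
                }
            except NoCrossingError as exc:
                report.thresholds[param] = {"no_crossing": str(exc), "bracket": list(bracket)}
                logger.info("threshold %s: %s", param, exc)

    if config.psa_enabled:
        with _stage("psa"):
            dists = default_distributions(model, ranges, hr_cis=hr_cis)
            report.psa = run_psa(model, dists, n=config.psa_iterations, seed=config.seed + 7)
            grid = _wtp_grid(config.wtp)
            report.ceac_points = ceac(report.psa, grid)
    report.provenance["model"] = "full-analysis"
    return report


def _threshold_bracket(param: str, base: float) -> tuple[float, float]:
    """Search bracket by parameter domain: up from base to the domain edge."""
    if param.startswith(("p_subsequent", "u_", "ae_disc")):
        return (base, 1.0 - 1e-9) if param.startswith("ae_disc") else (base, 1.0)
    if param.startswith("hr_"):
        return (base, 2.0)
    return (base, 5.0 * base if base > 0 else 1.0)


def _wtp_grid(wtp: float) -> np.ndarray:
    """0 .. 2x WTP in 40 steps, always containing the WTP itself."""
    return np.unique(np.concatenate([np.linspace(0.0, 2.0 * wtp, 41), [wtp]]))


def _provenance(config: AnalysisConfig) -> dict[str, Any]:
    import lifelines
    import scipy

    blob = yaml.safe_dump(dict(config.raw), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "nsclc_cea": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
        },
    }


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: RunReport, outdir, settings=None) -> None:
    """Write the report as CSV ledgers plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    all_fits = [f for fits in report.fits.values() for f in fits]
    frame = fits_to_frame(all_fits)
    frame.insert(0, "endpoint", [ep for ep, fits in report.fits.items() for _ in fits])
    frame.to_csv(outdir / "fits.csv", index=False)

    for label, res in (("intervention", report.base.intervention),
                       ("control", report.base.control)):
        ledgers_to_frame(res).to_csv(outdir / f"ledger_{label}.csv", index=False)

    rows = []
    for name, pair in report.subgroups.items():
        c = pair.comparison
        rows.append(
            {
                "subgroup": name,
                "cost_intervention": pair.intervention.total_cost,
                "qalys_intervention": pair.intervention.total_qalys,
                "delta_cost": c.delta_cost,
                "delta_qalys": c.delta_qalys,
                "icer": c.icer,
                "cost_effective": c.cost_effective,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "subgroups.csv", index=False)

    if report.tornado is not None:
        tornado_to_frame(report.tornado).to_csv(outdir / "tornado.csv", index=False)
    if report.psa is not None:
        report.psa.to_frame().to_csv(outdir / "psa_draws.csv", index=False)
    if report.ceac_points is not None:
        ceac_to_frame(report.ceac_points).to_csv(outdir / "ceac.csv", index=False)
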