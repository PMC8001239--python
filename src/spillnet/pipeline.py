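"""End-to-end orchestration: simulate or load a weekly panel, screen it,
estimate the TVP-VAR, derive connectedness indices, aggregate to monthly
frequency and regress the indices on covariate cycles.

Every run writes a manifest recording the seed, a hash of the resolved
configuration, the package version and a checksum per output file; identical
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import connectedness as conn
from . import preprocessing as prep
from . import robust_regression as robust
from . import synthetic_data as synth
from . import tvp_var

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class _EarlyStop(Exception):
    """Internal marker: stop after the simulation/screening stages."""


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run; see ``from_yaml``."""

    outdir: str = "spillnet_out"
    seed: int = 0
    mode: str = "synthetic"  # or "csv"
    panel_csv: str | None = None
    covariates_csv: str | None = None
    # synthetic inputs
    start_date: str = "2000-01-01"
    end_date: str = "2003-12-31"
    n_series: int = 8
    true_order: int = 1
    target_radius: float = 0.55
    innovation_correlation: float = 0.3
    diagonal_truth: bool = False
    burn_in: int = 200
    # estimation
    var_order: int | None = 1  # None -> BIC selection over 1..4
    kappa1: float = 0.99
    kappa2: float = 0.96
    prior: str = "ols"
    prior_fraction: float = 0.1
    horizon: int = 10
    tci_denominator: str = "N"
    # preprocessing / regression
    hp_lambda: float = prep.MONTHLY_HP_LAMBDA
    recipe: dict = field(default_factory=dict)
    run_estimation: bool = True
    run_regression: bool = True
    mm_efficiency: float = 0.95
    mm_breakdown: float = 0.5
    mm_resamples: int = 500
    baumol_scale: float = 100.0
    rstudent_cut: float = 2.0
    dffits_scale: float = 2.0
    covratio_scale: float = 3.0
    min_edge: float = 0.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def validate(self) -> None:
        if self.mode not in {"synthetic", "csv"}:
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv":
            needed = [("panel_csv", self.panel_csv)]
            if self.run_regression:
                needed.append(("covariates_csv", self.covariates_csv))
            for label, p in needed:
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{label} does not exist: {p}")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(config: PipelineConfig):
    cal = synth.make_calendar(config.start_date, config.end_date)
    rng = np.random.default_rng(config.seed)
    if config.diagonal_truth:
        coefs = np.stack(
            [np.diag(np.full(config.n_series, config.target_radius))]
            + [np.zeros((config.n_series, config.n_series))] * (config.true_order - 1)
        )
        cov = np.eye(config.n_series)
    else:
        coefs = synth.random_stationary_coefficients(
            config.n_series, config.true_order, rng, target_radius=config.target_radius
        )
        cov = synth.random_innovation_cov(config.n_series, rng, config.innovation_correlation)
    sim = synth.SimulationConfig(
        calendar=cal,
        coefficients=coefs,
        innovation_cov=cov,
        n_series=config.n_series,
        seed=config.seed,
        burn_in=config.burn_in,
    )
    panel = synth.generate_expenditure_panel(sim)
    covariates = synth.generate_covariates(synth.CovariateConfig(seed=config.seed + 1), cal)
    return panel, covariates


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest dictionary.

    Stage failures abort with the stage name attached to the exception.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "input"
    try:
        if config.mode == "synthetic":
            panel, covariates = _simulate_inputs(config)
            outputs["panel"] = outdir / "panel.csv"
            panel.to_csv(outputs["panel"])
            outputs["covariates"] = outdir / "covariates.csv"
            synth.write_covariates_csv(covariates, outputs["covariates"])
            synth.write_simulation_metadata(
                outdir / "simulation_meta.yaml", config.seed, {"mode": "synthetic"}
            )
            outputs["simulation_meta"] = outdir / "simulation_meta.yaml"
        else:
            panel = synth.ExpenditurePanel.from_csv(config.panel_csv)
            covariates = (
                synth.read_covariates_csv(config.covariates_csv)
                if config.covariates_csv
                else None
            )
        cal = panel.calendar
        values = panel.to_numpy()
        labels = panel.series_ids

        stage = "stationarity screening"
        pp_rows = []
        for sid, col in zip(labels, values.T):
            res = prep.pp_test(col)
            pp_rows.append(
                {
                    "series": sid,
                    "z_tau": res.z_tau,
                    "z_rho": res.z_rho,
                    "bandwidth": res.bandwidth,
                    "spec": res.deterministic_spec,
                    "crit_5pct": res.crit_5pct,
                    "reject_5pct": res.reject_5pct,
                }
            )
        pp_report = pd.DataFrame(pp_rows)
        outputs["pp_report"] = outdir / "pp_report.csv"
        pp_report.to_csv(outputs["pp_report"], index=False, float_format="%.10g")
        n_fail = int((~pp_report["reject_5pct"]).sum())
        if n_fail:
            logger.warning("%d series fail the 5%% stationarity screen", n_fail)

        if not config.run_estimation:
            raise _EarlyStop
        stage = "tvp-var estimation"
        p = config.var_order or tvp_var.select_var_order(values, max_p=4)
        logger.info("VAR order p=%d, kappa1=%.3f, kappa2=%.3f", p, config.kappa1, config.kappa2)
        states = tvp_var.fit_tvp_var(
            values,
            p,
            kappa1=config.kappa1,
            kappa2=config.kappa2,
            prior=config.prior,
            prior_fraction=config.prior_fraction,
        )

        stage = "connectedness"
        tables = conn.dynamic_connectedness(
            states, config.horizon, labels=labels, tci_denominator=config.tci_denominator
        )
        week_labels = [cal.week_starts[t.label] for t in tables]
        tci = pd.Series([t.tci for t in tables], name="TCI")
        ntdci = conn.ntdci_frame(tables)
        dynamic = pd.concat([tci, ntdci.reset_index(drop=True)], axis=1)
        dynamic.insert(0, "week_start", [d.isoformat() for d in week_labels])
        outputs["dynamic_indices"] = outdir / "dynamic_indices.csv"
        dynamic.to_csv(outputs["dynamic_indices"], index=False, float_format="%.10g")

        static = conn.average_table(tables)
        fevd_frame = pd.DataFrame(static.fevd.values, index=list(labels), columns=list(labels))
        outputs["static_fevd"] = outdir / "static_fevd.csv"
        fevd_frame.to_csv(outputs["static_fevd"], index_label="series", float_format="%.10g")
        static_idx = static.to_frame()
        static_idx.loc["__TCI__"] = [np.nan, np.nan, np.nan]
        static_idx.loc["__TCI__", "to_others"] = static.tci
        outputs["static_indices"] = outdir / "static_indices.csv"
        static_idx.to_csv(outputs["static_indices"], index_label="series", float_format="%.10g")

        edges = conn.export_network(static, min_edge=config.min_edge)
        outputs["edges"] = outdir / "edges.csv"
        conn.write_edge_list(edges, outputs["edges"])
        outputs["network_dot"] = outdir / "network.dot"
        conn.write_dot(static, edges, outputs["network_dot"])

        roles = conn.classify_nodes(tables)
        outputs["node_roles"] = outdir / "node_roles.csv"
        pd.DataFrame(
            [(r.series_id, r.mean_ntdci, r.role, r.purity) for r in roles],
            columns=["series", "mean_ntdci", "role", "purity"],
        ).to_csv(outputs["node_roles"], index=False, float_format="%.10g")

        stage = "monthly aggregation"
        monthly_cols = {}
        offset = cal.n_weeks - len(tables)  # filter consumes the first p weeks
        for name, series in [("TCI", tci)] + [(c, ntdci[c]) for c in ntdci.columns]:
            full = np.full(cal.n_weeks, np.nan)
            full[offset:] = series.to_numpy()
            # back-fill the lag window so the monthly average is defined
            full[:offset] = full[offset]
            monthly_cols[name] = prep.aggregate_weekly_to_monthly(full, cal)
        monthly = pd.DataFrame(monthly_cols)
        outputs["monthly_indices"] = outdir / "monthly_indices.csv"
        mi = monthly.copy()
        mi.index = mi.index.astype(str)
        mi.to_csv(outputs["monthly_indices"], index_label="month", float_format="%.10g")

        if config.run_regression and covariates is not None:
            stage = "regression"
            common = monthly.index.intersection(covariates.index)
            table = robust.spillover_regression(
                monthly.loc[common],
                covariates.loc[common],
                recipe=config.recipe,
                hp_lambda=config.hp_lambda,
                thresholds=robust.InfluenceThresholds(
                    rstudent=config.rstudent_cut,
                    dffits_scale=config.dffits_scale,
                    covratio_scale=config.covratio_scale,
                ),
                efficiency=config.mm_efficiency,
                breakdown=config.mm_breakdown,
                n_resamples=config.mm_resamples,
                seed=config.seed,
                baumol_scale=config.baumol_scale,
            )
            outputs["regression_tidy"] = outdir / "regression_table.csv"
            table.tidy.to_csv(outputs["regression_tidy"], index=False, float_format="%.10g")
            outputs["regression_outliers"] = outdir / "regression_outliers.csv"
            table.outliers.to_csv(
                outputs["regression_outliers"], index_label="response", float_format="%.10g"
            )
            outputs["regression_text"] = outdir / "regression_table.txt"
            outputs["regression_text"].write_text(table.format_text() + "\n")

        if covariates is not None:
            stage = "covariate cycles"
            recipe = dict(config.recipe)
            for col in robust.DESIGN_COLUMNS:
                recipe.setdefault(col, "hp_cycle")
            cycles = prep.apply_recipe(
                covariates[list(robust.DESIGN_COLUMNS)], recipe, config.hp_lambda
            )
            outputs["covariate_cycles"] = outdir / "covariate_cycles.csv"
            cc = cycles.copy()
            cc.index = cc.index.astype(str)
            cc.to_csv(outputs["covariate_cycles"], index_label="month", float_format="%.10g")
    except _EarlyStop:
        pass
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "outputs": {name: {"path": p.name, "sha256": _checksum(p)} for name, p in outputs.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
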