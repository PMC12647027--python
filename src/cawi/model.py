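"""Model/Results interface for the CAWI validation pipeline.

:class:`CAWIValidation` is built from a hospital-year panel (a DataFrame, a
CSV, or the synthetic generator) and a :class:`RunConfig`; its :meth:`fit`
runs the full comparative battery — indicator derivation, quintile group
summaries, normality gatekeeping, the variance F-test of GR against CAWI,
Spearman correlations of CMI and LOS with GR, per-control-variable
correlation comparisons (Fisher z and/or Steiger z), univariate Huber
regressions of both indicators on every control variable, and residual
diagnostics — and returns a :class:`CAWIValidationResults` that serializes
losslessly to JSON and renders a text summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import indices, io, simulate, stratify
from . import stats as cstats

__all__ = ["RunConfig", "CAWIValidation", "CAWIValidationResults"]

logger = logging.getLogger(__name__)

#: Controls entering the correlation comparison (continuous only).
CORRELATION_CONTROLS = ("icu_patients", "mdr_incidence", "inpatients")
#: Controls entering the robust regressions (includes the binary flag).
REGRESSION_CONTROLS = ("icu_patients", "mdr_incidence", "inpatients", "educational")


@dataclass(frozen=True)
class RunConfig:
    """Options governing a validation run."""

    aggregation: str = "institution_mean"  # or "pooled"
    control_variables: tuple[str, ...] = REGRESSION_CONTROLS
    comparison: str = "fisher"  # "fisher" | "steiger" | "both"
    weight_function: str = "huber"
    tuning_c: float = cstats.HUBER_C
    tol: float = 1e-8
    max_iter: int = 50
    regression_mode: str = "univariate"  # or "multivariable"
    alpha: float = 0.05
    leap_aware: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.control_variables) - set(REGRESSION_CONTROLS)
        if unknown:
            raise ValueError(f"unknown control variables: {sorted(unknown)}")
        if self.comparison not in ("fisher", "steiger", "both"):
            raise ValueError(f"unknown comparison mode: {self.comparison!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["control_variables"] = list(self.control_variables)
        return d


class CAWIValidation:
    """Comparative validation of CAWI against the raw generation rate.

    Parameters
    ----------
    panel : DataFrame
        Hospital-year records (schema of :data:`cawi.simulate.PANEL_COLUMNS`).
    config : RunConfig, optional
    drg_table : DataFrame, optional
        DRG case table; when given, CMI is recomputed from it.
    """

    def __init__(
        self,
        panel: pd.DataFrame,
        config: RunConfig | None = None,
        drg_table: pd.DataFrame | None = None,
    ):
        self.config = config or RunConfig()
        self.config.validate()
        indices.validate_panel(panel)
        self.panel = panel
        self.drg_table = drg_table

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, **config_kwargs) -> "CAWIValidation":
        return cls(panel, RunConfig(**config_kwargs))

    @classmethod
    def from_csv(
        cls, path: str | Path, drg_path: str | Path | None = None, **config_kwargs
    ) -> "CAWIValidation":
        panel = io.read_panel_csv(path)
        drg = io.read_drg_csv(drg_path) if drg_path else None
        return cls(panel, RunConfig(**config_kwargs), drg_table=drg)

    @classmethod
    def from_synthetic(
        cls, params: simulate.GeneratorParams | None = None, seed: int = 0, **config_kwargs
    ) -> "CAWIValidation":
        if params is None:
            params = simulate.default_params(seed=seed)
        panel, _ = simulate.generate_panel(params)
        config_kwargs.setdefault("seed", params.seed)
        return cls(panel, RunConfig(**config_kwargs))

    # ------------------------------------------------------------------
    def fit(self) -> "CAWIValidationResults":
        """Run every stage of the validation battery, in order."""
        cfg = self.config
        records = indices.compute_index_records(
            self.panel, cfg.aggregation, self.drg_table, cfg.leap_aware
        )
        inst_records = (
            records
            if cfg.aggregation == "institution_mean"
            else indices.compute_index_records(
                self.panel, "institution_mean", self.drg_table, cfg.leap_aware
            )
        )
        if len(inst_records) < 5:
            raise ValueError(
                f"stratification stage: needs >= 5 institutions, got {len(inst_records)}"
            )

        grouping = stratify.assign_quintile_groups(inst_records)
        group_summaries, overall_sd = stratify.summarize_groups(inst_records, grouping)

        normality = {
            name: cstats.shapiro_wilk(records[name]).to_dict()
            for name in ("gr", "cmi", "los", "cawi")
        }
        variance_test = cstats.variance_f_test(records["gr"], records["cawi"])

        indicator_correlations = {
            "cmi_vs_gr": cstats.spearman(records["cmi"], records["gr"]).to_dict(),
            "los_vs_gr": cstats.spearman(records["los"], records["gr"]).to_dict(),
        }

        r_gr_cawi = cstats.spearman(records["gr"], records["cawi"]).rho
        corr_rows = []
        for ctrl in CORRELATION_CONTROLS:
            if ctrl not in cfg.control_variables:
                continue
            c_gr = cstats.spearman(records[ctrl], records["gr"])
            c_cawi = cstats.spearman(records[ctrl], records["cawi"])
            row = {
                "control": ctrl,
                "n": c_gr.n,
                "rho_gr": c_gr.rho,
                "p_gr": c_gr.p_value,
                "rho_cawi": c_cawi.rho,
                "p_cawi": c_cawi.p_value,
            }
            if cfg.comparison in ("fisher", "both"):
                t = cstats.fisher_z_compare(c_cawi.rho, c_cawi.n, c_gr.rho, c_gr.n)
                row["fisher_z"] = t.statistic
                row["fisher_p"] = t.p_value
            if cfg.comparison in ("steiger", "both"):
                t = cstats.steiger_compare_dependent(
                    c_cawi.rho, c_gr.rho, r_gr_cawi, c_gr.n
                )
                row["steiger_z"] = t.statistic
                row["steiger_p"] = t.p_value
            corr_rows.append(row)

        reg_rows = []
        residual_series = {}
        controls = [c for c in REGRESSION_CONTROLS if c in cfg.control_variables]
        for indicator in ("gr", "cawi"):
            if cfg.regression_mode == "multivariable":
                fits = [(",".join(controls), records[list(controls)])]
            else:
                fits = [(ctrl, records[[ctrl]]) for ctrl in controls]
            for label, design in fits:
                fit = cstats.huber_regression(
                    design,
                    records[indicator],
                    tuning_c=cfg.tuning_c,
                    max_iter=cfg.max_iter,
                    tol=cfg.tol,
                    weight_function=cfg.weight_function,
                )
                diag = cstats.residual_diagnostics(fit)
                for name in fit.params.index:
                    if name == "const":
                        continue
                    reg_rows.append(
                        {
                            "indicator": indicator,
                            "control": name if cfg.regression_mode == "multivariable" else label,
                            "coefficient": fit.params[name],
                            "se": fit.bse[name],
                            "p_value": fit.p_values[name],
                            "converged": fit.converged,
                            "n_iter": fit.n_iter,
                            "scale": fit.scale,
                            "residual_sd": diag.residual_sd,
                            "spread_slope": diag.spread_slope,
                        }
                    )
                if not fit.converged:
                    logger.warning(
                        "robust regression %s ~ %s did not converge", indicator, label
                    )
                residual_series[(indicator, label)] = (diag.fitted, diag.resid)

        manifest = {
            "config": cfg.to_dict(),
            "seed": cfg.seed,
            "package_version": _version,
            "n_records": int(len(records)),
            "n_institutions": int(len(inst_records)),
        }
        return CAWIValidationResults(
            model=self,
            records=records,
            group_summaries=group_summaries,
            overall_sd=overall_sd,
            normality=normality,
            variance_test=variance_test,
            indicator_correlations=indicator_correlations,
            control_correlations=pd.DataFrame(corr_rows),
            regressions=pd.DataFrame(reg_rows),
            residuals=residual_series,
            manifest=manifest,
        )


@dataclass
class CAWIValidationResults:
    """Fitted validation battery: every table and figure analogue of a run."""

    model: CAWIValidation = field(repr=False)
    records: pd.DataFrame = field(repr=False)
    group_summaries: list = field(repr=False)
    overall_sd: dict
    normality: dict
    variance_test: cstats.TestResult
    indicator_correlations: dict
    control_correlations: pd.DataFrame
    regressions: pd.DataFrame
    residuals: dict = field(repr=False)
    manifest: dict = field(repr=False)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        residuals = {
            f"{ind}~{ctrl}": {
                "fitted": [float(v) for v in fitted],
                "resid": [float(v) for v in resid],
            }
            for (ind, ctrl), (fitted, resid) in self.residuals.items()
        }
        return {
            "manifest": self.manifest,
            "group_summaries": [dataclasses.asdict(s) for s in self.group_summaries],
            "overall_sd": self.overall_sd,
            "normality": self.normality,
            "variance_test": self.variance_test.to_dict(),
            "indicator_correlations": self.indicator_correlations,
            "control_correlations": self.control_correlations.to_dict(orient="records"),
            "regressions": self.regressions.to_dict(orient="records"),
            "residuals": residuals,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, outdir: str | Path, plots: bool = False) -> None:
        """Write report.json plus one CSV per table analogue (and optional plots)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        stratify.summaries_to_frame(self.group_summaries).to_csv(
            outdir / "group_summaries.csv", index=False
        )
        self.control_correlations.to_csv(outdir / "control_correlations.csv", index=False)
        self.regressions.to_csv(outdir / "regressions.csv", index=False)
        rows = []
        for (ind, ctrl), (fitted, resid) in self.residuals.items():
            rows.append(
                pd.DataFrame(
                    {"indicator": ind, "control": ctrl, "fitted": fitted, "resid": resid}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(outdir / "residuals.csv", index=False)
        if plots:
            self.plot_residuals(outdir / "residuals.png")

    def plot_residuals(self, path: str | Path | None = None):
        """Side-by-side residual scatter of the GR and CAWI regression models."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=False)
        for ax, indicator in zip(axes, ("gr", "cawi")):
            for (ind, ctrl), (fitted, resid) in self.residuals.items():
                if ind == indicator:
                    ax.scatter(fitted, resid, s=12, alpha=0.6, label=ctrl)
            ax.axhline(0.0, color="k", lw=0.8)
            ax.set_title(f"{indicator.upper()} model residuals")
            ax.set_xlabel("fitted")
            ax.set_ylabel("residual")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable run summary (group table, tests, regressions)."""
        lines = [
            "CAWI validation summary",
            "=" * 70,
            f"institutions: {self.manifest['n_institutions']}  "
            f"records: {self.manifest['n_records']}  "
            f"aggregation: {self.manifest['config']['aggregation']}",
            "",
            "Group summaries (quintiles by bed capacity):",
            stratify.summaries_to_frame(self.group_summaries).round(4).to_string(index=False),
            "",
            f"overall SD: GR {self.overall_sd['gr_sd']:.4f}  "
            f"CAWI {self.overall_sd['cawi_sd']:.4f}",
            f"variance F-test GR vs CAWI: F = {self.variance_test.statistic:.3f}, "
            f"p = {self.variance_test.p_value:.3g}",
            "",
            "Spearman with GR: "
            + "  ".join(
                f"{k.split('_vs_')[0].upper()} rho = {v['rho']:.3f} (p = {v['p_value']:.3g})"
                for k, v in self.indicator_correlations.items()
            ),
            "",
            "Correlation comparison (CAWI vs GR) per control variable:",
            self.control_correlations.round(4).to_string(index=False),
            "",
            "Robust regressions (univariate per control):",
            self.regressions.drop(columns=["spread_slope"]).to_string(index=False),
        ]
        return "\n".join(lines)
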