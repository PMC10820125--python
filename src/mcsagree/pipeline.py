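"""One-command analysis pipeline: data -> full report battery.

Stage order is fixed: explore -> mixed-model fits and selection ->
agreement -> similarity/repeatability -> optional measurement-error
track -> optional recalibration.  Every stage writes its table analogue
as CSV into the output directory, and a plain-text run log records the
seed, package version, stage progress and convergence flags.  A failing
stage aborts with the stage name while earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement import MagnitudeGrid, agreement_profile, recalibrate_fixed_bias
from .datasets import LINKED, MCSDataset, design_summary, read_long
from .disagreement import repeatability_table, similarity
from .errors import MCSError
from .explore import bland_altman, extended_ba, interaction_summary, trellis_data
from .measurement_error import bias_profile, fit_me, precision_profile
from .mixed_model import ModelSpec, fit, select
from .simulate import SimConfig, simulate


class PipelineError(MCSError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_csv: str | None = None
    schema: dict = field(default_factory=dict)
    method_labels: tuple[str, str] | None = None
    linkage: str = LINKED
    sim: SimConfig | None = None
    covariates: tuple[str, ...] = ()
    p: float = 0.9
    grid_n: int = 20
    recalibrate: bool = False
    me_track: bool = False
    seed: int = 0
    outdir: str = "mcs_report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sim" in d and d["sim"] is not None:
            sim = d["sim"]
            for k in ("cluster_weights", "cluster_means", "cluster_sds",
                      "sigma_e2", "delta", "me_mode"):
                if isinstance(sim.get(k), list):
                    sim[k] = tuple(sim[k])
            d["sim"] = SimConfig(**sim)
        for k in ("method_labels", "covariates"):
            if isinstance(d.get(k), list):
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class ReportBundle:
    outdir: Path
    tables: dict
    fits: dict
    log_lines: list


def _write(outdir: Path, name: str, frame: pd.DataFrame, tables: dict) -> None:
    frame.to_csv(outdir / f"{name}.csv", index=False)
    tables[name] = frame


def run_pipeline(config: RunConfig) -> ReportBundle:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict = {}
    fits: dict = {}
    log: list[str] = [f"mcsagree {__version__}", f"seed {config.seed}"]
    stage = "load_data"
    try:
        if config.input_csv is not None:
            ds = read_long(config.input_csv, schema=config.schema or None,
                           linkage=config.linkage,
                           method_labels=config.method_labels)
            log.append(f"loaded {config.input_csv}: {ds!r} "
                       f"({ds.n_dropped} rows dropped)")
        elif config.sim is not None:
            ds = simulate(config.sim, seed=config.seed)
            log.append(f"simulated dataset: {ds!r}")
        else:
            raise MCSError("run config names neither input_csv nor sim")

        stage = "design_summary"
        summ = design_summary(ds)
        _write(outdir, "design_summary",
               summ.per_method_summary.reset_index(names="method"), tables)
        log.append(f"design: {summ.n_subjects} subjects, "
                   f"balanced={summ.balanced}")

        stage = "explore"
        ba, trend = extended_ba(ds)
        _write(outdir, "ba_pairs", ba.pairs, tables)
        _write(outdir, "ba_summary", pd.DataFrame([{
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_lo": ba.loa[0], "loa_hi": ba.loa[1],
            "trend_slope": ba.trend_slope, "trend_pvalue": ba.trend_pvalue,
            "trend_present": trend}]), tables)
        _write(outdir, "trellis", trellis_data(ds).rows, tables)
        inter = interaction_summary(ds)
        _write(outdir, "interaction_method",
               inter.method_profiles.reset_index(), tables)
        log.append(f"extended BA trend present: {trend}; "
                   f"method-profile crossings: {inter.method_crossings}")

        stage = "mixed_model"
        base = ModelSpec(linkage="unlinked", heteroscedastic=False)
        fits["homoscedastic"] = fit(ds, base)
        fits["heteroscedastic"] = fit(
            ds, dataclasses.replace(base, heteroscedastic=True))
        candidates = [fits["homoscedastic"], fits["heteroscedastic"]]
        if config.covariates:
            fits["heteroscedastic+covariates"] = fit(
                ds, dataclasses.replace(base, heteroscedastic=True,
                                        covariate_names=tuple(config.covariates)))
            candidates.append(fits["heteroscedastic+covariates"])
        sel = select(candidates)
        _write(outdir, "model_selection", sel.table, tables)
        best = sel.preferred
        for f in candidates:
            if f.notes:
                log.extend(f"note: {n}" for n in f.notes)
        log.append(f"preferred model: {sel.table.iloc[0]['model']} "
                   f"(AIC {best.aic:.3f}, converged={best.converged})")
        _write(outdir, "fit_summary", best.summary_table(), tables)

        stage = "agreement"
        grid = MagnitudeGrid.from_fit(best, n=config.grid_n)
        profile = agreement_profile(best, grid, p=config.p)
        _write(outdir, "agreement_profile", profile.table, tables)

        stage = "disagreement_sources"
        sim_res = similarity(best, grid)
        sim_tab = sim_res.precision_ratio.copy()
        sim_tab["fixed_bias"] = sim_res.fixed_bias
        sim_tab["fixed_bias_lo"] = sim_res.fixed_bias_ci[0]
        sim_tab["fixed_bias_hi"] = sim_res.fixed_bias_ci[1]
        _write(outdir, "similarity", sim_tab, tables)
        _write(outdir, "repeatability",
               repeatability_table(best, grid, p=config.p), tables)

        if config.me_track:
            stage = "measurement_error"
            mefit = fit_me(ds, seed=config.seed)
            log.append(f"ME track: alpha={mefit.alpha:.4f} "
                       f"beta={mefit.beta:.4f}")
            _write(outdir, "me_bias", bias_profile(mefit, grid), tables)
            _write(outdir, "me_precision", precision_profile(mefit, grid),
                   tables)

        if config.recalibrate:
            stage = "recalibration"
            _, refit, reprofile = recalibrate_fixed_bias(ds, best, grid,
                                                         p=config.p)
            fits["recalibrated"] = refit
            _write(outdir, "recalibrated_profile", reprofile.table, tables)
            log.append(f"recalibrated fixed bias: {refit.beta0:+.5f}")

        stage = "finish"
        log.append("pipeline completed")
    except Exception as exc:
        log.append(f"FAILED in stage {stage}: {exc}")
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
        raise PipelineError(stage, exc) from exc
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return ReportBundle(outdir=outdir, tables=tables, fits=fits, log_lines=log)
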