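"""End-to-end pipeline: simulate -> preprocess -> drift fits -> reliability
-> validity, with a self-describing JSON report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as prep
from . import reliability as rel
from . import validity as val
from .irt import DiffusionIRT
from .simulate import (StudyDesign, GeneratorParams, simulate_study,
                       attach_traits, inject_artifacts, simulate_symbol_search,
                       write_study)

log = logging.getLogger("emaclarity")

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError", "ConvergenceError"]

INDICATORS = ["na_drift", "pa_drift", "na_rt", "pa_rt"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class ConvergenceError(RuntimeError):
    """A model stage failed to converge."""


@dataclass
class PipelineConfig:
    ema_path: str | None = None
    symbol_path: str | None = None
    traits_path: str | None = None
    out_dir: str = "emaclarity_out"
    simulate: bool = False            # generate inputs instead of reading them
    n_persons: int = 196
    n_days: int = 14
    rt_min: float = prep.RT_MIN
    rt_max: float = prep.RT_MAX
    dichot_rule: str = "scale_midpoint"
    ter_policy: str = "occasion_min"
    quadrature_nodes: int = 15
    reliability_threshold: float = 0.70
    reliability_n_max: int = 70
    adjust_processing_speed: bool = False
    fdr: bool = True
    run_validity: bool = True
    seed: int = 0

    def validate(self):
        if not 0 < self.rt_min < self.rt_max:
            raise ConfigError("need 0 < rt_min < rt_max")
        if not 0 < self.reliability_threshold < 1:
            raise ConfigError("reliability_threshold must be in (0, 1)")
        if self.dichot_rule not in ("scale_midpoint", "person_mean"):
            raise ConfigError(f"unknown dichot_rule {self.dichot_rule!r}")
        if self.ter_policy not in ("occasion_min", "global"):
            raise ConfigError(f"unknown ter_policy {self.ter_policy!r}")
        if not self.simulate and self.ema_path is None:
            raise ConfigError("either set simulate=true or provide ema_path")
        if self.run_validity and not self.simulate and self.traits_path is None:
            raise ConfigError("validity testing requested but no traits file given")

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        design = StudyDesign(n_persons=cfg.n_persons, n_days=cfg.n_days)
        ema, truth = simulate_study(design, seed=cfg.seed)
        ema, _ = inject_artifacts(ema, seed=cfg.seed + 1)
        traits = attach_traits(truth, seed=cfg.seed + 2)
        symbol = simulate_symbol_search(truth, seed=cfg.seed + 3)
        return ema, traits, symbol
    ema = prep.read_ema_csv(cfg.ema_path)
    traits = pd.read_csv(cfg.traits_path) if cfg.traits_path else None
    symbol = pd.read_csv(cfg.symbol_path) if cfg.symbol_path else None
    return ema, traits, symbol


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write CSV outputs plus a JSON summary.

    Any stage failure raises with the stage name; partial outputs written
    before the failure are preserved in ``cfg.out_dir``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {"config": asdict(cfg), "config_hash": cfg.config_hash(),
                     "seed": cfg.seed, "stages": {}}

    stage = "load"
    try:
        ema, traits, symbol = _load_inputs(cfg)
        if cfg.simulate:
            ema.to_csv(out / "ema.csv", index=False)
            if traits is not None:
                traits.to_csv(out / "traits.csv", index=False)

        stage = "preprocess"
        ind, cov, report = prep.build_indicators(ema, dichot_rule=cfg.dichot_rule)
        if symbol is not None:
            ps = prep.processing_speed(symbol)
            cov = cov.merge(ps, on="person_id", how="left")
        ind.to_csv(out / "indicators.csv", index=False)
        cov.to_csv(out / "person_covariates.csv", index=False)
        summary["stages"]["preprocess"] = {
            "n_occasions": int(len(ind)),
            "rt_excluded_n": report.n_flagged,
            "rt_excluded_pct": report.percent,
        }

        stage = "fit_drift"
        df = prep.to_seconds(ema)
        df, _ = prep.filter_rts(df, lo=cfg.rt_min, hi=cfg.rt_max)
        aff = df[df["valence"].isin(["NA", "PA"])]
        aff = prep.dichotomize(aff, rule=cfg.dichot_rule)
        drift_scores = {}
        fit_info = {}
        for valence in ("NA", "PA"):
            mod = DiffusionIRT.from_dataframe(
                aff, valence, ter_policy=cfg.ter_policy,
                quadrature_nodes=cfg.quadrature_nodes)
            res = mod.fit(seed=cfg.seed)
            if not res.converged:
                raise ConvergenceError(f"{valence} drift model did not converge")
            sc = res.eap_scores()
            sc.to_csv(out / f"drift_scores_{valence.lower()}.csv", index=False)
            res.item_table().to_csv(out / f"drift_items_{valence.lower()}.csv",
                                    index=False)
            drift_scores[valence] = sc
            fit_info[valence] = {"llf": res.llf, "aic": res.aic, "bic": res.bic,
                                 "converged": res.converged,
                                 "sd_theta": res.sd_theta,
                                 "mu_logalpha": res.mu_logalpha}
        summary["stages"]["fit_drift"] = fit_info

        stage = "merge_scores"
        keys = ["person_id", "occasion_id"]
        occ = ind.merge(drift_scores["NA"][keys + ["log_ad"]]
                        .rename(columns={"log_ad": "na_drift"}),
                        on=keys, how="left")
        occ = occ.merge(drift_scores["PA"][keys + ["log_ad"]]
                        .rename(columns={"log_ad": "pa_drift"}),
                        on=keys, how="left")
        occ.to_csv(out / "occasion_scores.csv", index=False)

        stage = "reliability"
        rel_rows, curve_rows, n_min = [], [], {}
        for name in INDICATORS:
            vc = rel.variance_components(occ[name], occ["person_id"], name)
            curve = rel.reliability_curve(vc, n_max=cfg.reliability_n_max,
                                          threshold=cfg.reliability_threshold)
            rel_rows.append({"indicator": name, "var_between": vc.var_between,
                             "var_within": vc.var_within, "icc": vc.icc,
                             "n_persons": vc.n_persons,
                             "n_occasions": vc.n_occasions_total,
                             "n_min": curve.n_min})
            for n, r in zip(curve.n_grid, curve.rel):
                curve_rows.append({"indicator": name, "n": int(n), "rel": r})
            n_min[name] = curve.n_min
        pd.DataFrame(rel_rows).to_csv(out / "variance_components.csv", index=False)
        pd.DataFrame(curve_rows).to_csv(out / "reliability_curves.csv", index=False)
        summary["stages"]["reliability"] = {"n_min_070": n_min}

        if cfg.run_validity and traits is not None:
            stage = "validity"
            scores = None
            for name in INDICATORS:
                s = val.person_scores(occ, name).rename(columns={"score": name})
                s = s[["person_id", name]]
                scores = s if scores is None else scores.merge(s, on="person_id",
                                                               how="outer")
            scores = scores.merge(cov, on="person_id", how="left")
            covs = ["base_speed"]
            if cfg.adjust_processing_speed and "proc_speed" in scores:
                covs.append("proc_speed")
            table = val.validity_table(scores, traits, INDICATORS,
                                       covariate_cols=covs, fdr=cfg.fdr)
            scores.to_csv(out / "person_scores.csv", index=False)
            table.to_csv(out / "validity_results.csv", index=False)
            summary["stages"]["validity"] = {
                "n_tests": int(len(table)),
                "n_sig_05": int((table["p"] < 0.05).sum()),
            }
    except (ConfigError, ConvergenceError):
        raise
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float))
    log.info("pipeline finished in %.1f s; outputs in %s",
             summary["elapsed_s"], out)
    return summary
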