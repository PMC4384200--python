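"""Config-driven pipeline orchestration.

A run is described by one YAML file and materialized as an artifact
directory with conventional filenames.  Stages run in dependency order
(synth -> preprocess -> trends -> pls -> fit -> cv -> predict); each
stage reads only earlier stages' outputs and never mutates them, so a
run is resumable stage by stage and byte-identical when repeated with
the same config.  Every JSON artifact records the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as prep
from .data_model import STDataset, read_dataset, write_dataset
from .evaluation import model_selection_grid, r2_temporally_adjusted, stratified_cv
from .pls_features import build_feature_set
from .prediction import long_term_average, predict
from .st_model import ModelParams, ModelStructure, fit_ml
from .synthetic import ScenarioConfig, TrueParams, generate_campaign, small_scenario
from .trend_basis import estimate_trend_basis

log = logging.getLogger("stfield")

STAGES = ("synth", "preprocess", "trends", "pls", "fit", "cv", "select", "predict")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "out_dir" not in cfg:
        raise ValueError("run config must be a mapping with an 'out_dir' key")
    for key in cfg.get("stages", []):
        if key not in STAGES:
            raise ValueError(f"unknown stage {key!r}; valid: {STAGES}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _dump_json(path: Path, obj: dict, cfg_hash: str) -> None:
    obj = dict(obj)
    obj["config_hash"] = cfg_hash
    path.write_text(json.dumps(obj, indent=2, default=str))


class PipelineRun:
    """One region-pollutant run rooted at ``cfg['out_dir']``."""

    def __init__(self, cfg: dict):
        self.cfg = cfg
        self.hash = config_hash(cfg)
        self.out = Path(cfg["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(cfg.get("seed", 0))

    # -- stage: synth ------------------------------------------------------
    def stage_synth(self) -> None:
        sc = dict(self.cfg.get("scenario", {}))
        use_small = sc.pop("small", False)
        tp = sc.pop("true_params", None)
        if tp:
            sc["true_params"] = TrueParams(**tp)
        sc.setdefault("seed", self.seed)
        config = small_scenario(**sc) if use_small else ScenarioConfig(**sc)
        data, truth = generate_campaign(config)
        # emit raw-looking (original scale) observations for preprocess
        raw = STDataset(
            data.sites, data.axis,
            data.obs.assign(value=np.exp(data.obs["value"])),
            scale="original", units=data.units,
        )
        d = self.out / "synth"
        write_dataset(raw, d)
        truth["covariates"].to_csv(d / "covariates_all.csv")
        pd.DataFrame(
            {
                "location_id": truth["holdout_ids"],
                "x_km": truth["holdout_coords"][:, 0],
                "y_km": truth["holdout_coords"][:, 1],
                "true_lta": truth["holdout_lta"],
            }
        ).to_csv(d / "holdout_truth.csv", index=False)
        _dump_json(
            d / "truth.json",
            {
                "m_true": config.m_true,
                "beta_specs": [dataclasses.asdict(b) for b in truth["beta_specs"]],
                "residual": dataclasses.asdict(truth["residual"]),
                "n_below_lod": truth["n_below_lod"],
                "n_sites": len(data.sites),
                "n_obs": len(data.obs),
            },
            self.hash,
        )
        log.info("synth: %d sites, %d observations", len(data.sites), len(data.obs))

    # -- stage: preprocess -------------------------------------------------
    def stage_preprocess(self) -> None:
        pcfg = self.cfg.get("preprocess", {})
        raw = read_dataset(self.out / "synth")
        report = prep.FilterReport()
        data, report = prep.filter_monitors(
            raw,
            min_years=float(pcfg.get("min_years", 2.0)),
            min_quarter_frac=float(pcfg.get("min_quarter_frac", 0.10)),
            report=report,
        )
        cov = pd.read_csv(self.out / "synth" / "covariates_all.csv",
                          dtype={"site_id": str}).set_index("site_id")
        monitor_ids = set(data.site_ids)
        prep.filter_covariates(
            cov,
            monitor_ids=monitor_ids,
            participant_ids=set(cov.index) - monitor_ids,
            landuse_names=set(pcfg.get("landuse_names", [])),
            report=report,
        )
        cov_kept = prep.apply_covariate_filter(cov, report)
        data = prep.log_transform(data)
        d = self.out / "clean"
        write_dataset(data, d)
        cov_kept.to_csv(d / "covariates_all.csv")
        _dump_json(d / "filter_report.json", report.to_dict(), self.hash)
        log.info("preprocess: kept %d sites, %d covariates",
                 len(data.sites), cov_kept.shape[1])

    # -- shared loaders ----------------------------------------------------
    def _clean(self) -> tuple[STDataset, pd.DataFrame]:
        data = read_dataset(self.out / "clean")
        cov = pd.read_csv(self.out / "clean" / "covariates_all.csv",
                          dtype={"site_id": str}).set_index("site_id")
        return data, cov

    def _basis(self, data: STDataset):
        tcfg = self.cfg.get("trends", {})
        return estimate_trend_basis(
            data, m=int(tcfg.get("m", 1)), df_per_year=int(tcfg.get("df_per_year", 4))
        )

    def _structure(self, m: int) -> ModelStructure:
        mcfg = self.cfg.get("model", {})
        b0 = "exponential" if mcfg.get("beta0_smoothing", True) else "independent"
        bi = "exponential" if mcfg.get("betai_smoothing", False) else "independent"
        return ModelStructure(
            beta_kinds=[b0] + [bi] * m,
            residual_nugget=bool(mcfg.get("residual_nugget", True)),
            time_effect=bool(mcfg.get("time_effect", True)),
        )

    # -- stage: trends -----------------------------------------------------
    def stage_trends(self) -> None:
        data, _ = self._clean()
        basis = self._basis(data)
        basis.to_frame().to_csv(self.out / "trends.csv", index=False)
        _dump_json(
            self.out / "trend_meta.json",
            {
                "m": basis.m,
                "df_per_year": basis.df_per_year,
                "source_sites": basis.source_sites,
                "singular_values": list(map(float, basis.singular_values)),
            },
            self.hash,
        )

    # -- stage: pls --------------------------------------------------------
    def stage_pls(self) -> None:
        data, cov = self._clean()
        basis = self._basis(data)
        n_comp = int(self.cfg.get("pls", {}).get("n_scores", 2))
        features = build_feature_set(data, basis, cov.loc[data.site_ids], n_comp)
        rows = []
        for i, X in enumerate(features.designs):
            for j, sid in enumerate(features.site_ids):
                rows.append(
                    {"site_id": sid, "trend_index": i,
                     **{f"comp_{k}": X[j, k + 1] for k in range(n_comp)}}
                )
        pd.DataFrame(rows).to_csv(self.out / "pls_scores.csv", index=False)
        _dump_json(
            self.out / "pls_model.json",
            {"models": [m.to_dict() for m in features.models]},
            self.hash,
        )

    def _features(self, data: STDataset, cov: pd.DataFrame):
        basis = self._basis(data)
        n_comp = int(self.cfg.get("pls", {}).get("n_scores", 2))
        return basis, build_feature_set(data, basis, cov.loc[data.site_ids], n_comp)

    # -- stage: fit --------------------------------------------------------
    def stage_fit(self) -> None:
        data, cov = self._clean()
        basis, features = self._features(data, cov)
        structure = self._structure(basis.m)
        params = fit_ml(data, basis, features, structure, seed=self.seed)
        out = params.to_dict()
        out["structure"] = dataclasses.asdict(structure)
        _dump_json(self.out / "model_params.json", out, self.hash)
        log.info("fit: loglik %.2f", params.loglik)

    # -- stage: cv ---------------------------------------------------------
    def stage_cv(self) -> None:
        data, cov = self._clean()
        basis, features = self._features(data, cov)
        structure = self._structure(basis.m)
        ccfg = self.cfg.get("cv", {})
        reports = stratified_cv(
            data, basis, features, structure,
            seed=int(ccfg.get("seed", self.seed)),
            strata=tuple(ccfg.get("strata", ("long_series", "home", "snapshot"))),
        )
        for name, rep in reports.items():
            if name == "home":
                for ref in ("avg", "close", "smooth"):
                    try:
                        r2_temporally_adjusted(rep, data, basis, ref)
                    except ValueError:
                        pass
        _dump_json(
            self.out / "cv_report.json",
            {name: rep.to_dict() for name, rep in reports.items()},
            self.hash,
        )
        pd.concat(
            [rep.table.assign(stratum=name) for name, rep in reports.items()]
        ).to_csv(self.out / "cv_report.csv", index=False)

    # -- stage: select -----------------------------------------------------
    def stage_select(self) -> None:
        data, cov = self._clean()
        scfg = self.cfg.get("select", {})
        table = model_selection_grid(
            data, cov.loc[data.site_ids],
            seed=int(scfg.get("seed", self.seed)),
            maxiter=int(scfg.get("maxiter", 150)),
            strata=tuple(scfg.get("strata", ("home", "long_series", "snapshot"))),
        )
        table.to_csv(self.out / "selection_table.csv", index=False)

    # -- stage: predict ----------------------------------------------------
    def stage_predict(self) -> None:
        data, cov = self._clean()
        basis, features = self._features(data, cov)
        pj = json.loads((self.out / "model_params.json").read_text())
        params = ModelParams.from_dict(pj)
        targets = pd.read_csv(self.out / "synth" / "holdout_truth.csv",
                              dtype={"location_id": str})
        tcov = cov.loc[targets["location_id"]]
        coords = targets[["x_km", "y_km"]].to_numpy(float)
        ps = predict(
            params, data, basis, features,
            list(targets["location_id"]), coords,
            target_covariates=tcov,
        )
        ps.to_frame().to_csv(self.out / "predictions.csv", index=False)
        pcfg = self.cfg.get("predict", {})
        d_from = date.fromisoformat(str(pcfg.get(
            "from", data.axis.period_starts[0].isoformat())))
        d_to = date.fromisoformat(str(pcfg.get(
            "to", data.axis.period_starts[-1].isoformat())))
        lta = long_term_average(ps, d_from, d_to)
        lta_df = lta.reset_index()
        lta_df["from"] = d_from.isoformat()
        lta_df["to"] = d_to.isoformat()
        lta_df.to_csv(self.out / "ltas.csv", index=False)

    def run(self, stages: list[str] | None = None) -> Path:
        stages = list(stages or self.cfg.get("stages", STAGES))
        for st in STAGES:
            if st in stages:
                log.info("stage: %s", st)
                getattr(self, f"stage_{st}")()
        return self.out


def run_pipeline(config: dict | str | Path, stages: list[str] | None = None) -> Path:
    cfg = load_config(config) if not isinstance(config, dict) else config
    return PipelineRun(cfg).run(stages)
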