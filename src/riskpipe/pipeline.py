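"""End-to-end orchestration: simulate -> outcomes -> cohorts -> encode ->
train -> ensemble -> evaluate, as one configured, logged, seeded run.

Stage seeds derive deterministically from the global seed, stage outputs are
cached on disk keyed by a config fingerprint (rerunning with an unchanged
config reuses intermediates; deleting one regenerates only downstream
stages), and a JSON-lines log records stage name, wall time, row counts and
seed.

The base-model census mirrors the reference workflow at desk scale: three
learners trained on the matched case-control cohort (L1 logistic, random
forest, feed-forward net; the attention-based tabular slot is reserved),
two Cox models trained on the event-triggered cohorts, and calendar-cohort
logistic models (an earlier-calendar model trained on each target outcome,
plus one on the target-calendar cohort). Two ensembles are fine-tuned on
the target calendar cohort: the combined-outcome ensemble excludes the
earlier-calendar suicide-trained base, and the suicide ensemble excludes
the earlier-calendar combined-trained base, keeping seven bases in each.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from riskpipe.synthetic_emr import PopulationConfig, generate_population
from riskpipe.outcomes import classify_events
from riskpipe.cohorts import (RccConfig, assign_dob_partitions, build_rcc,
                              build_calendar_cohort, build_event_cohort,
                              compute_outcomes)
from riskpipe.features import encode_cohort, WINDOW_DAYS
from riskpipe.models import FitError, LearnerConfig, even_odd_protocol
from riskpipe.ensemble import (ContractError, score_base_models, fit_ensemble,
                               apply_ensemble,
                               default_finetune_frame)
from riskpipe.metrics import (auroc, auprc, harrell_c, calibration,
                              concentration_of_risk, drift_eval)


@dataclass
class RunConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    n_partitions: int = 20
    controls_per_case: int = 4
    gap_days: int = 45
    early_date: str = "2015-01-01"     # C15 analogue
    target_date: str = "2017-01-01"    # C17 analogue
    drift_date: str = "2019-01-01"     # C19 analogue (drift scenario)
    lookback_months: float = 3
    exclusion_days: int = 7
    followup_years: float = 2
    rcc_kinds: tuple = ("glm-lasso", "random-forest", "neural-net")
    learner: LearnerConfig = field(default_factory=lambda: LearnerConfig(
        nn_hidden=(128, 64), rf_trees=200, nn_max_iter=40,
        glm_cv_folds=3, glm_n_lambda=12))
    include_cox: bool = True
    run_drift: bool = False
    qs: tuple = (0.01, 0.001)
    seed: int = 0
    out_dir: str = "riskpipe_run"

    def fingerprint(self, stage: str) -> str:
        payload = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(f"{stage}:{payload}".encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


class PipelineRun:
    """Cached stage-by-stage execution of a :class:`RunConfig`."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._log_path = self.out / "log.jsonl"
        self._manifest_path = self.out / "manifest.json"
        self._manifest = (json.loads(self._manifest_path.read_text())
                          if self._manifest_path.exists() else {})
        self._cache = {}

    # -- infrastructure -----------------------------------------------------
    def _log(self, stage, wall, **info):
        rec = {"stage": stage, "wall_s": round(wall, 2),
               "seed": self.config.stage_seed(stage), **info}
        with open(self._log_path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")

    def _stage(self, name, paths, builder, loader, saver):
        """Run/cache one stage. ``paths`` relative to out_dir."""
        fp = self.config.fingerprint(name)
        paths = [self.out / p for p in paths]
        if name in self._cache:
            return self._cache[name]
        if self._manifest.get(name) == fp and all(p.exists() for p in paths):
            obj = loader(paths)
            self._cache[name] = obj
            return obj
        t0 = time.time()
        obj = builder()
        saver(obj, paths)
        self._manifest[name] = fp
        self._manifest_path.write_text(json.dumps(self._manifest, indent=1))
        self._log(name, time.time() - t0)
        self._cache[name] = obj
        return obj

    # -- stages -------------------------------------------------------------
    def population(self):
        cfg = dataclasses.replace(self.config.population,
                                  seed=self.config.stage_seed("simulate"))

        def build():
            return generate_population(cfg)

        def save(pop, paths):
            with open(paths[0], "wb") as fh:
                pickle.dump(pop, fh)
            pop.to_dir(self.out / "population")

        def load(paths):
            with open(paths[0], "rb") as fh:
                return pickle.load(fh)

        return self._stage("simulate", ["population.pkl"], build, load, save)

    def component_events(self):
        pop = self.population()

        def build():
            return classify_events(pop.events, pop.deaths)

        return self._stage(
            "outcomes", ["component_events.csv"], build,
            lambda p: pd.read_csv(p[0], parse_dates=["date"]),
            lambda obj, p: obj.to_csv(p[0], index=False))

    def partitions(self):
        pop = self.population()
        return assign_dob_partitions(pop.patients, self.config.n_partitions)

    def cohorts(self) -> dict:
        cfg = self.config
        pop = self.population()
        comp = self.component_events()
        parts = self.partitions()

        def build():
            oc = compute_outcomes(pop)
            out = {"rcc": build_rcc(pop, oc, RccConfig(
                controls_per_case=cfg.controls_per_case, gap_days=cfg.gap_days,
                seed=cfg.stage_seed("rcc")), partitions=parts,
                calendar_range=cfg.population.calendar_range)}
            for tag, date in (("c15", cfg.early_date), ("c17", cfg.target_date)):
                for target in ("combined", "suicide"):
                    out[f"{tag}_{target}"] = build_calendar_cohort(
                        pop, comp, date, cfg.lookback_months, cfg.exclusion_days,
                        cfg.followup_years, target, parts, design_tag=tag.upper())
            if cfg.include_cox:
                out["coxmh"] = build_event_cohort(
                    pop, comp, "psychiatric-visit", partitions=parts,
                    calendar_range=cfg.population.calendar_range)
                out["coxvisit"] = build_event_cohort(
                    pop, comp, "office-visit", partitions=parts,
                    calendar_range=cfg.population.calendar_range)
            if cfg.run_drift:
                for target in ("combined", "suicide"):
                    out[f"c19_{target}"] = build_calendar_cohort(
                        pop, comp, cfg.drift_date, cfg.lookback_months,
                        cfg.exclusion_days, cfg.followup_years, target, parts,
                        design_tag="C19")
            return out

        def save(obj, paths):
            with open(paths[0], "wb") as fh:
                pickle.dump(obj, fh)
            for k, df in obj.items():
                df.to_csv(self.out / f"cohort_{k}.csv", index=False)

        def load(paths):
            with open(paths[0], "rb") as fh:
                return pickle.load(fh)

        return self._stage("cohorts", ["cohorts.pkl"], build, load, save)

    def features(self) -> dict:
        pop = self.population()
        cohorts = self.cohorts()

        def build():
            return {k: encode_cohort(df, pop) for k, df in cohorts.items()
                    if len(df)}

        def save(obj, paths):
            with open(paths[0], "wb") as fh:
                pickle.dump(obj, fh)

        def load(paths):
            with open(paths[0], "rb") as fh:
                return pickle.load(fh)

        return self._stage("encode", ["features.pkl"], build, load, save)

    def base_models(self) -> dict:
        cfg = self.config
        fms = self.features()

        def build():
            out = {}
            rcc = fms["rcc"]
            y = rcc.cohort["is_case"].to_numpy()
            even = rcc.cohort["even"].to_numpy()
            for kind in cfg.rcc_kinds:
                short = {"glm-lasso": "glm", "random-forest": "rf",
                         "neural-net": "nn", "naive-bayes": "nb"}[kind]
                out[f"rcc_{short}"] = even_odd_protocol(
                    kind, rcc, y, even, cfg.learner,
                    seed=cfg.stage_seed(f"train_rcc_{kind}"),
                    target_name="combined", cohort_tag="Rcc")
            if cfg.include_cox and "coxmh" in fms:
                for tag in ("coxmh", "coxvisit"):
                    fm = fms[tag]
                    t = fm.cohort["time_to_event_days"].to_numpy(dtype=float)
                    e = fm.cohort["is_case"].to_numpy(dtype=bool)
                    out[tag] = even_odd_protocol(
                        "cox", fm, (t, e), fm.cohort["even"].to_numpy(),
                        cfg.learner, seed=cfg.stage_seed(f"train_{tag}"),
                        target_name="combined", cohort_tag=tag)
            for name, key, target in (("c15_all", "c15_combined", "combined"),
                                      ("c15_ndi", "c15_suicide", "suicide"),
                                      ("c17_glm", "c17_combined", "combined")):
                fm = fms[key]
                y = fm.cohort["is_case"].to_numpy()
                try:
                    out[name] = even_odd_protocol(
                        "glm-lasso", fm, y, fm.cohort["even"].to_numpy(),
                        cfg.learner, seed=cfg.stage_seed(f"train_{name}"),
                        target_name=target, cohort_tag=key)
                except FitError as exc:
                    # too few cases at this scale: drop the base with a note,
                    # the way non-converging prospective models are dropped
                    self._log(f"train_{name}_skipped", 0.0, reason=str(exc))
            return out

        def save(obj, paths):
            with open(paths[0], "wb") as fh:
                pickle.dump(obj, fh)

        def load(paths):
            with open(paths[0], "rb") as fh:
                return pickle.load(fh)

        return self._stage("train", ["base_models.pkl"], build, load, save)

    def registry(self, target: str):
        """Seven-base registry for one ensemble target."""
        models = self.base_models()
        exclude = {"combined": "c15_ndi", "suicide": "c15_all"}[target]
        return [(name, res.final_model) for name, res in models.items()
                if name != exclude]

    def _target_score_matrix(self, target: str, fm) -> pd.DataFrame:
        """Base-score columns for the target cohort, leakage-safe.

        Transfer bases (matched, time-to-event, earlier-calendar designs)
        score the cohort with their final models — already out-of-sample.
        Bases trained on the target cohort itself contribute their
        out-of-half scores, so no row is scored by a model that saw it.
        """
        models = self.base_models()
        exclude = {"combined": "c15_ndi", "suicide": "c15_all"}[target]
        cols = {}
        for name, res in models.items():
            if name == exclude:
                continue
            if res.final_model.cohort_tag.startswith("c17"):
                cols[name] = res.scores  # same rows as every c17 cohort
            else:
                cols[name] = score_base_models(
                    [(name, res.final_model)], fm)[name].to_numpy()
        return pd.DataFrame(cols)

    def ensembles(self) -> dict:
        cfg = self.config
        pop = self.population()
        fms = self.features()

        def build():
            out = {}
            for target, key in (("combined", "c17_combined"),
                                ("suicide", "c17_suicide")):
                fm = fms[key]
                S = self._target_score_matrix(target, fm)
                ft = default_finetune_frame(fm, pop)
                y = fm.cohort["is_case"].to_numpy()
                try:
                    model, oof = fit_ensemble(S, ft, y,
                                              fm.cohort["even"].to_numpy(),
                                              target=target)
                except ContractError as exc:
                    self._log(f"ensemble_{target}_skipped", 0.0, reason=str(exc))
                    out[target] = {"skipped": str(exc), "score_matrix": S,
                                   "labels": y,
                                   "even": fm.cohort["even"].to_numpy()}
                    continue
                out[target] = {"model": model, "scores": oof, "score_matrix": S,
                               "finetune": ft, "labels": y,
                               "even": fm.cohort["even"].to_numpy(),
                               "components": fm.cohort["component"].to_numpy()}
                model.to_frame().to_csv(self.out / f"ensemble_{target}.csv",
                                        index=False)
            return out

        def save(obj, paths):
            with open(paths[0], "wb") as fh:
                pickle.dump(obj, fh)

        def load(paths):
            with open(paths[0], "rb") as fh:
                return pickle.load(fh)

        return self._stage("ensemble", ["ensembles.pkl"], build, load, save)

    def evaluate(self) -> dict:
        cfg = self.config
        models = self.base_models()
        ens = self.ensembles()
        fms = self.features()

        def build():
            metrics = {}
            for target, bundle in ens.items():
                if "skipped" in bundle:
                    metrics[target] = {"skipped": bundle["skipped"],
                                       "n": int(len(bundle["labels"])),
                                       "n_cases": int(bundle["labels"].sum())}
                    continue
                y, sc = bundle["labels"], bundle["scores"]
                entry = {"ensemble_auroc": auroc(sc, y),
                         "ensemble_auprc": auprc(sc, y),
                         "n": int(len(y)), "n_cases": int(y.sum())}
                base_auc = {name: auroc(bundle["score_matrix"][name], y)
                            for name in bundle["score_matrix"]}
                entry["base_auroc"] = base_auc
                cal = calibration(sc, y)
                cal.to_csv(self.out / f"calibration_{target}.csv", index=False)
                try:
                    cor = concentration_of_risk(sc, y, list(cfg.qs),
                                                components=bundle["components"])
                    cor.to_csv(self.out / f"strata_{target}.csv", index=False)
                    entry["concentration"] = {
                        f"top{r['q']:g}": r["concentration"]
                        for _, r in cor.iterrows() if r["component"] == "all"}
                except ValueError:
                    entry["concentration"] = {}
                metrics[target] = entry
            if cfg.include_cox and "coxmh" in models:
                for tag in ("coxmh", "coxvisit"):
                    fm = fms[tag]
                    res = models[tag]
                    metrics[tag] = {"harrell_c": harrell_c(
                        res.scores, fm.cohort["time_to_event_days"],
                        fm.cohort["is_case"])}
            (self.out / "metrics.json").write_text(
                json.dumps(metrics, indent=1, default=float))
            return metrics

        def load(paths):
            return json.loads(paths[0].read_text())

        return self._stage("evaluate", ["metrics.json"], build, load,
                           lambda obj, p: None)

    def drift(self, target: str = "suicide") -> pd.DataFrame:
        """Frozen-vs-refreshed fine-tuning on the later-calendar cohort.

        The model fine-tuned at the target date is applied *frozen* to the
        drift-date cohort and compared with a fine-tuning refreshed on that
        cohort. Falls back to the combined outcome when the requested target
        could not be fine-tuned at this scale.
        """
        cfg = self.config
        pop = self.population()
        fms = self.features()
        if f"c19_{target}" not in fms:
            raise ValueError("configure run_drift=True to build the drift cohort")
        ens = self.ensembles()

        def degenerate(t):
            if "skipped" in ens[t]:
                return ens[t]["skipped"]
            coh = fms[f"c19_{t}"].cohort
            y = coh["is_case"].to_numpy()
            e = coh["even"].to_numpy()
            if y[e].sum() == 0 or y[~e].sum() == 0 or (~y).sum() == 0:
                return "drift cohort half has a single outcome class"
            return None

        reason = degenerate(target)
        if reason is not None and target != "combined":
            self._log("drift_target_fallback", 0.0, requested=target,
                      reason=reason)
            target = "combined"
        fm19 = fms[f"c19_{target}"]
        frozen_model = ens[target]["model"]
        reg = self.registry(target)
        S19 = score_base_models(reg, fm19)
        ft19 = default_finetune_frame(fm19, pop)
        y19 = fm19.cohort["is_case"].to_numpy()
        frozen_scores = apply_ensemble(frozen_model, S19, ft19)
        _, refreshed_scores = fit_ensemble(S19, ft19, y19,
                                           fm19.cohort["even"].to_numpy(),
                                           target=target)
        report = drift_eval(frozen_scores, refreshed_scores, y19, cfg.qs)
        report.to_csv(self.out / "drift_report.csv", index=False)
        return report


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the metrics dict."""
    pr = PipelineRun(config)
    pr.population()
    pr.component_events()
    pr.cohorts()
    pr.features()
    pr.base_models()
    pr.ensembles()
    metrics = pr.evaluate()
    if config.run_drift:
        pr.drift()
    return metrics
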