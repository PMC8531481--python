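"""End-to-end study orchestration: synthetic data -> baselines + SPORT ->
rendered reports.

``run_study`` reproduces the two study designs on synthetic spectra — a
qualitative task (geographic-origin discrimination by PLS-DA) and a
quantitative task (total-secoiridoid content by PLSR) — writing CSV/JSON
artifacts only: per-model metric tables, relative-improvement deltas,
synchronous-2DCOS difference summaries, permutation p-values, serialized
predictions, and a manifest with the seed, a config hash, and the
train/test partition. Reports are derived artifacts: every number in them
is recomputable from the serialized predictions shipped alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .plscore import cv_class_accuracy, cv_q2, permutation_test
from .preprocess import METHODS, PreprocessingBank
from .sport import WorkflowResult, run_sport_workflow
from .synthdata import GeneratorConfig, SpectrumSet, generate_dataset, write_spectra
from .twodcos import map_difference, sync_2dcos

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "load_config"]

FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """Configuration of one full study run.

    ``train_frac`` defaults to the 182/273 calibration/test split ratio;
    folds and permutation iterations default to 7 and 200. Tasks may be any
    subset of {'classify', 'regress'}.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preproc: list[str] = field(default_factory=lambda: ["MSC", "SNV", "VSN", "SD"])
    tasks: list[str] = field(default_factory=lambda: ["classify", "regress"])
    train_frac: float = 182.0 / 273.0
    n_folds: int = 7
    max_lv: int = 10
    search: str = "grid"
    permutation_iterations: int = 200
    permutation_methods: list[str] = field(default_factory=lambda: ["RAW", "SD"])
    permutation_max_lv: int = 5
    seed: int = 0
    outdir: str = "study_out"

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        bad = [m for m in self.preproc if m not in METHODS or m == "RAW"]
        if bad:
            raise ValueError(f"unknown preprocessing names: {bad}")
        bad_t = [t for t in self.tasks if t not in ("classify", "regress")]
        if bad_t:
            raise ValueError(f"unknown tasks: {bad_t}")
        self.generator.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in dataclasses.asdict(self.generator).items()
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML key-value file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = raw.pop("generator", {})
    gen = GeneratorConfig(**gen_raw)
    cfg = StudyConfig(generator=gen, **raw)
    cfg.validate()
    return cfg


def _class_table(reports: dict) -> pd.DataFrame:
    rows = []
    for method, rep in reports.items():
        tr, te = rep["train"], rep["test"]
        for i, c in enumerate(tr.classes):
            rows.append({
                "method": method, "class": str(c),
                "SEN_train": round(float(tr.sensitivity[i]), 4),
                "SPE_train": round(float(tr.specificity[i]), 4),
                "ACC_train": round(float(tr.accuracy), 4),
                "SEN_test": round(float(te.sensitivity[i]), 4),
                "SPE_test": round(float(te.specificity[i]), 4),
                "ACC_test": round(float(te.accuracy), 4),
            })
    return pd.DataFrame(rows)


def _reg_table(reports: dict, predictions: dict) -> pd.DataFrame:
    rows = []
    for method, rep in reports.items():
        lv = predictions[method].get("n_lv", predictions[method].get("lv_combination"))
        rows.append({
            "method": method,
            "LVs": str(lv),
            "R2c": round(rep.r2c, 4),
            "RMSECV": round(rep.rmsecv, 4),
            "R2p": round(rep.r2p, 4),
            "RMSEP": round(rep.rmsep, 4),
        })
    return pd.DataFrame(rows)


def _predictions_frame(result: WorkflowResult, data: SpectrumSet,
                       response: np.ndarray) -> pd.DataFrame:
    """Long-format serialization of train/test predictions of every model."""
    rows = []
    for which, idx in (("train", result.train_idx), ("test", result.test_idx)):
        ids = [data.sample_ids[i] for i in idx]
        truth = response[idx]
        for method, pred in result.predictions.items():
            for sid, t, p in zip(ids, truth, pred[which]):
                rows.append({"set": which, "method": method, "sample_id": sid,
                             "truth": t, "predicted": p})
    return pd.DataFrame(rows)


def _twodcos_summary(data: SpectrumSet, bank: PreprocessingBank,
                     methods: list[str]) -> pd.DataFrame:
    """Pairwise synchronous-map differences among preprocessed variants."""
    maps = {m: sync_2dcos(bank.transform_one(data, m)) for m in ["RAW"] + methods}
    rows = []
    names = list(maps)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = map_difference(maps[a], maps[b])
            rows.append({"pair": f"{a}|{b}", **{k: round(v, 6) for k, v in d.items()}})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict:
    """Run the configured study end to end and write its report bundle.

    Returns a dict with the WorkflowResult per task, the permutation
    results, the 2DCOS summary and the manifest. Any stage failure aborts
    with the stage name; the manifest of completed stages is still written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    timings: dict[str, float] = {}
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages_completed": completed,
        "timings_s": timings,
    }
    bundle: dict = {"manifest": manifest}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                _write_manifest(outdir, manifest)
                raise RuntimeError(f"study stage '{name}' failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            completed.append(name)
            logger.info("stage %s done in %.3fs", name, timings[name])
            return out
        return deco

    gen = dataclasses.replace(config.generator, seed=config.seed)

    data = stage("generate")(lambda: generate_dataset(gen))
    stage("write_data")(lambda: write_spectra(
        data, outdir / "spectra.csv", outdir / "metadata.csv"))
    bundle["data"] = data

    for task in config.tasks:
        short = "qualitative" if task == "classify" else "quantitative"

        result: WorkflowResult = stage(f"{short}_workflow")(
            lambda t=task: run_sport_workflow(
                data, task=t, preproc=config.preproc,
                train_frac=config.train_frac, max_lv=config.max_lv,
                n_folds=config.n_folds, search=config.search,
            )
        )
        bundle[task] = result
        response = (np.asarray(data.class_labels) if task == "classify"
                    else np.asarray(data.content, float))

        def render(t=task, r=result, resp=response, name=short):
            if t == "classify":
                table = _class_table(r.reports)
            else:
                table = _reg_table(r.reports, r.predictions)
            table.to_csv(outdir / f"{name}_metrics.csv", index=False,
                         float_format=FLOAT_FMT)
            deltas = pd.DataFrame(
                [{"comparison": k, **v} for k, v in r.deltas.items()]
            )
            deltas.to_csv(outdir / f"{name}_deltas.csv", index=False,
                          float_format=FLOAT_FMT)
            _predictions_frame(r, data, resp).to_csv(
                outdir / f"{name}_predictions.csv", index=False,
                float_format=FLOAT_FMT)
            manifest[f"{name}_split"] = {
                "train_ids": [data.sample_ids[i] for i in r.train_idx],
                "test_ids": [data.sample_ids[i] for i in r.test_idx],
            }
            manifest[f"{name}_sport_lvs"] = list(r.sport_model.lv_combination)

        stage(f"{short}_reports")(render)

        if config.permutation_iterations > 0 and config.permutation_methods:
            def permute(t=task, r=result, resp=response, name=short):
                train = data.subset(r.train_idx)
                bank = PreprocessingBank(methods=config.preproc).fit(train)
                out = {}
                for method in config.permutation_methods:
                    X = bank.transform_one(train, method).intensities
                    y = resp[r.train_idx]
                    cap = min(config.permutation_max_lv, X.shape[0] - 1, X.shape[1])
                    if t == "classify":
                        pipe = lambda Xp, yp: cv_class_accuracy(  # noqa: E731
                            Xp, yp, max_lv=cap, n_folds=config.n_folds)
                    else:
                        pipe = lambda Xp, yp: cv_q2(  # noqa: E731
                            Xp, yp, max_lv=cap, n_folds=config.n_folds)
                    res = permutation_test(pipe, X, y,
                                           n_iter=config.permutation_iterations,
                                           seed=config.seed)
                    out[method] = {"observed": round(res.observed, 6),
                                   "p_value": round(res.p_value, 6),
                                   "n_iter": config.permutation_iterations}
                with open(outdir / f"{name}_permutation.json", "w") as fh:
                    json.dump(out, fh, indent=2, sort_keys=True)
                return out

            bundle[f"{task}_permutation"] = stage(f"{short}_permutation")(permute)

    def twodcos():
        # complementarity summary on the qualitative training portion if
        # available, else on the full set
        first = config.tasks[0] if config.tasks else None
        if first and first in bundle:
            r = bundle[first]
            train = data.subset(r.train_idx)
        else:
            train = data
        bank = PreprocessingBank(methods=config.preproc).fit(train)
        df = _twodcos_summary(train, bank, config.preproc)
        df.to_csv(outdir / "twodcos_differences.csv", index=False,
                  float_format=FLOAT_FMT)
        return df

    bundle["twodcos"] = stage("twodcos_summary")(twodcos)

    _write_manifest(outdir, manifest)
    return bundle


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
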