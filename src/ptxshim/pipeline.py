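"""End-to-end reproducible pipeline: simulate fields, derive reference
shims, train the weight regressor, evaluate against the classical arms,
and optionally screen outputs with the non-uniformity detector.

Every stage derives its own seed from the single run seed, writes its
output under the run directory, and can be resumed from intermediates; two
runs with the same configuration and seed produce identical metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import nfd as _nfd
from . import predictor as _pred
from . import shimcore
from .fieldsim import GeneratorConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "NFDStageConfig", "ProvenanceRecord", "run_pipeline"]

TOOL_VERSION = "0.1.0"


@dataclass(frozen=True)
class NFDStageConfig:
    """Settings for the optional screening stage."""

    enabled: bool = True
    n_per_class: int = 100
    test_fraction: float = 0.25
    detector: _nfd.NFDConfig = field(default_factory=_nfd.NFDConfig)


@dataclass(frozen=True)
class RunConfig:
    """Full-pipeline configuration: one nested block per stage plus the
    global seed.  Loading from YAML rejects unknown keys so a typo cannot
    silently fall back to a default."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    shim: shimcore.ShimObjectiveConfig = field(
        default_factory=lambda: shimcore.ShimObjectiveConfig(n_restarts=20, max_iters=300)
    )
    predictor: _pred.PredictorConfig = field(default_factory=_pred.PredictorConfig)
    nfd: NFDStageConfig = field(default_factory=NFDStageConfig)
    seed: int = 0
    out_dir: str = "ptxshim_run"
    verbosity: str = "INFO"

    # -- serialization ------------------------------------------------------

    @staticmethod
    def _build(cls, data: dict, path: str):
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            ftype = fields[name].type
            target = {
                "generator": GeneratorConfig,
                "shim": shimcore.ShimObjectiveConfig,
                "predictor": _pred.PredictorConfig,
                "nfd": NFDStageConfig,
                "detector": _nfd.NFDConfig,
            }.get(name)
            if target is not None and isinstance(value, dict):
                kwargs[name] = RunConfig._build(target, value, f"{path}.{name}")
            elif isinstance(value, list):
                kwargs[name] = tuple(value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls._build(cls, dict(data), "run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ProvenanceRecord:
    """Carried by every report the pipeline writes."""

    tool_version: str
    config_hash: str
    dataset_seed: int
    stage_seeds: dict
    timestamps: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    return {
        "simulate": int(state[0]),
        "reference": int(state[1]),
        "train": int(state[2]),
        "nfd": int(state[3]),
    }


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute the full pipeline and return a report bundle.

    Stages: simulate → reference shims (multi-restart Adam) → train the
    regressor → evaluate on the held-out split against the quadrature and
    variable-exchange arms → optional NFD screen.  Intermediates land in
    ``config.out_dir`` (dataset.h5 with cached references, model.npz,
    metrics.csv, summary.json, provenance.json); with ``resume`` existing
    intermediates are reused.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    prov = ProvenanceRecord(
        tool_version=TOOL_VERSION,
        config_hash=config.config_hash(),
        dataset_seed=seeds["simulate"],
        stage_seeds=seeds,
    )
    logger.info("run %s (seed %d) -> %s", prov.config_hash, config.seed, out)
    dataset_path = out / "dataset.h5"

    # -- stage: simulate ----------------------------------------------------
    t0 = time.time()
    try:
        if resume and dataset_path.exists():
            volumes = _io.read_dataset(dataset_path)
        else:
            volumes = simulate_dataset(config.generator, seeds["simulate"])
            _io.write_dataset(volumes, dataset_path, config=config.generator,
                              seed=seeds["simulate"])
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    prov.timestamps["simulate"] = time.time() - t0

    # -- stage: reference shims --------------------------------------------
    t0 = time.time()
    try:
        ref_tables = None
        if resume:
            try:
                ref_tables = _io.read_reference(dataset_path)
            except _io.DatasetFormatError:
                ref_tables = None
        if ref_tables is None:
            ref_tables = []
            warm = None
            for v, vol in enumerate(volumes):
                table = shimcore.shim_volume(
                    vol, "adam",
                    replace(config.shim, seed=seeds["reference"] + 1000 * v),
                    coherent=True, warm_start=warm,
                )
                ok_rows = table[table["ok"]]
                if len(ok_rows):
                    warm = ok_rows.iloc[-1]["weights"]
                ref_tables.append(table)
            _io.write_reference(ref_tables, dataset_path)
    except Exception as exc:
        raise StageError("reference", exc) from exc
    prov.timestamps["reference"] = time.time() - t0

    # -- stage: train -------------------------------------------------------
    t0 = time.time()
    try:
        examples = _pred.build_examples(
            volumes, ref_tables, mode=config.predictor.encoding_mode
        )
        pred_cfg = replace(config.predictor, seed=seeds["train"])
        splits = _pred.split_dataset(examples, pred_cfg.split_ratios, pred_cfg.seed)
        model, history = _pred.train(examples, pred_cfg, splits)
        _pred.save_model(model, out / "model.npz",
                         extra={"config_hash": prov.config_hash})
    except Exception as exc:
        raise StageError("train", exc) from exc
    prov.timestamps["train"] = time.time() - t0

    # -- stage: evaluate ----------------------------------------------------
    t0 = time.time()
    try:
        test_idx = list(splits[2])
        test_examples = [examples[i] for i in test_idx]
        quad, mls = [], []
        for ex in test_examples:
            wq = shimcore.quadrature_weights(ex.fields_ref.channel_count)
            quad.append(
                shimcore.rmse_percent(ex.fields_ref, wq, ex.target_map, ex.mask)
            )
            res = shimcore.mls_variable_exchange(
                ex.fields_ref, ex.target_map, ex.mask,
                lambda_reg=config.shim.lambda_reg,
            )
            mls.append(res.rmse_percent)
        report = _pred.evaluate(
            model, test_examples,
            comparisons={"mls": mls, "quadrature": quad},
            batch_size=config.predictor.batch_size,
        )
        metrics = report["per_slice"].copy()
        metrics.insert(0, "test_index", test_idx)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    prov.timestamps["evaluate"] = time.time() - t0

    # -- stage: NFD (optional) ----------------------------------------------
    nfd_report = None
    if config.nfd.enabled:
        t0 = time.time()
        try:
            maps, masks, rmses = [], [], []
            for vol, table in zip(volumes, ref_tables):
                for s, row in table.sort_values("slice").iterrows():
                    if not row["ok"]:
                        continue
                    w = shimcore.ShimWeights(np.asarray(row["weights"]))
                    mag = np.abs(shimcore.combined_field(vol.slices[int(row["slice"])], w))
                    maps.append(mag)
                    masks.append(vol.masks[int(row["slice"])])
                    rmses.append(float(row["rmse_percent"]))
            det_cfg = replace(config.nfd.detector, seed=seeds["nfd"])
            examples_nfd = _nfd.make_nfd_dataset(
                maps, masks, config.nfd.n_per_class, seed=seeds["nfd"],
                config=det_cfg, rmse_percents=rmses,
            )
            n_test = max(2, int(config.nfd.test_fraction * len(examples_nfd)))
            n_test -= n_test % 2  # keep both classes present (pairs are adjacent)
            test_nfd, train_nfd_ex = examples_nfd[:n_test], examples_nfd[n_test:]
            detector, _ = _nfd.train_nfd(train_nfd_ex, det_cfg)
            nfd_report = _nfd.evaluate_nfd(detector, test_nfd)
            (out / "nfd_report.json").write_text(
                json.dumps(
                    {
                        k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in nfd_report.items()
                    },
                    indent=2,
                )
            )
        except Exception as exc:
            raise StageError("nfd", exc) from exc
        prov.timestamps["nfd"] = time.time() - t0

    summary = {
        "mean_rmse_percent": report["mean"],
        "n_test_slices": len(test_examples),
        "n_examples": len(examples),
        "best_epoch": history.best_epoch,
        "provenance": dataclasses.asdict(prov),
    }
    if nfd_report is not None:
        summary["nfd_balanced_accuracy"] = nfd_report["balanced_accuracy"]
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "provenance.json").write_text(
        json.dumps(dataclasses.asdict(prov), indent=2, default=float)
    )
    config.to_yaml(out / "config.yaml")
    return {
        "out_dir": str(out),
        "metrics": metrics,
        "summary": summary,
        "history": history,
        "nfd_report": nfd_report,
    }
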