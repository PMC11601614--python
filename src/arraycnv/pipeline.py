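"""End-to-end orchestration: simulate / prep / train / predict runs.

Each run reads a declarative YAML config, writes its outputs plus a run
log (parameters, seed, input digests) and is deterministic for a fixed
seed.  The config schema (all sections optional unless a run needs them):

.. code-block:: yaml

    region:
      gene: PRKN            # or chromosome/start/stop
      buffer: 250000
    prep:
      cnv_type: deletion
      split: 5
      total_windows: 50
      gentrain_cutoff: 0.2
      whitelist: null        # optional bim/pvar path
      whitelist_format: bim
    model:
      epochs: 100
      batch_size: 32
      learning_rate: 0.001
      patience: 10
      seed: 0
    simulate:
      n_samples: 100
      carrier_fraction: 0.3
      seed: 0
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import regions as reg
from . import signals as sig
from .model import CnvLstmModel, ModelConfig, load_results
from .review import export_app_table
from .simulate import DEFAULT_EVENT_SIZE_RANGE, simulate_panel

__all__ = ["load_config", "run_simulate", "run_prep", "run_train", "run_predict"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "region" not in cfg:
        raise ValueError("config missing required section: region")
    return cfg


def _resolve_region(cfg: dict) -> reg.RegionSpec:
    rcfg = cfg["region"]
    buffer = int(rcfg.get("buffer", reg.DEFAULT_BUFFER_BP))
    if "gene" in rcfg:
        return reg.resolve_region(rcfg["gene"], buffer=buffer)
    try:
        return reg.resolve_region(
            (rcfg["chromosome"], rcfg["start"], rcfg["stop"]), buffer=buffer
        )
    except KeyError as exc:
        raise ValueError(f"config region missing field: {exc}") from exc


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_run_log(out_dir: Path, name: str, params: dict, inputs: list[Path]) -> None:
    log = {
        "run": name,
        "params": params,
        "inputs": {str(p): _digest(p) for p in inputs},
    }
    (out_dir / f"{name}_runlog.json").write_text(json.dumps(log, indent=2, default=str))


def run_simulate(cfg: dict, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write the signal table + truth labels."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region = _resolve_region(cfg)
    scfg = cfg.get("simulate", {})
    panel, truth = simulate_panel(
        region,
        n_samples=int(scfg.get("n_samples", 100)),
        carrier_fraction=float(scfg.get("carrier_fraction", 0.3)),
        cnv_type=scfg.get("cnv_type", cfg.get("prep", {}).get("cnv_type", "deletion")),
        event_size_range=tuple(scfg.get("event_size_range", DEFAULT_EVENT_SIZE_RANGE)),
        seed=int(scfg.get("seed", 0)),
    )
    signal_path = out_dir / "signal_table.tsv"
    truth_path = out_dir / "truth.tsv"
    panel.to_table(signal_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    _write_run_log(out_dir, "simulate", scfg, [signal_path, truth_path])
    return {"signal_table": signal_path, "truth": truth_path}


def run_prep(cfg: dict, signal_table: str | Path, out_dir: str | Path,
             scaling: feat.ScalingStats | None = None) -> dict:
    """Read, filter, window and aggregate a signal table into features."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    region = _resolve_region(cfg)
    pcfg = cfg.get("prep", {})
    cnv_type = pcfg.get("cnv_type", "deletion")
    panel = sig.read_signal_table(signal_table)
    panel = sig.apply_gentrain_filter(panel, cutoff=float(pcfg.get("gentrain_cutoff", 0.2)))
    whitelist = None
    if pcfg.get("whitelist"):
        whitelist = sig.read_variant_whitelist(
            pcfg["whitelist"], format=pcfg.get("whitelist_format", "bim")
        )
    panel = sig.subset_panel(panel, region, whitelist)
    scheme = reg.compute_window_scheme(
        region,
        split=int(pcfg.get("split", 5)),
        total_windows=int(pcfg.get("total_windows", 50)),
    )
    arr = feat.build_feature_array(panel, scheme, cnv_type, scaling=scaling)
    feat_path = out_dir / f"{cnv_type}_features.tsv"
    arr.to_long_table(feat_path)
    _write_run_log(
        out_dir, "prep",
        {**pcfg, "region": region.name or region.chromosome},
        [Path(signal_table), feat_path],
    )
    return {"features": arr, "panel": panel, "scheme": scheme, "path": feat_path}


def run_train(cfg: dict, signal_table: str | Path, labels_path: str | Path,
              out_dir: str | Path) -> dict:
    """Prep + train a scorer; writes the model artifact and a history log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prep = run_prep(cfg, signal_table, out_dir)
    arr = prep["features"]
    truth = pd.read_csv(labels_path, sep="\t")
    labels = truth.set_index("sample_id").loc[arr.sample_ids, "label"].to_numpy()
    mcfg = cfg.get("model", {})
    config = ModelConfig(
        epochs=int(mcfg.get("epochs", 100)),
        batch_size=int(mcfg.get("batch_size", 32)),
        learning_rate=float(mcfg.get("learning_rate", 1e-3)),
        patience=int(mcfg.get("patience", 10)),
        validation_fraction=float(mcfg.get("validation_fraction", 0.0)),
        seed=int(mcfg.get("seed", 0)),
    )
    results = CnvLstmModel(arr, labels).fit(config)
    model_path = out_dir / f"{arr.cnv_type}_model.npz"
    results.save(model_path)
    _write_run_log(out_dir, "train", {"config": str(config)}, [Path(signal_table), model_path])
    return {"results": results, "model_path": model_path}


def run_predict(cfg: dict, signal_table: str | Path, model_path: str | Path,
                out_dir: str | Path) -> dict:
    """Score a cohort with a saved model and emit review files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cnv_type = cfg.get("prep", {}).get("cnv_type", "deletion")
    results = load_results(model_path, expected_cnv_type=cnv_type)
    prep = run_prep(cfg, signal_table, out_dir, scaling=results.scaling)
    arr, panel = prep["features"], prep["panel"]
    if arr.values.shape[1:] != (results.n_windows, results.n_features):
        raise ValueError(
            f"prep produced shape {arr.values.shape[1:]}, model expects "
            f"({results.n_windows}, {results.n_features}); check split/total_windows"
        )
    scores = results.predict(arr)
    predictions = dict(zip(arr.sample_ids, (float(s) for s in scores)))
    region = _resolve_region(cfg)
    review_path, plot_path = export_app_table(
        panel,
        predictions,
        region_name=region.name or f"{region.chromosome}_{region.start}",
        cnv_type=cnv_type,
        out_dir=out_dir,
        review_threshold=float(cfg.get("review", {}).get("threshold", 0.8)),
    )
    _write_run_log(out_dir, "predict", {"model": str(model_path)},
                   [Path(signal_table), review_path])
    return {"scores": np.asarray(scores), "review": review_path, "plot": plot_path}
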