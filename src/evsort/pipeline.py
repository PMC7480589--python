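"""End-to-end sorting workflow: images -> CAE features -> forest -> .pop files.

Mirrors the acquisition-side workflow: per-cell TIF exports are encoded by
the pre-trained autoencoder, the random forest assigns each object to the
apoptotic or EV-decorated population, and the two object-number lists are
written as population files that partition the input. Every stage is seeded,
so a rerun with the same configuration reproduces the output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cae as cae_mod
from .io import DatasetManifest, PopulationFile, write_population
from .sorter import SortResult, predict_labels

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_sort", "save_forest", "load_forest"]


@dataclass
class PipelineConfig:
    manifest_path: str
    weights_path: str
    forest_path: str
    out_prefix: str = "sorted"
    threshold: float = 0.5
    seed: int = 0


def save_forest(forest, path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(forest, fh)
    return path


def load_forest(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


def _sha(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_sort(config: PipelineConfig,
             ) -> tuple[PopulationFile, PopulationFile, SortResult]:
    """Sort every cell in the manifest into two population files.

    Returns (apoptotic population, ev population, full sort result); the two
    populations partition the manifest's object ids. Provenance (input
    hashes, config) is logged and written next to the outputs.
    """
    manifest = DatasetManifest.from_csv(config.manifest_path)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    for path in (config.weights_path, config.forest_path):
        if not Path(path).exists():
            raise FileNotFoundError(path)
    weights = cae_mod.CAEWeights.load(config.weights_path)
    forest = load_forest(config.forest_path)

    pixels = manifest.load_pixel_array()
    feats = cae_mod.extract_features(weights, pixels)
    result = predict_labels(forest, feats, object_ids=manifest.object_ids(),
                            threshold=config.threshold, method="cae_rf")
    pops = result.to_population_files(Path(config.out_prefix).name)
    out_ap = Path(f"{config.out_prefix}_apoptotic.pop")
    out_ev = Path(f"{config.out_prefix}_ev.pop")
    write_population(pops["apoptotic"], out_ap)
    write_population(pops["ev"], out_ev)
    prov = {
        "manifest": str(config.manifest_path),
        "manifest_sha": _sha(config.manifest_path),
        "weights_sha": _sha(config.weights_path),
        "weights_config": weights.config_hash,
        "forest_sha": _sha(config.forest_path),
        "threshold": config.threshold,
        "seed": config.seed,
        "n_cells": len(manifest),
        "n_apoptotic": len(pops["apoptotic"].object_ids),
        "n_ev": len(pops["ev"].object_ids),
    }
    with open(f"{config.out_prefix}_provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    logger.info("sorted %d cells -> %d apoptotic, %d ev", prov["n_cells"],
                prov["n_apoptotic"], prov["n_ev"])
    return pops["apoptotic"], pops["ev"], result
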