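"""End-to-end pipeline: preprocess → decimate → transform → features →
cross-validated classification → majority vote → report.

A single master seed deterministically spawns one sub-seed per stage
(via ``numpy.random.SeedSequence([master, stage_index])``), so the whole
run is bit-reproducible and each stage can also be reproduced on its own
from the logged configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainingConfig
from .evaluate import EvaluationReport, cross_validate
from .features import FeatureVector, HiguchiConfig, extract_features
from .lwt import build_lifting_scheme
from .preprocess import PreprocessConfig, polyphase_decimate, preprocess
from .simulate import Signal

log = logging.getLogger("emgdx")

_STAGE_INDEX = {"simulate": 0, "folds": 1, "training": 2}


def spawn_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (below 2**31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    wavelet: str = "rbio3.7"
    levels: int = 5
    extension_mode: str = "periodization"
    higuchi: HiguchiConfig = HiguchiConfig()
    lbp_normalize: bool = True
    training: TrainingConfig = TrainingConfig()
    k_folds: int = 10
    runs: int = 1
    group_by_parent: bool = False
    master_seed: int = 0

    def provenance(self) -> dict:
        return {
            "normalize": self.preprocess.normalize,
            "bandpass_hz": self.preprocess.bandpass_hz,
            "M": self.preprocess.decimation_factor,
            "wavelet": self.wavelet,
            "levels": self.levels,
            "extension_mode": self.extension_mode,
            "k_max": self.higuchi.k_max,
            "lbp_normalize": self.lbp_normalize,
            "n_hidden": self.training.n_hidden,
            "n_epochs": self.training.n_epochs,
            "k_folds": self.k_folds,
            "runs": self.runs,
            "group_by_parent": self.group_by_parent,
            "master_seed": self.master_seed,
            "stage_seeds": {s: spawn_seed(self.master_seed, s) for s in _STAGE_INDEX},
        }


def compute_feature_table(signals: list[Signal], config: PipelineConfig) -> list[FeatureVector]:
    """Preprocess, decimate and featurize every recording."""
    scheme = build_lifting_scheme(config.wavelet)
    M = config.preprocess.decimation_factor
    features: list[FeatureVector] = []
    t0 = time.perf_counter()
    for sig in signals:
        if sig.label == "unknown":
            raise ValueError(f"signal {sig.signal_id!r} has no class label")
        pre = preprocess(sig, config.preprocess)
        for child in polyphase_decimate(pre, M).children:
            features.append(
                extract_features(
                    child,
                    levels=config.levels,
                    scheme=scheme,
                    extension_mode=config.extension_mode,
                    higuchi=config.higuchi,
                    lbp_normalize=config.lbp_normalize,
                )
            )
    log.info(
        "featurized %d recordings into %d vectors in %.1f s",
        len(signals), len(features), time.perf_counter() - t0,
    )
    return features


def run_pipeline(signals: list[Signal], config: PipelineConfig = PipelineConfig()) -> EvaluationReport:
    """Full evaluation of a labeled signal collection.

    Returns the cross-validated report; ``config.provenance()`` holds
    everything needed to reproduce it.
    """
    features = compute_feature_table(signals, config)
    t0 = time.perf_counter()
    report = cross_validate(
        features,
        k=config.k_folds,
        config=config.training,
        M=config.preprocess.decimation_factor,
        runs=config.runs,
        seed=spawn_seed(config.master_seed, "folds"),
        group_by_parent=config.group_by_parent,
    )
    log.info("cross-validation (%d runs) in %.1f s", config.runs, time.perf_counter() - t0)
    return report
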