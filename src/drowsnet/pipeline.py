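"""Declarative end-to-end runs: simulate -> preprocess -> evaluate -> analyze.

A :class:`RunConfig` document fully determines a run; the same config and
seed reproduce the metric files exactly.  Every artifact directory carries a
``run.json`` log with the config, its hash, and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .nn.model import default_spec, small_spec
from .preprocess import (
    FIVE_CLASS,
    TWO_CLASS,
    EpochSet,
    bandpass_filter,
    downsample,
    make_folds,
    notch_filter,
    reject_eog_ics,
    segment_epochs,
)
from .simulate import SimConfig, null_config, separable_config, simulate_session
from .spectral import band_power_by_class
from .train_eval import NetworkClassifier, TrainConfig, cross_validate, loso_validate

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


def _strict(cls, section: str, values: dict[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    return cls(**values)


@dataclass(frozen=True)
class SimSection:
    generator: str = "default"  # default | separable | null
    n_subjects: int = 1
    n_trials: int = 60
    trial_flight_s: float = 60.0
    kss_window_s: float = 10.0
    fs: float = 1000.0
    blink_rate: float = 12.0


@dataclass(frozen=True)
class PreprocessSection:
    notch: bool = False
    notch_freq: float = 60.0
    low: float = 1.0
    high: float = 50.0
    order: int = 2
    target_fs: float = 100.0
    ica: bool = False
    ica_threshold: float = 0.7


@dataclass(frozen=True)
class ModelSection:
    size: str = "small"  # small | full
    scheme: str = "five_class"  # two_class | five_class


@dataclass(frozen=True)
class TrainSection:
    epochs: int = 5
    batch_size: int = 32
    lr: float = 1e-3


@dataclass(frozen=True)
class EvalSection:
    mode: str = "cv"  # cv | loso
    k: int = 4


@dataclass(frozen=True)
class AnalyzeSection:
    enabled: bool = True


@dataclass(frozen=True)
class RunConfig:
    sim: SimSection = field(default_factory=SimSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    eval: EvalSection = field(default_factory=EvalSection)
    analyze: AnalyzeSection = field(default_factory=AnalyzeSection)
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        doc = dict(doc)
        sections = {
            "sim": SimSection, "preprocess": PreprocessSection, "model": ModelSection,
            "train": TrainSection, "eval": EvalSection, "analyze": AnalyzeSection,
        }
        kwargs: dict[str, Any] = {}
        for name, section_cls in sections.items():
            kwargs[name] = _strict(section_cls, name, doc.pop(name, {}))
        seed = doc.pop("seed", 0)
        if doc:
            raise ValueError(f"unknown top-level key(s): {sorted(doc)}")
        return cls(seed=int(seed), **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sim_config(section: SimSection, seed: int) -> SimConfig:
    common = dict(
        n_trials=section.n_trials, trial_flight_s=section.trial_flight_s,
        kss_window_s=section.kss_window_s, fs=section.fs, seed=seed,
    )
    if section.generator == "separable":
        base = separable_config(**common)
    elif section.generator == "null":
        base = null_config(**common)
    elif section.generator == "default":
        base = SimConfig(blink_rate=section.blink_rate, **common)
    else:
        raise ValueError(f"unknown generator {section.generator!r}")
    return base


def preprocess_session(session, cfg: PreprocessSection, seed: int = 0,
                       trial_flight_s: float = 60.0, kss_window_s: float = 10.0) -> EpochSet:
    if cfg.notch:
        session = notch_filter(session, cfg.notch_freq)
    session = bandpass_filter(session, cfg.low, cfg.high, cfg.order)
    session = downsample(session, cfg.target_fs)
    if cfg.ica:
        session = reject_eog_ics(session, threshold=cfg.ica_threshold, seed=seed)
    return segment_epochs(session, trial_flight_s=trial_flight_s, kss_window_s=kss_window_s)


def _atomic_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_name(f".{path.name}.tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the configured pipeline and write artifacts under ``outdir``.

    Returns a summary dict (also written to ``run.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = {"two_class": TWO_CLASS, "five_class": FIVE_CLASS}[config.model.scheme]

    stage = "simulate"
    try:
        subject_sets: list[EpochSet] = []
        for s in range(config.sim.n_subjects):
            sim_cfg = _sim_config(config.sim, seed=config.seed + 1000 * s)
            session = simulate_session(sim_cfg, subject_id=f"S{s + 1}")
            stage = "preprocess"
            subject_sets.append(
                preprocess_session(
                    session, config.preprocess, seed=config.seed,
                    trial_flight_s=config.sim.trial_flight_s,
                    kss_window_s=config.sim.kss_window_s,
                )
            )
            stage = "simulate"

        stage = "evaluate"
        spec_builder = small_spec if config.model.size == "small" else default_spec
        spec = spec_builder(n_classes=scheme.n_classes)
        train_cfg = TrainConfig(epochs=config.train.epochs, batch_size=config.train.batch_size,
                                lr=config.train.lr, seed=config.seed)
        factory = lambda: NetworkClassifier(spec, train_cfg)  # noqa: E731
        pooled = subject_sets[0] if len(subject_sets) == 1 else EpochSet.concat(subject_sets)
        if config.eval.mode == "cv":
            folds = make_folds(pooled, k=config.eval.k, seed=config.seed)
            report = cross_validate(factory, pooled, folds, scheme)
        elif config.eval.mode == "loso":
            report = loso_validate(factory, subject_sets, scheme)
        else:
            raise ValueError(f"unknown eval mode {config.eval.mode!r}")

        metrics = pd.DataFrame({
            "fold": list(range(len(report.fold_accuracies))),
            "accuracy": report.fold_accuracies,
            "n_test": report.n_test,
        })
        if report.sensitivity is not None:
            metrics["sensitivity"] = report.sensitivity
            metrics["specificity"] = report.specificity
        _atomic_csv(metrics, outdir / "metrics.csv")
        _atomic_csv(pd.DataFrame(report.confusion,
                                 columns=[f"target_{c}" for c in scheme.class_names]),
                    outdir / "confusion.csv")

        stage = "analyze"
        if config.analyze.enabled:
            table = band_power_by_class(pooled, scheme)
            _atomic_csv(pd.DataFrame(table.to_records()), outdir / "spectra.csv")
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "mean_accuracy": report.mean_accuracy,
        "std_accuracy": report.std_accuracy,
        "fold_accuracies": report.fold_accuracies,
    }
    tmp = outdir / ".run.json.tmp"
    tmp.write_text(json.dumps(summary, indent=2))
    tmp.replace(outdir / "run.json")
    return summary
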