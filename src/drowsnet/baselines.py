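"""Conventional comparators: band-power features + SVM, with optional
canonical-correlation feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import EpochSet
from .spectral import DEFAULT_BANDS, BandDef

__all__ = ["FeatureTable", "psd_features", "cca_select", "fit_baseline", "BaselineClassifier"]


@dataclass
class FeatureTable:
    """Per-epoch feature matrix with channel x band feature names."""

    x: np.ndarray  # (n_epochs, n_features)
    names: list[str]

    def __post_init__(self) -> None:
        if self.x.ndim != 2 or self.x.shape[1] != len(self.names):
            raise ValueError("feature matrix and names are inconsistent")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("features contain non-finite values")


def _band_powers(epochs: np.ndarray, fs: float, bands: list[BandDef]) -> np.ndarray:
    """(n, channels, bands) band power via full-epoch periodogram."""
    n, n_ch, n_samp = epochs.shape
    freqs, pxx = sps.periodogram(epochs, fs=fs, window="boxcar", detrend="constant", axis=-1)
    out = np.empty((n, n_ch, len(bands)))
    for b, band in enumerate(bands):
        sel = (freqs >= band.low) & (freqs < band.high)
        if not np.any(sel):
            raise ValueError(f"band {band.name} ({band.low}-{band.high} Hz) outside resolution")
        out[:, :, b] = pxx[:, :, sel].sum(axis=-1)
    return out


def psd_features(epochs: EpochSet, bands: list[BandDef] | None = None) -> FeatureTable:
    """Per-channel band power features (channels x bands per epoch)."""
    bands = bands if bands is not None else DEFAULT_BANDS
    nyq = epochs.fs / 2.0
    for band in bands:
        if band.low >= nyq:
            raise ValueError(f"band {band.name} lies beyond Nyquist {nyq} Hz")
    powers = _band_powers(epochs.epochs, epochs.fs, bands)
    n = powers.shape[0]
    labels = epochs.channel_labels or [f"ch{i}" for i in range(powers.shape[1])]
    names = [f"{ch}:{band.name}" for ch in labels for band in bands]
    return FeatureTable(x=powers.reshape(n, -1), names=names)


def cca_select(features: FeatureTable, labels: np.ndarray, k: int) -> tuple[FeatureTable, np.ndarray]:
    """Rank features by canonical correlation with the one-hot labels.

    For a single feature against a class-indicator matrix the (first)
    canonical correlation reduces to the correlation ratio
    sqrt(SS_between / SS_total).  Returns the top-``k`` table and the
    selected column indices (to be reused on held-out data).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = features.x
    y = np.asarray(labels)
    n, p = x.shape
    k = min(k, p)
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=0)
    ss_between = np.zeros(p)
    for cls in np.unique(y):
        sel = y == cls
        ss_between += sel.sum() * (x[sel].mean(axis=0) - grand) ** 2
    degenerate = ss_total <= 0
    if np.any(degenerate):
        warnings.warn("constant feature(s) encountered; assigned zero canonical correlation")
    r = np.zeros(p)
    ok = ~degenerate
    r[ok] = np.sqrt(np.clip(ss_between[ok] / ss_total[ok], 0.0, 1.0))
    order = np.argsort(-r, kind="stable")
    keep = np.sort(order[:k])
    return FeatureTable(x=x[:, keep], names=[features.names[i] for i in keep]), keep


class BaselineClassifier:
    """Band-power SVM baseline operating directly on epoch tensors.

    ``kind='psd_svm'`` uses all channel x band powers; ``kind='cca_svm'``
    first keeps the top-k features by canonical correlation with the labels.
    Scaling and selection statistics are fitted on the training data only.
    """

    def __init__(self, kind: str = "psd_svm", fs: float = 100.0,
                 bands: list[BandDef] | None = None, k: int = 30, c: float = 1.0,
                 channel_labels: list[str] | None = None):
        if kind not in ("psd_svm", "cca_svm"):
            raise ValueError(f"unknown baseline kind {kind!r}")
        self.kind = kind
        self.fs = fs
        self.bands = bands if bands is not None else DEFAULT_BANDS
        self.k = k
        self.c = c
        self.channel_labels = channel_labels
        self._scaler: StandardScaler | None = None
        self._svm: SVC | None = None
        self._keep: np.ndarray | None = None

    def _features(self, x: np.ndarray) -> FeatureTable:
        es = EpochSet(
            epochs=np.asarray(x, dtype=float),
            kss=np.ones(x.shape[0], dtype=int),
            trial_index=np.zeros(x.shape[0], dtype=int),
            fs=self.fs,
            channel_labels=self.channel_labels or [],
        )
        return psd_features(es, self.bands)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BaselineClassifier":
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training set contains a single class")
        table = self._features(x)
        feats = table.x
        if self.kind == "cca_svm":
            _, self._keep = cca_select(table, y, self.k)
            feats = feats[:, self._keep]
        self._scaler = StandardScaler().fit(feats)
        self._svm = SVC(kernel="rbf", C=self.c).fit(self._scaler.transform(feats), y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._svm is None:
            raise RuntimeError("fit must be called before predict")
        feats = self._features(x).x
        if self._keep is not None:
            feats = feats[:, self._keep]
        return self._svm.predict(self._scaler.transform(feats))


def fit_baseline(x: np.ndarray, y: np.ndarray, kind: str = "psd_svm",
                 fs: float = 100.0, **kwargs) -> BaselineClassifier:
    """Train a margin-based kernel classifier on z-scored spectral features."""
    return BaselineClassifier(kind=kind, fs=fs, **kwargs).fit(x, y)
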