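"""Raw-session preprocessing: filtering, decimation, ocular-component
rejection, epoch segmentation, label mapping, and fold assignment.

The canonical stage order is notch (optional) -> band-pass -> downsample ->
ICA-based EOG rejection -> 1-s epoch segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .simulate import Event, RawSession

__all__ = [
    "EpochSet",
    "LabelScheme",
    "TWO_CLASS",
    "FIVE_CLASS",
    "FoldAssignment",
    "bandpass_filter",
    "notch_filter",
    "downsample",
    "reject_eog_ics",
    "segment_epochs",
    "map_labels",
    "make_folds",
]


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from KSS (1-9) to class ids.

    ``mapping`` lists inclusive KSS ranges in class-id order; the ranges must
    partition 1..9.
    """

    mode: str
    class_names: tuple[str, ...]
    mapping: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        covered = []
        for low, high in self.mapping:
            covered.extend(range(low, high + 1))
        if sorted(covered) != list(range(1, 10)):
            raise ValueError("label ranges must partition KSS 1..9")

    @property
    def n_classes(self) -> int:
        return len(self.mapping)


TWO_CLASS = LabelScheme(mode="two_class", class_names=("alert", "drowsy"), mapping=((1, 6), (7, 9)))
FIVE_CLASS = LabelScheme(
    mode="five_class",
    class_names=("VA", "FA", "NAS", "SNEA", "VS"),
    mapping=((1, 2), (3, 4), (5, 6), (7, 8), (9, 9)),
)


def map_labels(kss: int | np.ndarray, scheme: LabelScheme) -> int | np.ndarray:
    """Deterministic KSS -> class-id mapping under a label scheme."""
    arr = np.asarray(kss)
    if np.any((arr < 1) | (arr > 9)):
        raise ValueError(f"KSS values must lie in [1, 9], got {kss}")
    out = np.full(arr.shape, -1, dtype=int)
    for cls, (low, high) in enumerate(scheme.mapping):
        out[(arr >= low) & (arr <= high)] = cls
    return int(out) if np.isscalar(kss) or arr.ndim == 0 else out


@dataclass
class EpochSet:
    """Non-overlapping 1-s EEG epochs with their sleepiness labels."""

    epochs: np.ndarray  # (n, 30, samples-per-epoch)
    kss: np.ndarray  # (n,) integers 1-9
    trial_index: np.ndarray  # (n,)
    subject_id: str = "S1"
    fs: float = 100.0
    channel_labels: list[str] = field(default_factory=list)
    subject_index: np.ndarray | None = None  # set for pooled multi-subject sets

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D tensor (n, channels, samples)")
        n = self.epochs.shape[0]
        if self.kss.shape != (n,) or self.trial_index.shape != (n,):
            raise ValueError("kss and trial_index must have one entry per epoch")
        if np.any((self.kss < 1) | (self.kss > 9)):
            raise ValueError("KSS labels must lie in [1, 9]")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def labels2(self) -> np.ndarray:
        return map_labels(self.kss, TWO_CLASS)

    @property
    def labels5(self) -> np.ndarray:
        return map_labels(self.kss, FIVE_CLASS)

    def labels(self, scheme: LabelScheme) -> np.ndarray:
        return map_labels(self.kss, scheme)

    @staticmethod
    def concat(sets: Sequence["EpochSet"]) -> "EpochSet":
        """Pool epoch sets, offsetting trial indices so trials stay distinct."""
        if not sets:
            raise ValueError("no epoch sets to concatenate")
        offset = 0
        trials, subj = [], []
        for i, es in enumerate(sets):
            trials.append(es.trial_index + offset)
            offset += int(es.trial_index.max()) + 1 if len(es) else 0
            subj.append(np.full(len(es), i))
        return EpochSet(
            epochs=np.concatenate([es.epochs for es in sets]),
            kss=np.concatenate([es.kss for es in sets]),
            trial_index=np.concatenate(trials),
            subject_id="+".join(es.subject_id for es in sets),
            fs=sets[0].fs,
            channel_labels=list(sets[0].channel_labels),
            subject_index=np.concatenate(subj),
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Per-epoch fold ids for k-fold cross-validation."""

    k: int
    fold_ids: np.ndarray
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_ids == fold

    def train_mask(self, fold: int) -> np.ndarray:
        return self.fold_ids != fold


def bandpass_filter(session: RawSession, low: float = 1.0, high: float = 50.0,
                    order: int = 2) -> RawSession:
    """Zero-phase Butterworth band-pass (order-``order`` prototype applied
    forward-backward, so the magnitude response is squared)."""
    nyq = session.fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=session.fs, output="sos")
    # generous padding so edge transients of the slow low-cut pole decay fully
    # (also makes filtering exactly time-reversal symmetric)
    padlen = min(session.n_samples - 1, int(round(10.0 * session.fs / low)))
    filtered = sps.sosfiltfilt(sos, session.data, axis=1, padlen=padlen)
    return session.copy_with(data=filtered)


def notch_filter(session: RawSession, f0: float = 60.0, q: float = 30.0) -> RawSession:
    """Zero-phase IIR notch at ``f0`` (power-line removal)."""
    nyq = session.fs / 2.0
    if f0 >= nyq:
        raise ValueError(f"notch frequency {f0} Hz must be below Nyquist {nyq} Hz")
    b, a = sps.iirnotch(f0, q, fs=session.fs)
    padlen = min(session.n_samples - 1, int(round(10.0 * session.fs)))
    filtered = sps.filtfilt(b, a, session.data, axis=1, padlen=padlen)
    return session.copy_with(data=filtered)


def downsample(session: RawSession, target_fs: float = 100.0) -> RawSession:
    """Integer-factor decimation by sample selection.

    The preceding band-pass (<= 50 Hz) acts as the anti-alias filter, so
    plain stride decimation is exact for in-band content.  Event sample
    indices are rescaled onto the new clock.
    """
    factor = session.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs {session.fs} not an integer multiple of target {target_fs}")
    factor = int(round(factor))
    data = session.data[:, ::factor].copy()
    events = [Event(e.sample // factor, e.kind, e.kss) for e in session.events]
    return session.copy_with(data=data, events=events, fs=target_fs)


def reject_eog_ics(session: RawSession, threshold: float = 0.7, seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-3,
                   on_nonconvergence: str = "warn") -> RawSession:
    """Remove ocular components from the EEG by reference-correlated ICA.

    The EEG block is unmixed into as many independent components as there
    are EEG channels; any component whose absolute Pearson correlation with
    at least one EOG reference channel exceeds ``threshold`` is zeroed
    before reconstruction.  EOG channels pass through untouched.

    The iteration cap is reported as a warning by default; the decomposition
    remains a lossless linear factorization even then, and sparse ocular
    components are the part the fixed-point iteration locks onto first.
    Pass ``on_nonconvergence='raise'`` to treat the cap as an error.
    """
    if on_nonconvergence not in ("warn", "raise"):
        raise ValueError(f"on_nonconvergence must be 'warn' or 'raise', got {on_nonconvergence!r}")
    eeg_idx = session.eeg_indices()
    eog_idx = session.eog_indices()
    if eog_idx.size < 4:
        raise ValueError("at least 4 EOG reference channels are required")
    x_eeg = session.data[eeg_idx].T  # (samples, channels)
    ica = FastICA(n_components=eeg_idx.size, random_state=seed, max_iter=max_iter,
                  tol=tol, whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x_eeg)  # (samples, components)
        conv_warnings = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
    if conv_warnings and on_nonconvergence == "raise":
        raise RuntimeError(
            "ICA did not converge "
            f"(max_iter={max_iter}, tol={tol}, n_iter={getattr(ica, 'n_iter_', '?')}); "
            "consider raising max_iter or relaxing tol"
        )
    if conv_warnings:
        warnings.warn(
            f"ICA hit the iteration cap (max_iter={max_iter}, tol={tol}); "
            "proceeding with the current unmixing",
            RuntimeWarning,
            stacklevel=2,
        )

    eog = session.data[eog_idx]
    n_comp = sources.shape[1]
    rejected = np.zeros(n_comp, dtype=bool)
    for c in range(n_comp):
        src = sources[:, c]
        src_sd = src.std()
        for r in range(eog.shape[0]):
            ref = eog[r]
            ref_sd = ref.std()
            if src_sd == 0 or ref_sd == 0:
                continue
            r_val = np.corrcoef(src, ref)[0, 1]
            if abs(r_val) > threshold:
                rejected[c] = True
                break
    sources[:, rejected] = 0.0
    x_clean = ica.inverse_transform(sources).T

    data = session.data.copy()
    data[eeg_idx] = x_clean
    return session.copy_with(data=data)


def segment_epochs(session: RawSession, trial_flight_s: float = 60.0,
                   kss_window_s: float = 10.0, epoch_s: float = 1.0) -> EpochSet:
    """Cut each trial's flight segment into non-overlapping 1-s epochs.

    The report window after the beep is excluded entirely.  Each epoch
    inherits its trial's reported KSS; trials without a response event are
    treated as KSS 9.
    """
    fs = session.fs
    epoch_len = int(round(epoch_s * fs))
    per_trial = int(round(trial_flight_s / epoch_s))
    flight_samples = per_trial * epoch_len
    window_samples = int(round(kss_window_s * fs))

    starts = [e.sample for e in session.events if e.kind == "trial_start"]
    if not starts:
        raise ValueError("session has no trial_start events")
    eeg_idx = session.eeg_indices()

    epochs, kss_list, trial_ids = [], [], []
    for trial, t0 in enumerate(starts):
        if t0 + flight_samples > session.n_samples:
            raise ValueError(
                f"trial {trial} is shorter than the expected flight segment "
                f"({session.n_samples - t0} < {flight_samples} samples)"
            )
        beep = t0 + flight_samples
        kss_value = 9  # missed report defaults to the maximal sleepiness value
        for e in session.events:
            if e.kind == "kss_response" and beep < e.sample <= beep + window_samples:
                kss_value = e.kss
                break
        block = session.data[eeg_idx, t0 : t0 + flight_samples]
        epochs.append(block.reshape(eeg_idx.size, per_trial, epoch_len).transpose(1, 0, 2))
        kss_list.extend([kss_value] * per_trial)
        trial_ids.extend([trial] * per_trial)

    return EpochSet(
        epochs=np.concatenate(epochs),
        kss=np.asarray(kss_list),
        trial_index=np.asarray(trial_ids),
        subject_id=session.subject_id,
        fs=fs,
        channel_labels=[session.channel_labels[i] for i in eeg_idx],
    )


def make_folds(epochs: EpochSet, k: int = 4, seed: int = 0,
               granularity: str = "sample") -> FoldAssignment:
    """Assign each epoch to one of ``k`` folds.

    ``sample`` granularity partitions the epochs of every trial into k
    near-equal random parts (sizes differ by at most one), so each fold's
    test set holds ~1/k of every trial.  ``trial`` granularity assigns whole
    trials to folds instead.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    n = len(epochs)
    fold_ids = np.full(n, -1, dtype=int)
    if granularity == "sample":
        for trial in np.unique(epochs.trial_index):
            idx = np.flatnonzero(epochs.trial_index == trial)
            if idx.size < k:
                raise ValueError(f"trial {trial} has fewer epochs ({idx.size}) than folds ({k})")
            perm = rng.permutation(idx)
            for fold, part in enumerate(np.array_split(perm, k)):
                fold_ids[part] = fold
    elif granularity == "trial":
        trials = np.unique(epochs.trial_index)
        perm = rng.permutation(trials)
        for fold, part in enumerate(np.array_split(perm, k)):
            for trial in part:
                fold_ids[epochs.trial_index == trial] = fold
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    assert np.all(fold_ids >= 0)
    return FoldAssignment(k=k, fold_ids=fold_ids, seed=seed)
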