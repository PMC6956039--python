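"""Electrode montage: 30 scalp EEG channels (10-20 system) plus 4 EOG references."""

from __future__ import annotations

import re

# Hyphen shorthand as commonly printed for this montage: "Fp1-2" means Fp1, Fp2.
EEG_SHORTHAND = (
    "Fp1-2, F3-4, Fz, FC1-2, FC5-6, T7-8, C3-4, Cz, CP1-2, CP5-6, "
    "TP9-10, P3-4, P7-8, Pz, PO9-10, O1-2, Oz"
)

EOG_LABELS = ("EOG1", "EOG2", "EOG3", "EOG4")

_PAIR_RE = re.compile(r"^([A-Za-z]+)(\d+)-(\d+)$")


def expand_shorthand(shorthand: str) -> list[str]:
    """Expand a comma-separated hyphen shorthand into individual labels.

    ``"Fp1-2"`` expands to ``["Fp1", "Fp2"]``; plain labels pass through.
    """
    labels: list[str] = []
    for token in shorthand.split(","):
        token = token.strip()
        if not token:
            continue
        m = _PAIR_RE.match(token)
        if m:
            prefix, a, b = m.groups()
            labels.append(f"{prefix}{a}")
            labels.append(f"{prefix}{b}")
        else:
            labels.append(token)
    return labels


def eeg_labels() -> list[str]:
    """The 30 scalp EEG channel labels, in montage order."""
    return expand_shorthand(EEG_SHORTHAND)


def eog_labels() -> list[str]:
    """The 4 EOG reference channel labels."""
    return list(EOG_LABELS)


def montage() -> list[str]:
    """All 34 channel labels: 30 EEG followed by 4 EOG."""
    return eeg_labels() + eog_labels()


# Scalp regions used by the simulator to place band-specific drowsiness
# signatures and by analyses to group channels.
FRONTAL = ("Fp1", "Fp2", "F3", "F4", "Fz", "FC1", "FC2", "FC5", "FC6")
TEMPOROPARIETAL = ("T7", "T8", "TP9", "TP10", "CP5", "CP6", "P7", "P8")
OCCIPITOPARIETAL = ("P3", "P4", "Pz", "PO9", "PO10", "O1", "O2", "Oz")
CENTRAL = ("C3", "C4", "Cz", "CP1", "CP2")

REGIONS = {
    "frontal": FRONTAL,
    "temporoparietal": TEMPOROPARIETAL,
    "occipitoparietal": OCCIPITOPARIETAL,
    "central": CENTRAL,
}


def region_of(label: str) -> str | None:
    for name, channels in REGIONS.items():
        if label in channels:
            return name
    return None
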