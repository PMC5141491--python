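"""Channel montages.

A 61-channel 10-10 layout for the full protocol emulation (61 scalp
channels at 256 Hz, common average computed without the fronto-polar
channels, 3 bad channels removed before connectivity, leaving 58), and a
19-channel 10-20 layout used for cheap simulation studies.
"""

from __future__ import annotations

#: 61-channel extended 10-10 montage.
LABELS_61: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Fronto-polar channels excluded from the common-average reference.
REFERENCE_EXCLUSIONS: tuple[str, ...] = ("Fp1", "AF3", "AF7", "Fp2", "AF4", "AF8")

#: Default bad channels under the full-protocol emulation (61 - 3 = 58 retained).
DEFAULT_BAD_CHANNELS: tuple[str, ...] = ("T7", "T8", "TP8")

#: Classic 19-channel 10-20 montage for reduced-scale simulation studies.
LABELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)


def default_labels(n_channels: int) -> tuple[str, ...]:
    """Labels for a simulated montage of ``n_channels`` channels."""
    if n_channels == 61:
        return LABELS_61
    if n_channels == 19:
        return LABELS_19
    return tuple(f"CH{i + 1:02d}" for i in range(n_channels))
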