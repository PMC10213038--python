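"""Channel montage and spectral band definitions.

The recording montage is a 32-channel 10-20 layout sampled at 500 Hz.
Four frontal channels contaminated by ocular artifacts are excluded from
analysis, and the remaining data are re-referenced to Cz (which is then
dropped), leaving 27 analysis channels. Five canonical EEG bands partition
the 2-45 Hz passband; per-channel relative band power over these bands
yields the 27 x 5 = 135-dimensional feature space.
"""

from __future__ import annotations

# Acquisition order of the 32-channel cap.
CHANNELS_32: tuple[str, ...] = (
    "P8", "T8", "AF7", "AF8", "F8", "F4", "C4", "P4", "FC5", "AF4",
    "Fp2", "Fp1", "AF3", "Fz", "C6", "Cz", "C5", "PO3", "O1", "Oz",
    "O2", "PO4", "Pz", "Fpz", "FC6", "P3", "C3", "F3", "F7", "FCz",
    "T7", "P7",
)

# Frontal channels removed before feature extraction (ocular artifacts).
FRONTAL_DROP: tuple[str, ...] = ("AF4", "Fp2", "Fp1", "AF3")

# Reference electrode; subtracted from all channels, then excluded.
REFERENCE: str = "Cz"

# The 27 channels that carry features, in acquisition order.
ANALYSIS_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in CHANNELS_32 if ch not in FRONTAL_DROP and ch != REFERENCE
)

# Band edges are half-open [low, high) so shared edges are not double-counted.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 45.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in BANDS)

N_FEATURES: int = len(ANALYSIS_CHANNELS) * len(BANDS)

# Coarse scalp regions used to parameterize phenotype topographies.
POSTERIOR: tuple[str, ...] = ("O1", "Oz", "O2", "PO3", "PO4", "Pz", "P3", "P4", "P7", "P8")
CENTRAL: tuple[str, ...] = ("C3", "C4", "C5", "C6", "Cz", "FCz", "T7", "T8")
FRONTAL: tuple[str, ...] = ("F3", "F4", "Fz", "F7", "F8", "Fpz", "AF7", "AF8", "FC5", "FC6",
                            "AF4", "Fp2", "Fp1", "AF3")


def feature_names() -> list[str]:
    """Column names of the flattened 135-vector: ``<channel>_<band>``,
    channels in acquisition order (exclusions removed), bands delta..gamma."""
    return [f"{ch}_{band}" for ch in ANALYSIS_CHANNELS for band in BAND_NAMES]
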