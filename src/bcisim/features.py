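"""Binned neural feature container shared by the generator, signal chain and decoders.

The decoders' common currency is a stream of 15-ms bins, each holding one
threshold-crossing count and one high-frequency LFP (HF-LFP) band-power value
per channel, plus the per-channel baseline currently being subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_WIDTH_S = 0.015
BIN_WIDTH_MS = 15
CROSSING_RESOLUTION_MS = 1


@dataclass
class BinnedFeatures:
    """Per-bin threshold-crossing counts and HF-LFP power for one stream.

    Parameters
    ----------
    timestamps : (T,) float array
        Bin start times in seconds; bins are half-open ``[t, t + 15 ms)``.
    crossings : (T, C) array
        Non-negative integer threshold-crossing counts per channel per bin.
        Bounded above by ``bin_width / crossing_resolution`` (15 with the
        standard 1-ms presence detector).
    hf_power : (T, C) array
        Non-negative HF-LFP band power per channel per bin (arbitrary units).
    baseline : (2C,) array or None
        Per-feature offset currently subtracted downstream, ordered as
        ``[crossings..., hf_power...]``.  ``None`` until estimated.
    """

    timestamps: np.ndarray
    crossings: np.ndarray
    hf_power: np.ndarray
    baseline: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.crossings = np.asarray(self.crossings)
        self.hf_power = np.asarray(self.hf_power, dtype=float)
        if self.crossings.shape != self.hf_power.shape:
            raise ValueError("crossings and hf_power must have the same shape")
        if self.crossings.shape[0] != self.timestamps.shape[0]:
            raise ValueError("one timestamp per bin required")
        if np.any(self.crossings < 0):
            raise ValueError("crossing counts must be non-negative")
        if np.any(self.hf_power < 0):
            raise ValueError("hf_power must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.crossings.shape[0]

    @property
    def n_channels(self) -> int:
        return self.crossings.shape[1]

    def matrix(self, feature_set: str = "both") -> np.ndarray:
        """Return the (T, m) feature matrix for one feature family.

        ``feature_set`` is ``"spikes"`` (crossing counts), ``"hf"`` (HF-LFP
        power) or ``"both"`` (columns stacked as crossings then power).
        """
        if feature_set == "spikes":
            return self.crossings.astype(float)
        if feature_set == "hf":
            return self.hf_power
        if feature_set == "both":
            return np.hstack([self.crossings.astype(float), self.hf_power])
        raise ValueError(f"unknown feature_set {feature_set!r}")

    def feature_slice(self, feature_set: str) -> slice:
        """Column range of one family inside the ``"both"`` matrix."""
        c = self.n_channels
        if feature_set == "spikes":
            return slice(0, c)
        if feature_set == "hf":
            return slice(c, 2 * c)
        if feature_set == "both":
            return slice(0, 2 * c)
        raise ValueError(f"unknown feature_set {feature_set!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (bin_index, timestamp_s, tx_*, hf_* columns)."""
        c = self.n_channels
        data = {"bin_index": np.arange(self.n_bins), "timestamp_s": self.timestamps}
        for i in range(c):
            data[f"tx_{i:03d}"] = self.crossings[:, i]
        for i in range(c):
            data[f"hf_{i:03d}"] = self.hf_power[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinnedFeatures":
        tx_cols = sorted(col for col in frame.columns if col.startswith("tx_"))
        hf_cols = sorted(col for col in frame.columns if col.startswith("hf_"))
        return cls(
            timestamps=frame["timestamp_s"].to_numpy(),
            crossings=frame[tx_cols].to_numpy(),
            hf_power=frame[hf_cols].to_numpy(),
        )

    def concat(self, other: "BinnedFeatures") -> "BinnedFeatures":
        return BinnedFeatures(
            timestamps=np.concatenate([self.timestamps, other.timestamps]),
            crossings=np.vstack([self.crossings, other.crossings]),
            hf_power=np.vstack([self.hf_power, other.hf_power]),
            baseline=self.baseline,
        )
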