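"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class UltrasoundFrameSequence:
    """Ordered grayscale frames with a common shape and frame rate.

    Frames are stored as a (n_frames, rows, cols) array, pixel (0, 0) top
    left.  ``t0`` is the acquisition start time in seconds; frame *i* is
    timestamped ``t0 + i / frame_rate``.
    """

    frames: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError("frames must be a (n, rows, cols) array")
        if len(self.frames) == 0:
            raise ValidationError("no frames")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.frames)) / self.frame_rate

    @property
    def duration(self) -> float:
        """Time span covered by the frames (seconds)."""
        return len(self.frames) / self.frame_rate


@dataclass
class TemperatureTrace:
    """Ground-truth temperatures (°C), nominally sampled at 1 Hz."""

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if self.times.shape != self.temps.shape or self.times.ndim != 1:
            raise ValidationError("times and temps must be equal-length 1D arrays")
        if len(self.times) == 0:
            raise ValidationError("empty trace")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "temp_C": self.temps}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TemperatureTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["temp_C"].to_numpy())


@dataclass
class RoiSpec:
    """Square region of interest, 0-based center, half-open extents."""

    center_row: int
    center_col: int
    size: int = 64

    def __post_init__(self):
        if self.size < 1:
            raise ValidationError("ROI size must be >= 1")

    def bounds(self) -> tuple[int, int, int, int]:
        """(row_start, row_stop, col_start, col_stop), half-open."""
        half = self.size // 2
        r0 = self.center_row - half
        c0 = self.center_col - half
        return r0, r0 + self.size, c0, c0 + self.size


#: channels used as model input by default; gray_temperature_grad requires the
#: measured temperature (the prediction target) and is excluded unless the
#: leakage-documented mode is explicitly enabled.
DEFAULT_CHANNELS = (
    "average_gray_level",
    "gray_level_entropy",
    "gray_temperature_grad",
    "mixture_entropy",
    "inertia",
    "inverse_difference_moment",
)

DEFAULT_MODEL_CHANNELS = tuple(
    c for c in DEFAULT_CHANNELS if c != "gray_temperature_grad"
)


@dataclass
class FeatureSeries:
    """Multichannel per-second texture feature series aligned to a trace."""

    times: np.ndarray
    channels: dict[str, np.ndarray]
    temps: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.times.shape:
                raise ValidationError(f"channel {name!r} length mismatch")
            if np.isnan(v).any():
                raise ValidationError(f"channel {name!r} contains NaN")
            self.channels[name] = v

    def __len__(self) -> int:
        return len(self.times)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def matrix(self, names: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        """Stack channels into a (T, n_channels) matrix."""
        names = list(names) if names is not None else self.channel_names
        return np.stack([self.channels[n] for n in names], axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"time_s": self.times}
        if self.temps is not None:
            data["temp_C"] = self.temps
        data.update(self.channels)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureSeries":
        temps = df["temp_C"].to_numpy() if "temp_C" in df else None
        chans = {
            c: df[c].to_numpy()
            for c in df.columns
            if c not in ("time_s", "temp_C")
        }
        return cls(df["time_s"].to_numpy(), chans, temps)

    @classmethod
    def from_csv(cls, path) -> "FeatureSeries":
        return cls.from_dataframe(pd.read_csv(path))
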