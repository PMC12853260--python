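"""Core data containers: continuous recordings, trial-epoched datasets,
and the channel-to-ROI map.

Arrays follow the convention ``(channels, time, trials)`` for epoched data
and ``(channels, samples)`` for continuous data.  Time is referenced to the
trial onset: sample ``k`` of an epoch occurs at ``(k - onset_index) * dt``
seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["TrialDataset", "ContinuousRecording", "ChannelMap"]


@dataclass
class TrialDataset:
    """Trial-epoched multichannel signals for one experimental condition.

    Parameters
    ----------
    data : (n_channels, n_times, n_trials) float array
    dt : sampling interval in seconds
    onset_index : sample index corresponding to 0 s (trial onset)
    phase : optional condition tag, e.g. ``"pre"`` or ``"post"``
    hand : optional condition tag, e.g. ``"unaffected"`` or ``"affected"``
    """

    data: np.ndarray
    dt: float
    onset_index: int
    phase: str | None = None
    hand: str | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, time, trials)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.onset_index < self.data.shape[1]:
            raise ValueError("onset_index must lie within the epoch")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to trial onset."""
        return (np.arange(self.n_times) - self.onset_index) * self.dt

    def select_channels(self, idx) -> "TrialDataset":
        idx = np.asarray(idx)
        return dataclasses.replace(
            self,
            data=self.data[idx],
            channel_names=[self.channel_names[i] for i in idx],
        )

    def select_trials(self, idx) -> "TrialDataset":
        return dataclasses.replace(self, data=self.data[:, :, np.asarray(idx)])

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, target) -> None:
        """Write to an HDF5 file path or open group."""
        if isinstance(target, (str, Path)):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        target.create_dataset("data", data=self.data)
        target.attrs["dt"] = self.dt
        target.attrs["onset_index"] = self.onset_index
        target.attrs["phase"] = self.phase or ""
        target.attrs["hand"] = self.hand or ""
        target.attrs["channel_names"] = [str(c) for c in self.channel_names]

    @classmethod
    def from_hdf5(cls, source) -> "TrialDataset":
        if isinstance(source, (str, Path)):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in source.attrs["channel_names"]
        ]
        return cls(
            data=source["data"][()],
            dt=float(source.attrs["dt"]),
            onset_index=int(source.attrs["onset_index"]),
            phase=str(source.attrs["phase"]) or None,
            hand=str(source.attrs["hand"]) or None,
            channel_names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (condition, trial, channel, sample, value)."""
        n, t, r = self.data.shape
        ch, ti, tr = np.meshgrid(np.arange(n), np.arange(t), np.arange(r), indexing="ij")
        return pd.DataFrame(
            {
                "phase": self.phase or "",
                "hand": self.hand or "",
                "trial": tr.ravel(),
                "channel": ch.ravel(),
                "sample": ti.ravel(),
                "value": self.data.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# dt={self.dt} onset_index={self.onset_index}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
            frame = pd.read_csv(fh)
        n = int(frame["channel"].max()) + 1
        t = int(frame["sample"].max()) + 1
        r = int(frame["trial"].max()) + 1
        data = np.zeros((n, t, r))
        data[frame["channel"], frame["sample"], frame["trial"]] = frame["value"]
        phase = str(frame["phase"].iloc[0]) if frame["phase"].notna().all() else None
        hand = str(frame["hand"].iloc[0]) if frame["hand"].notna().all() else None
        return cls(
            data=data,
            dt=float(meta["dt"]),
            onset_index=int(meta["onset_index"]),
            phase=phase or None,
            hand=hand or None,
        )


@dataclass
class ContinuousRecording:
    """Continuous multichannel recording with trial-onset markers.

    ``pathway`` optionally groups rows that measure the same channel through
    the two directions of a bidirectional optical pathway; rows sharing a
    pathway id are averaged by :func:`nirsgc.preprocess.collapse_pathways`.
    """

    data: np.ndarray
    dt: float
    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    channel_names: list[str] | None = None
    pathway: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.size:
            if np.any(np.diff(self.onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if self.onsets.min() < 0 or self.onsets.max() >= self.data.shape[1]:
                raise ValueError("onsets must lie within the recording")
        if self.channel_names is None:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class ChannelMap:
    """Assignment of channels to ROIs and hemispheres.

    Backed by a table with columns ``channel`` (integer index), ``roi``
    (label or ``"unassigned"``), ``hemisphere`` (``"ip"``, ``"co"`` or
    ``"medial"``) and ``seed`` (0/1 flag for seed channels).  Unassigned
    channels stay in the GC conditioning set but are excluded from
    region-level summaries.
    """

    HEMIS = ("ip", "co", "medial")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        required = {"channel", "roi", "hemisphere"}
        if not required.issubset(table.columns):
            raise ValueError(f"channel map needs columns {sorted(required)}")
        if "seed" not in table.columns:
            table["seed"] = 0
        if table["channel"].duplicated().any():
            raise ValueError("each channel maps to at most one ROI")
        bad = set(table["hemisphere"]) - set(self.HEMIS) - {"unassigned"}
        if bad:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad)}")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_assignments(cls, rois: dict[str, list[int]], hemispheres: dict[str, str],
                         n_channels: int, seeds: list[int] | None = None) -> "ChannelMap":
        rows = []
        assigned = {}
        for roi, chans in rois.items():
            for ch in chans:
                assigned[ch] = roi
        for ch in range(n_channels):
            roi = assigned.get(ch, "unassigned")
            hemi = hemispheres.get(roi, "unassigned")
            rows.append(
                {"channel": ch, "roi": roi, "hemisphere": hemi,
                 "seed": int(bool(seeds and ch in seeds))}
            )
        return cls(pd.DataFrame(rows))

    def rois(self) -> list[str]:
        out = [r for r in self.table["roi"].unique() if r != "unassigned"]
        return sorted(out)

    def channels_in(self, roi: str) -> np.ndarray:
        return self.table.loc[self.table["roi"] == roi, "channel"].to_numpy()

    def hemisphere_of(self, roi: str) -> str:
        rows = self.table.loc[self.table["roi"] == roi, "hemisphere"]
        if rows.empty:
            raise KeyError(f"unknown ROI {roi!r}")
        return str(rows.iloc[0])

    def seeds(self) -> np.ndarray:
        return self.table.loc[self.table["seed"] > 0, "channel"].to_numpy()

    def roi_of(self, channel: int) -> str:
        rows = self.table.loc[self.table["channel"] == channel, "roi"]
        return str(rows.iloc[0]) if not rows.empty else "unassigned"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChannelMap":
        return cls(pd.read_csv(path))
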