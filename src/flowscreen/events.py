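"""Per-cell event tables: the universal container for flow-cytometry data.

An :class:`EventTable` holds one row per acquired cell event and one column per
fluorescence channel, on the raw linear scale. Tables are loaded from CSV/TSV
event matrices (header row = channel names) or FCS 3.0/3.1 files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = ["EventTable", "load_events"]


@dataclass
class EventTable:
    """Fluorescence intensity matrix for one stained (or control) sample.

    Parameters
    ----------
    data
        One row per cell event, one column per channel; linear intensity units.
    sample_id
        Free-text sample identifier.
    metadata
        Arbitrary annotations (donor, condition, antibody well, ...).
    """

    data: pd.DataFrame
    sample_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        cols = [str(c) for c in self.data.columns]
        if len(set(cols)) != len(cols):
            raise FormatError(f"duplicate channel names in event table: {cols}")
        self.data.columns = cols
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise FormatError("event table contains non-finite intensities")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def values(self, channel: str) -> np.ndarray:
        """Intensities on one channel as a float array."""
        if channel not in self.data.columns:
            raise KeyError(f"channel {channel!r} not in {self.channels}")
        return self.data[channel].to_numpy(dtype=float)

    def select(self, mask: np.ndarray) -> "EventTable":
        """Row-subset preserving order, sample_id and metadata."""
        return EventTable(
            self.data.loc[np.asarray(mask, dtype=bool)],
            sample_id=self.sample_id,
            metadata=dict(self.metadata),
        )

    @classmethod
    def from_arrays(
        cls,
        events: np.ndarray | Iterable[Iterable[float]],
        channels: Iterable[str],
        sample_id: str = "",
        metadata: Mapping[str, Any] | None = None,
    ) -> "EventTable":
        channels = list(channels)
        arr = np.asarray(events, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, len(channels))
        if arr.ndim != 2 or arr.shape[1] != len(channels):
            raise FormatError(
                f"event matrix shape {arr.shape} does not match {len(channels)} channels"
            )
        return cls(pd.DataFrame(arr, columns=channels), sample_id, dict(metadata or {}))


def load_events(path: str | Path, format: str | None = None, sample_id: str | None = None) -> EventTable:
    """Load an event table from a CSV/TSV matrix or an FCS 3.0/3.1 file.

    ``format`` is ``"csv"``, ``"tsv"`` or ``"fcs"``; when omitted it is inferred
    from the file suffix. The channel list follows the file header and event
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"csv": "csv", "tsv": "tsv", "txt": "tsv", "fcs": "fcs"}.get(suffix)
        if format is None:
            raise FormatError(f"cannot infer format from suffix of {path.name}")
    sid = sample_id if sample_id is not None else path.stem

    if format == "fcs":
        from .fcs import read_fcs

        return read_fcs(path, sample_id=sid)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, header=0, dtype=float)
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
        if df.isna().to_numpy().any():
            raise FormatError(f"{path}: missing or ragged values in event matrix")
        return EventTable(df, sample_id=sid)
    raise FormatError(f"unknown format {format!r}")
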