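"""In-memory event container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytofpipe.panel import PanelSpec


@dataclass
class EventTable:
    """Events x channels matrix with channel metadata and per-event ids.

    ``data`` columns are channel names in ``metal_Marker`` convention and
    align with ``panel.channels``. ``sample_ids`` (optional) annotates each
    event with its sample of origin (after debarcoding), ``batch_id`` names
    the acquisition batch.
    """

    data: pd.DataFrame
    panel: PanelSpec
    batch_id: str | None = None
    sample_ids: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols != self.panel.names:
            raise ValueError("data columns do not match panel channel names")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != len(self.data):
                raise ValueError("sample_ids length does not match event count")
        if self.meta is not None and len(self.meta) != len(self.data):
            raise ValueError("meta length does not match event count")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def marker_values(self, markers: list[str] | str) -> pd.DataFrame | pd.Series:
        """Values for antibody markers addressed by marker name."""
        if isinstance(markers, str):
            return self.data[self.panel.by_marker(markers).name]
        return self.data[[self.panel.by_marker(m).name for m in markers]]

    def channel_values(self, name: str) -> pd.Series:
        return self.data[name]

    def take(self, idx: np.ndarray) -> "EventTable":
        """Row subset (positional indices or boolean mask)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EventTable(
            self.data.iloc[idx].reset_index(drop=True),
            self.panel,
            batch_id=self.batch_id,
            sample_ids=None if self.sample_ids is None else self.sample_ids[idx],
            meta=None if self.meta is None else self.meta.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "EventTable":
        return EventTable(
            self.data.copy(),
            self.panel,
            batch_id=self.batch_id,
            sample_ids=None if self.sample_ids is None else self.sample_ids.copy(),
            meta=None if self.meta is None else self.meta.copy(),
        )


def concat_tables(tables: list[EventTable]) -> EventTable:
    """Pool event tables sharing one panel; keeps sample annotations."""
    if not tables:
        raise ValueError("no tables to concatenate")
    panel = tables[0].panel
    for t in tables[1:]:
        if t.panel.names != panel.names:
            raise ValueError("tables have mismatched panels; harmonize first")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    if all(t.sample_ids is not None for t in tables):
        sids = np.concatenate([t.sample_ids for t in tables])
    else:
        sids = None
    if all(t.meta is not None for t in tables):
        meta = pd.concat([t.meta for t in tables], ignore_index=True)
    else:
        meta = None
    batch = tables[0].batch_id if len({t.batch_id for t in tables}) == 1 else None
    return EventTable(data, panel, batch_id=batch, sample_ids=sids, meta=meta)
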