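"""FCS batch harmonization, palladium debarcoding and acquisition planning."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from itertools import combinations

from cytofpipe.core import EventTable
from cytofpipe.panel import Channel, PanelSpec


# ---------------------------------------------------------------------------
# barcode key
# ---------------------------------------------------------------------------


@dataclass
class BarcodeKey:
    """k-hot-of-n combinatorial barcode scheme.

    ``barcodes`` maps barcode id to the set of hot channel names. All hot
    sets have size ``k_hot`` and are distinct.
    """

    barcodes: dict[str, frozenset[str]]
    n_channels: int
    k_hot: int

    def __post_init__(self) -> None:
        if self.k_hot >= self.n_channels:
            raise ValueError("k_hot must be smaller than the number of key channels")
        sets = list(self.barcodes.values())
        if any(len(s) != self.k_hot for s in sets):
            raise ValueError("every hot set must have size k_hot")
        if len(set(sets)) != len(sets):
            raise ValueError("hot sets must be distinct")

    @property
    def channels(self) -> list[str]:
        out = sorted({c for s in self.barcodes.values() for c in s})
        return out

    def barcode_for_index(self, i: int) -> str:
        return list(self.barcodes)[i]


def default_barcode_key(channels: list[str] | None = None) -> BarcodeKey:
    """20-plex key: every 3-hot combination of the six palladium channels."""
    if channels is None:
        channels = ["102Pd_BC1", "104Pd_BC2", "105Pd_BC3",
                    "106Pd_BC4", "108Pd_BC5", "110Pd_BC6"]
    combos = list(combinations(channels, 3))
    barcodes = {f"BC{i + 1:02d}": frozenset(c) for i, c in enumerate(combos)}
    return BarcodeKey(barcodes, n_channels=len(channels), k_hot=3)


# ---------------------------------------------------------------------------
# panel harmonization
# ---------------------------------------------------------------------------


def harmonize_panels(
    tables: list[EventTable],
    rename_map: dict[str, str] | None = None,
    drop: set[str] | None = None,
    strict: bool = True,
) -> list[EventTable]:
    """Bring all tables onto one ordered channel set.

    ``rename_map`` maps old channel names to new ones; a rename that
    strips the marker (e.g. ``155Gd_IRF4 -> 155Gd``) marks the channel
    role ``excluded`` (present but ignored during analysis). Channels in
    ``drop`` are removed everywhere. Channels present in only some tables
    raise under ``strict``; otherwise they are dropped.
    """
    rename_map = rename_map or {}
    drop = set(drop or ())
    for old in rename_map:
        if not any(old in t.panel.names for t in tables):
            raise ValueError(f"rename source channel {old!r} found in no table")

    renamed: list[EventTable] = []
    for t in tables:
        panel = t.panel
        df = t.data
        for old, new in rename_map.items():
            if old not in panel.names:
                continue
            metal, _, marker = new.partition("_")
            role = "excluded" if not marker else None
            panel = panel.rename(old, metal, marker, role=role)
            df = df.rename(columns={old: new})
        renamed.append(EventTable(df[panel.names], panel,
                                  batch_id=t.batch_id, sample_ids=t.sample_ids))

    shared = [n for n in renamed[0].panel.names
              if all(n in t.panel.names for t in renamed) and n not in drop]
    out = []
    for i, t in enumerate(renamed):
        extra = [n for n in t.panel.names if n not in shared and n not in drop]
        if extra and strict:
            raise ValueError(
                f"table {t.batch_id or i} has channels not shared by all "
                f"batches: {extra} (pass strict=False to drop them)"
            )
        chans = [t.panel.by_name(n) for n in shared]
        panel = PanelSpec(chans, t.panel.cofactor)
        out.append(EventTable(t.data[shared], panel,
                              batch_id=t.batch_id, sample_ids=t.sample_ids))
    return out


# ---------------------------------------------------------------------------
# debarcoding
# ---------------------------------------------------------------------------


@dataclass
class DebarcodeResult:
    """Per-event barcode assignment with separation and Mahalanobis
    diagnostics; ``assignment`` holds the barcode id or ``None``."""

    assignment: np.ndarray
    separation: np.ndarray
    mahalanobis: np.ndarray
    counts: pd.Series

    @property
    def n_assigned(self) -> int:
        return int(sum(a is not None for a in self.assignment))


def _rescale_barcode(
    x: np.ndarray, lo_pct: float = 0.1, hi_pct: float = 99.9
) -> np.ndarray:
    """Map each barcode channel to [0, 1] by its within-file percentile
    range (defaults 0.1/99.9)."""
    lo = np.percentile(x, lo_pct, axis=0)
    hi = np.percentile(x, hi_pct, axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return np.clip((x - lo) / span, 0.0, 1.0)


def debarcode(
    table: EventTable,
    key: BarcodeKey,
    min_separation: float = 0.12,
    max_distance: float = 30.0,
    cofactor: float | None = None,
    rescale_percentiles: tuple[float, float] = (0.1, 99.9),
) -> DebarcodeResult:
    """Single-cell debarcoding with separation and Mahalanobis filters.

    Barcode channels are arcsinh transformed, rescaled to [0, 1] by their
    within-file percentile range, and sorted per event. The separation is
    the gap between the k-th and (k+1)-th largest normalized intensities;
    an event is preliminarily assigned to the key whose hot set equals its
    top-k channels, dropped if separation < ``min_separation``, and then
    dropped if its Mahalanobis distance to its preliminary barcode
    population (in normalized barcode space) exceeds ``max_distance``.
    """
    chans = key.channels
    missing = [c for c in chans if c not in table.panel.names]
    if missing:
        raise ValueError(f"table lacks barcode channels {missing}")
    cofactor = cofactor or table.panel.cofactor
    n = table.n_events
    x = np.arcsinh(table.data[chans].to_numpy(dtype=float) / cofactor)
    z = _rescale_barcode(x, *rescale_percentiles)

    k = key.k_hot
    order = np.argsort(z, axis=1)  # ascending
    sorted_z = np.take_along_axis(z, order, axis=1)
    separation = sorted_z[:, -k] - sorted_z[:, -(k + 1)]

    lookup = {hot: bid for bid, hot in key.barcodes.items()}
    chan_arr = np.array(chans, dtype=object)
    assignment = np.full(n, None, dtype=object)
    top = order[:, -k:]
    for i in range(n):
        if separation[i] < min_separation or separation[i] <= 0:
            continue  # ties give separation 0, below any positive threshold
        assignment[i] = lookup.get(frozenset(chan_arr[top[i]]))

    # Mahalanobis filter per preliminary barcode population (single pass)
    mahal = np.full(n, np.nan)
    for bid in key.barcodes:
        idx = np.flatnonzero(assignment == bid)
        if idx.size == 0:
            continue
        pts = z[idx]
        mu = pts.mean(axis=0)
        if idx.size > len(chans):
            cov = np.cov(pts, rowvar=False)
        else:
            cov = np.diag(pts.var(axis=0))
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular barcode covariance for {bid}; using diagonal",
                RuntimeWarning, stacklevel=2,
            )
            diag = np.where(np.diag(cov) > 0, np.diag(cov), 1e-12)
            inv = np.diag(1.0 / diag)
        d = pts - mu
        mahal[idx] = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", d, inv, d), 0.0))
        too_far = idx[mahal[idx] > max_distance]
        assignment[too_far] = None

    ids = list(key.barcodes)
    counts = pd.Series(
        [int((assignment == b).sum()) for b in ids] + [int(sum(a is None for a in assignment))],
        index=ids + ["unassigned"],
        name="events",
    )
    return DebarcodeResult(assignment, separation, mahal, counts)


def split_by_barcode(
    table: EventTable,
    result: DebarcodeResult,
    sample_of_barcode: dict[str, str] | None = None,
) -> dict[str, EventTable]:
    """Partition assigned events into per-sample tables; unassigned events
    are discarded. ``sample_of_barcode`` optionally renames barcodes to
    sample ids."""
    if len(result.assignment) != table.n_events:
        raise ValueError("debarcode result does not match table size")
    out: dict[str, EventTable] = {}
    barcodes = [b for b in result.counts.index if b != "unassigned"]
    for bid in barcodes:
        mask = result.assignment == bid
        name = (sample_of_barcode or {}).get(bid, bid)
        sub = table.take(mask)
        sub.sample_ids = np.full(sub.n_events, name, dtype=object)
        out[name] = sub
    return out


# ---------------------------------------------------------------------------
# acquisition planning
# ---------------------------------------------------------------------------


def plan_acquisition(
    n_samples: int,
    target_cells_per_sample: int,
    frac_target: float,
    event_rate: float = 500.0,
) -> tuple[int, int, float]:
    """Events per sample, total events, and acquisition seconds needed to
    collect ``target_cells_per_sample`` target cells when the target
    population is ``frac_target`` of all events at ``event_rate``
    events/second."""
    if not 0 < frac_target <= 1:
        raise ValueError("frac_target must be in (0, 1]")
    if event_rate <= 0:
        raise ValueError("event_rate must be positive")
    events_per_sample = math.ceil(target_cells_per_sample / frac_target)
    total = events_per_sample * n_samples
    return events_per_sample, total, total / event_rate
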