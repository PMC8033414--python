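"""Automated live-CD45+ pre-gating and sample-level exclusion.

The manual strategy this reproduces: Gaussian acquisition-parameter
cleanup versus time, bead-channel exclusion, intact-cell selection on the
iridium DNA intercalator, viability on cisplatin (membrane exclusion
stain), apoptosis exclusion on cleaved caspase-3, and finally CD45
positivity. The original gates were drawn by hand; here every threshold
is derived from the data (the kernel-density valley between the two
major modes, with a permissive robust fallback when a channel is
unimodal) and is config-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cytofpipe.core import EventTable
from cytofpipe.panel import PanelSpec


@dataclass(frozen=True)
class Gate:
    """One 1-D gate on a named channel (transformed scale).

    ``kind`` is ``"interval"`` (pass when lo <= x <= hi), ``"below"`` or
    ``"above"`` a threshold.
    """

    name: str
    channel: str
    kind: str
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self) -> None:
        if self.kind not in {"interval", "below", "above"}:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "interval" and not self.lo < self.hi:
            raise ValueError(f"gate {self.name}: interval needs lo < hi")

    def mask(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "interval":
            return (x >= self.lo) & (x <= self.hi)
        if self.kind == "below":
            return x <= self.hi
        return x >= self.lo


@dataclass
class GateSpec:
    """Ordered gate sequence applied on the transformed scale."""

    gates: list[Gate]

    def validate(self, panel: PanelSpec) -> None:
        for g in self.gates:
            if g.channel not in panel.names:
                raise ValueError(f"gate {g.name}: channel {g.channel!r} missing from panel")


@dataclass
class GatingResult:
    """Nested per-stage pass masks plus final live-CD45+ mask."""

    stage_masks: dict[str, np.ndarray]
    final_mask: np.ndarray

    def counts(self) -> pd.Series:
        return pd.Series({k: int(v.sum()) for k, v in self.stage_masks.items()})


def find_valley(
    x: np.ndarray,
    min_bandwidth: float = 0.15,
    prominence_frac: float = 0.002,
    min_peak_distance: float = 0.8,
    rng_seed: int = 0,
) -> float | None:
    """Density valley between the two major modes of a 1-D sample.

    Estimates a kernel density (bandwidth at least ``min_bandwidth`` on
    the transformed scale, so ion-count discreteness near zero does not
    create spurious modes), finds peaks at least ``min_peak_distance``
    apart, and returns the density minimum between the two most prominent
    ones. Returns ``None`` when the sample is effectively unimodal (a
    minority population may simply be absent); callers choose a
    permissive fallback in that case.
    """
    from scipy.signal import find_peaks
    from scipy.stats import gaussian_kde

    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50 or np.ptp(x) == 0:
        return None
    sub = x if x.size <= 20_000 else np.random.default_rng(rng_seed).choice(x, 20_000, replace=False)
    std = sub.std()
    bw = max(min_bandwidth, std * sub.size ** -0.2)
    kde = gaussian_kde(sub, bw_method=bw / std)
    grid = np.linspace(sub.min(), sub.max(), 512)
    step = grid[1] - grid[0]
    dens = kde(grid)
    peaks, _ = find_peaks(
        dens,
        prominence=prominence_frac * dens.max(),
        distance=max(1, int(round(min_peak_distance / step))),
    )
    if peaks.size < 2:
        return None
    proms = dens[peaks]
    top = np.sort(peaks[np.argsort(proms)[-2:]])
    between = slice(top[0], top[1] + 1)
    return float(grid[top[0] + int(np.argmin(dens[between]))])


def _robust_interval(x: np.ndarray, nmads: float = 5.0) -> tuple[float, float]:
    med = float(np.median(x))
    sd = 1.4826 * float(np.median(np.abs(x - med))) or float(np.std(x)) or 1.0
    return med - nmads * sd, med + nmads * sd


def auto_gate_spec(
    table: EventTable,
    gaussian_nmads: float = 5.0,
) -> GateSpec:
    """Derive the default gate sequence from a transformed event table.

    Stage order: Gaussian parameter intervals vs time -> bead channel low
    -> iridium high (intact) -> cisplatin low (live) -> c-Cas3 low
    (non-apoptotic) -> CD45 high. The acquisition-parameter cleanup keeps
    events within ``gaussian_nmads`` robust standard deviations
    (1.4826 x MAD) of the per-channel median, so only genuine instrument
    outliers fall out.
    """
    panel = table.panel
    gates: list[Gate] = []
    for ch in panel.with_role("gaussian"):
        lo, hi = _robust_interval(table.data[ch.name].to_numpy(), gaussian_nmads)
        gates.append(Gate(f"gauss_{ch.name}", ch.name, "interval", lo, hi))

    def threshold(x: np.ndarray, kind: str) -> float:
        """Valley threshold; when the channel is unimodal the minority
        population is taken to be absent and the gate stays permissive."""
        v = find_valley(x)
        if v is not None:
            return v
        lo, hi = _robust_interval(x)
        return hi if kind == "below" else lo

    bead = panel.with_role("bead")[0].name
    gates.append(Gate("beads_low", bead, "below",
                      hi=threshold(table.data[bead].to_numpy(), "below")))

    dna = panel.with_role("dna")[0].name
    gates.append(Gate("intact_dna", dna, "above",
                      lo=threshold(table.data[dna].to_numpy(), "above")))

    cis = panel.with_role("viability")[0].name
    gates.append(Gate("live_cisplatin", cis, "below",
                      hi=threshold(table.data[cis].to_numpy(), "below")))

    ccas3 = panel.by_marker("c-Cas3").name
    gates.append(Gate("nonapoptotic_ccas3", ccas3, "below",
                      hi=threshold(table.data[ccas3].to_numpy(), "below")))

    cd45 = panel.by_marker("CD45").name
    gates.append(Gate("cd45_pos", cd45, "above",
                      lo=threshold(table.data[cd45].to_numpy(), "above")))
    return GateSpec(gates)


def apply_gates(table: EventTable, spec: GateSpec) -> GatingResult:
    """Sequentially apply gates; stage masks are nested by construction."""
    spec.validate(table.panel)
    current = np.ones(table.n_events, dtype=bool)
    stages: dict[str, np.ndarray] = {}
    for g in spec.gates:
        current = current & g.mask(table.data[g.channel].to_numpy())
        stages[g.name] = current.copy()
    return GatingResult(stages, current)


def filter_samples(
    counts: dict[str, int] | pd.Series, min_cells: int = 5000
) -> tuple[dict[str, int], dict[str, int]]:
    """Split samples into kept (>= ``min_cells`` live CD45+ events) and
    excluded; 'fewer than min_cells' excludes only strictly smaller
    counts, so the boundary is kept."""
    counts = dict(counts)
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    kept = {s: c for s, c in counts.items() if c >= min_cells}
    excluded = {s: c for s, c in counts.items() if c < min_cells}
    if excluded:
        warnings.warn(
            "excluded samples below {} live CD45+ events: {}".format(
                min_cells, {s: c for s, c in sorted(excluded.items())}
            ),
            UserWarning, stacklevel=2,
        )
    return kept, excluded
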