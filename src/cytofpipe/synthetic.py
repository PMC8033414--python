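"""Ground-truth-annotated synthetic CyTOF cohorts.

The generator emulates the data structure the downstream pipeline assumes:
several acquisition batches of barcode-multiplexed events; a minority
(~1-12%) live CD45+ immune target fraction among tumor cells, dead and
apoptotic events, normalization beads and debris; 21 immune populations
with distinct marker archetypes; per-batch per-marker scale/shift batch
effects applied on the raw ion-count scale; and a planted two-group
("chow" vs "HFD") abundance effect.

Populations are specified as Gaussians on the transformed (arcsinh) scale
— the space in which the pipeline operates — and pushed through the
inverse transform to ion counts. Vendor-style uniform-negative-distribution
(UND) randomization is emulated by adding uniform(-1, 0) noise to the
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cytofpipe.core import EventTable
from cytofpipe.panel import PanelSpec, default_panel
from cytofpipe.preprocess import BarcodeKey, default_barcode_key

EVENT_RATE_HZ = 500.0  # typical acquisition rate used for the time channel

# ---------------------------------------------------------------------------
# population atlas
# ---------------------------------------------------------------------------

BACKGROUND_LOC = 0.4
BACKGROUND_SCALE = 0.35

# 21 immune populations: hot/graded marker levels on the arcsinh scale.
# Markers not listed sit at the background level. The myeloid compartment
# spans six macrophage subsets, four DC subsets, two MDSC subsets and
# eosinophils; the lymphoid compartment spans six T-cell subsets, B cells
# and NK cells.
_ATLAS: dict[str, tuple[str, dict[str, float]]] = {
    "CD4_T_GITRhi": ("lymphoid", {"CD3": 5.0, "CD4": 5.0, "TCRb": 4.5, "GITR": 5.0,
                                  "Sca-1": 3.5, "IL-7Ra": 2.5, "CD5": 4.5, "CD44": 3.0}),
    "Mac_M1": ("myeloid", {"CD11b": 5.0, "F4/80": 4.5, "CD11c": 4.5, "MHC-II": 5.5,
                           "CD64": 4.0, "CD86": 3.5}),
    "Mac_F480hi": ("myeloid", {"CD11b": 5.0, "F4/80": 6.0, "MHC-II": 4.0, "CD64": 4.5,
                               "CD14": 3.0}),
    "B_cell": ("lymphoid", {"CD19": 5.0, "B220": 5.5, "MHC-II": 4.5}),
    "DN_T_Ly6C": ("lymphoid", {"CD3": 5.0, "TCRb": 4.5, "Ly6-C": 4.5, "CD5": 4.5}),
    "CD8_T_Ly6C": ("lymphoid", {"CD3": 5.0, "CD8": 5.0, "TCRb": 4.5, "Ly6-C": 4.0,
                                "Sca-1": 4.0, "CD5": 4.5, "PD-1": 2.5}),
    "CD8_T": ("lymphoid", {"CD3": 5.0, "CD8": 5.0, "TCRb": 4.5, "CD5": 4.5, "PD-1": 2.5}),
    "Mac_M2": ("myeloid", {"CD11b": 5.0, "F4/80": 4.5, "CD206": 5.0, "CD14": 4.0,
                           "CD169": 4.0, "MHC-II": 2.0}),
    "Mac_Sca1": ("myeloid", {"CD11b": 5.0, "F4/80": 4.5, "Sca-1": 5.0, "ICAM-1": 4.0,
                             "PD-L1": 3.5, "MHC-II": 3.5}),
    "pDC": ("myeloid", {"CD11c": 3.5, "B220": 4.0, "MHC-II": 3.5, "Ly6-C": 3.5}),
    "DC_ICAM1": ("myeloid", {"CD11c": 5.0, "MHC-II": 5.0, "ICAM-1": 5.0, "CD86": 3.5}),
    "NK": ("lymphoid", {"NK1.1": 5.0, "Sca-1": 3.0}),
    "Mac_plain": ("myeloid", {"CD11b": 4.5, "F4/80": 3.5, "CD64": 3.5, "MHC-II": 3.0}),
    "Mac_Ly6C": ("myeloid", {"CD11b": 5.0, "F4/80": 4.0, "Ly6-C": 5.0, "MHC-II": 3.5,
                             "CD64": 3.5}),
    "CD4_T_eff": ("lymphoid", {"CD3": 5.0, "CD4": 5.0, "TCRb": 4.5, "CD5": 4.5}),
    "DC_CD11b": ("myeloid", {"CD11c": 5.0, "CD11b": 4.5, "MHC-II": 5.0, "CD24": 3.5}),
    "Eosinophil": ("myeloid", {"CD11b": 4.5, "Siglec-F": 5.0, "F4/80": 3.5}),
    "M-MDSC": ("myeloid", {"CD11b": 5.0, "Ly6-C": 5.5, "F4/80": 1.2}),
    "G-MDSC": ("myeloid", {"CD11b": 5.0, "Ly6-G": 5.5, "Ly6-C": 1.2, "CD24": 3.0}),
    "DN_T_IL7Ra": ("lymphoid", {"CD3": 5.0, "TCRb": 4.5, "IL-7Ra": 5.0, "CD5": 4.5}),
    "DC_PDL1": ("myeloid", {"CD11c": 5.0, "PD-L1": 5.0, "MHC-II": 5.5, "CD86": 4.0,
                            "ICAM-1": 3.5, "IL-7Ra": 2.5, "GITR": 2.5}),
}

# qualitative baseline abundance weights (normalized at design build time);
# a generic mixed infiltrate in which every population is >= 1%
_BASELINE_WEIGHTS: dict[str, float] = {
    "CD4_T_GITRhi": 5.0, "Mac_M1": 6.0, "Mac_F480hi": 9.0, "B_cell": 5.0,
    "DN_T_Ly6C": 3.0, "CD8_T_Ly6C": 6.0, "CD8_T": 6.0, "Mac_M2": 8.0,
    "Mac_Sca1": 5.0, "pDC": 1.5, "DC_ICAM1": 6.0, "NK": 4.0, "Mac_plain": 5.0,
    "Mac_Ly6C": 3.0, "CD4_T_eff": 5.0, "DC_CD11b": 5.0, "Eosinophil": 3.0,
    "M-MDSC": 5.0, "G-MDSC": 8.0, "DN_T_IL7Ra": 2.5, "DC_PDL1": 1.5,
}

# planted HFD effect: G-MDSC and PD-L1+ DC up, both CD8 T subsets down
PLANTED_LOGFOLD: dict[str, float] = {
    "G-MDSC": 0.7,
    "DC_PDL1": 0.7,
    "CD8_T": -0.5,
    "CD8_T_Ly6C": -0.5,
}


@dataclass
class PopulationTemplate:
    """Gaussian archetype of one immune population on the arcsinh scale."""

    name: str
    marker_loc: dict[str, float]
    marker_scale: dict[str, float]
    lineage: str = "other"

    def __post_init__(self) -> None:
        if set(self.marker_loc) != set(self.marker_scale):
            raise ValueError(f"{self.name}: loc/scale marker sets differ")
        for m, s in self.marker_scale.items():
            if s <= 0:
                raise ValueError(f"{self.name}: scale for {m} must be > 0")
        for m, mu in self.marker_loc.items():
            if mu < 0:
                raise ValueError(f"{self.name}: loc for {m} must be >= 0")
        if self.lineage not in {"myeloid", "lymphoid", "other"}:
            raise ValueError(f"{self.name}: unknown lineage {self.lineage!r}")


def make_default_atlas(panel: PanelSpec | None = None) -> list[PopulationTemplate]:
    """Build the 21 default population templates for ``panel``.

    Every phenotyping-role marker in the panel receives a loc/scale; a
    panel lacking a marker required (hot) by a template raises a
    ``ValueError`` naming the marker.
    """
    panel = panel or default_panel()
    markers = panel.phenotyping_markers()
    out = []
    for name, (lineage, hot) in _ATLAS.items():
        missing = [m for m in hot if m not in markers]
        if missing:
            raise ValueError(
                f"panel lacks marker {missing[0]!r} required by template {name!r}"
            )
        loc = {m: BACKGROUND_LOC for m in markers}
        scale = {m: BACKGROUND_SCALE for m in markers}
        if "IRF4" in loc:
            loc["IRF4"] = 0.2  # stained but low-to-negative in all cohorts
        loc.update(hot)
        out.append(PopulationTemplate(name, loc, scale, lineage))
    return out


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Multi-batch, two-group cohort layout and generative parameters.

    Defaults describe the study conditions the generator emulates: ~5%
    live CD45+ target fraction, two barcoded batches of eight samples
    (eight chow and eight HFD in total), 20,000 events per sample,
    moderate per-batch per-marker scale/shift effects, and the planted
    HFD abundance effect on G-MDSCs, CD8 T cells and PD-L1+ DCs.
    """

    n_batches: int = 2
    samples_per_batch: int = 8
    group_of_sample: dict[str, str] = field(default_factory=dict)
    baseline_abundance: dict[str, float] = field(default_factory=dict)
    group_logfold: dict[str, float] = field(default_factory=dict)
    batch_scale: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    events_per_sample: int = 20_000
    frac_cd45: float = 0.05
    frac_dead: float = 0.15
    frac_beads: float = 0.03
    frac_debris: float = 0.05
    abundance_sd: float = 0.25
    barcode_key: BarcodeKey | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.barcode_key is None:
            self.barcode_key = default_barcode_key()
        if self.samples_per_batch > len(self.barcode_key.barcodes):
            raise ValueError(
                f"samples_per_batch={self.samples_per_batch} exceeds the "
                f"{len(self.barcode_key.barcodes)} barcodes in the key"
            )
        if self.samples_per_batch > 14:
            raise ValueError("at most 14 samples are barcoded per batch")
        for name, frac in [
            ("frac_cd45", self.frac_cd45), ("frac_dead", self.frac_dead),
            ("frac_beads", self.frac_beads), ("frac_debris", self.frac_debris),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name}={frac} outside [0, 1]")
        if self.baseline_abundance:
            vals = np.array(list(self.baseline_abundance.values()))
            if (vals < 0).any():
                raise ValueError("baseline abundances must be non-negative")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"baseline abundances sum to {vals.sum():.12f}, not 1"
                )
            eff = vals * np.exp([
                self.group_logfold.get(p, 0.0) for p in self.baseline_abundance
            ])
            if (eff < 0).any():
                raise ValueError("abundance negative after group effect")

    @property
    def sample_names(self) -> list[str]:
        return sorted(self.group_of_sample)

    def samples_in_batch(self, batch: str) -> list[str]:
        return [s for s in self.sample_names if s.startswith(batch + "_")]

    def batch_names(self) -> list[str]:
        return [f"B{b + 1}" for b in range(self.n_batches)]


def default_design(
    planted: bool = True,
    seed: int = 0,
    *,
    n_batches: int = 2,
    samples_per_batch: int = 8,
    events_per_sample: int = 20_000,
    batch_effect_sd: float = 0.15,
    batch_shift_sd: float = 1.0,
    **overrides,
) -> CohortDesign:
    """Default two-group cohort design with generated batch effects.

    ``planted=True`` installs the HFD effect (G-MDSC +0.7, PD-L1+ DC +0.7,
    both CD8 T subsets -0.5 on the log scale); ``planted=False`` yields a
    null cohort. Batch scale factors are lognormal around 1 (sd
    ``batch_effect_sd`` on the log scale) and shifts are small positive
    ion-count offsets, both drawn reproducibly from ``seed``.
    """
    weights = np.array(list(_BASELINE_WEIGHTS.values()), dtype=float)
    baseline = dict(zip(_BASELINE_WEIGHTS, weights / weights.sum()))
    # exact unit sum despite float division
    first = next(iter(baseline))
    baseline[first] += 1.0 - sum(baseline.values())

    groups: dict[str, str] = {}
    for b in range(n_batches):
        for i in range(samples_per_batch):
            name = f"B{b + 1}_S{i + 1}"
            groups[name] = "chow" if i < samples_per_batch / 2 else "HFD"

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7C]))
    markers = default_panel().phenotyping_markers()
    batch_scale: dict[str, dict[str, float]] = {}
    batch_shift: dict[str, dict[str, float]] = {}
    for b in range(n_batches):
        batch = f"B{b + 1}"
        batch_scale[batch] = {
            m: float(np.exp(rng.normal(0.0, batch_effect_sd))) for m in markers
        }
        batch_shift[batch] = {
            m: float(abs(rng.normal(0.0, batch_shift_sd))) for m in markers
        }

    return CohortDesign(
        n_batches=n_batches,
        samples_per_batch=samples_per_batch,
        group_of_sample=groups,
        baseline_abundance=baseline,
        group_logfold=dict(PLANTED_LOGFOLD) if planted else {},
        batch_scale=batch_scale,
        batch_shift=batch_shift,
        events_per_sample=events_per_sample,
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Per-event ground truth and per-sample realized abundances.

    ``events`` has one row per generated event, aligned with the emitted
    tables (columns: event_id, sample, batch, population, barcode,
    viability, class). ``abundance`` is samples x populations, rows summing
    to 1 over the atlas populations among live CD45+ cells.
    """

    events: pd.DataFrame
    abundance: pd.DataFrame

    def live_cd45_mask(self, batch: str | None = None) -> np.ndarray:
        df = self.events if batch is None else self.events[self.events["batch"] == batch]
        return (
            (df["class"] == "cell")
            & (df["viability"] == "live")
            & (df["population"].notna())
            & (df["population"] != "tumor")
        ).to_numpy()


# ---------------------------------------------------------------------------
# abundance model (shared by event-level and abundance-level simulation)
# ---------------------------------------------------------------------------


def sample_probability_vector(
    design: CohortDesign, sample: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample population probabilities: baseline x group effect x
    per-sample lognormal biological variation, renormalized."""
    pops = list(design.baseline_abundance)
    p = np.array([design.baseline_abundance[k] for k in pops], dtype=float)
    if design.group_of_sample.get(sample) == "HFD":
        p = p * np.exp([design.group_logfold.get(k, 0.0) for k in pops])
    if design.abundance_sd > 0:
        p = p * np.exp(rng.normal(0.0, design.abundance_sd, size=len(p)))
    if (p < 0).any():
        raise ValueError("abundance vector has negative entries after group effect")
    return p / p.sum()


def simulate_abundances(design: CohortDesign, seed: int | None = None) -> pd.DataFrame:
    """Samples x populations realized abundance fractions (multinomial at
    the expected live CD45+ count), without generating events.

    A fast surrogate with the same abundance model as
    :func:`simulate_cohort`, for power and calibration studies.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n_target = max(1, int(round(design.events_per_sample * design.frac_cd45)))
    pops = list(design.baseline_abundance)
    rows = {}
    for sample in design.sample_names:
        p = sample_probability_vector(design, sample, rng)
        counts = rng.multinomial(n_target, p)
        rows[sample] = counts / counts.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=pops)


# ---------------------------------------------------------------------------
# event-level simulation
# ---------------------------------------------------------------------------


def _event_composition(design: CohortDesign) -> dict[str, float]:
    cellular = 1.0 - design.frac_beads - design.frac_debris
    if cellular <= 0:
        raise ValueError("bead + debris fractions leave no cellular events")
    live = cellular * (1.0 - design.frac_dead)
    if design.frac_cd45 > live:
        raise ValueError(
            f"frac_cd45={design.frac_cd45} exceeds the live cellular "
            f"fraction {live:.3f}"
        )
    q_cd45 = design.frac_cd45 / live  # CD45+ share among live cellular events
    return {"cellular": cellular, "q_cd45": q_cd45}


def simulate_cohort(
    design: CohortDesign,
    atlas: list[PopulationTemplate] | None = None,
    panel: PanelSpec | None = None,
) -> tuple[list[EventTable], SyntheticTruth]:
    """Generate one raw-scale :class:`EventTable` per batch plus truth.

    Deterministic given ``design.seed`` (hierarchical RNG streams per
    batch and sample, so any sub-cohort reproduces independently).
    """
    panel = panel or default_panel()
    atlas = atlas if atlas is not None else make_default_atlas(panel)
    by_name = {t.name: t for t in atlas}
    missing = [p for p in design.baseline_abundance if p not in by_name]
    if missing:
        raise ValueError(f"design populations not in atlas: {missing}")

    comp = _event_composition(design)
    markers = panel.phenotyping_markers()
    names = panel.names
    col = {n: i for i, n in enumerate(names)}
    bc_channels = panel.barcode_channels
    key = design.barcode_key
    dna_cols = [c.name for c in panel.with_role("dna")]
    gauss_cols = [c.name for c in panel.with_role("gaussian")]
    cis_col = panel.with_role("viability")[0].name
    bead_col = panel.with_role("bead")[0].name
    cd45_col = panel.by_marker("CD45").name
    ccas3_col = panel.by_marker("c-Cas3").name
    time_col = panel.time_channel.name
    # channels carrying ion counts (UND randomization applies)
    mass_cols = [
        c.name for c in panel.channels if c.role not in {"time", "gaussian"}
    ]

    root = np.random.SeedSequence([design.seed, 0x5EED])
    batch_seeds = root.spawn(design.n_batches)

    tables: list[EventTable] = []
    truth_frames: list[pd.DataFrame] = []
    abundance_rows: dict[str, np.ndarray] = {}
    pops = list(design.baseline_abundance)

    for b, batch in enumerate(design.batch_names()):
        samples = design.samples_in_batch(batch)
        if len(samples) != design.samples_per_batch:
            raise ValueError(
                f"group_of_sample defines {len(samples)} samples for {batch}, "
                f"expected {design.samples_per_batch}"
            )
        sample_seeds = batch_seeds[b].spawn(len(samples) + 1)
        batch_rng = np.random.default_rng(sample_seeds[-1])

        mats, truths, sids = [], [], []
        for s_i, sample in enumerate(samples):
            rng = np.random.default_rng(sample_seeds[s_i])
            n = design.events_per_sample
            T = np.empty((n, len(names)), dtype=np.float64)

            # event classes ------------------------------------------------
            u = rng.random(n)
            is_bead = u < design.frac_beads
            is_debris = (~is_bead) & (u < design.frac_beads + design.frac_debris)
            cellular = ~(is_bead | is_debris)
            viability = np.full(n, "live", dtype=object)
            viability[is_bead | is_debris] = "none"
            v = rng.random(n)
            dead = cellular & (v < design.frac_dead * 0.6)
            apop = cellular & ~dead & (v < design.frac_dead)
            viability[dead] = "dead"
            viability[apop] = "apoptotic"
            cd45pos = cellular & (rng.random(n) < comp["q_cd45"])

            # population labels ---------------------------------------------
            p_vec = sample_probability_vector(design, sample, rng)
            population = np.full(n, None, dtype=object)
            idx_cd45 = np.flatnonzero(cd45pos)
            draws = rng.choice(len(pops), size=idx_cd45.size, p=p_vec)
            population[idx_cd45] = np.array(pops, dtype=object)[draws]
            population[cellular & ~cd45pos] = "tumor"

            # transformed-scale signals --------------------------------------
            T[:] = np.clip(rng.normal(BACKGROUND_LOC, 0.3, size=T.shape), 0, None)
            for m in markers:  # antibody background
                T[:, col[panel.by_marker(m).name]] = np.clip(
                    rng.normal(BACKGROUND_LOC, BACKGROUND_SCALE, n), 0, None
                )
            for j, pop in enumerate(pops):
                rows = idx_cd45[draws == j]
                if rows.size == 0:
                    continue
                tpl = by_name[pop]
                for m in markers:
                    T[rows, col[panel.by_marker(m).name]] = np.clip(
                        rng.normal(tpl.marker_loc[m], tpl.marker_scale[m], rows.size),
                        0, None,
                    )
            # structural channels
            T[:, col[cd45_col]] = np.clip(rng.normal(0.3, 0.2, n), 0, None)
            T[cd45pos, col[cd45_col]] = np.clip(
                rng.normal(5.0, 0.4, int(cd45pos.sum())), 0, None
            )
            for dc in dna_cols:
                T[:, col[dc]] = np.clip(rng.normal(0.6, 0.4, n), 0, None)
                T[cellular, col[dc]] = np.clip(
                    rng.normal(6.0, 0.3, int(cellular.sum())), 0, None
                )
                T[is_bead, col[dc]] = np.clip(
                    rng.normal(0.2, 0.15, int(is_bead.sum())), 0, None
                )
            T[:, col[cis_col]] = np.clip(rng.normal(0.5, 0.3, n), 0, None)
            T[dead, col[cis_col]] = np.clip(rng.normal(4.0, 0.4, int(dead.sum())), 0, None)
            T[:, col[ccas3_col]] = np.clip(rng.normal(0.4, 0.3, n), 0, None)
            T[apop, col[ccas3_col]] = np.clip(rng.normal(4.0, 0.4, int(apop.sum())), 0, None)
            T[:, col[bead_col]] = np.clip(rng.normal(0.1, 0.1, n), 0, None)
            T[is_bead, col[bead_col]] = np.clip(
                rng.normal(5.5, 0.3, int(is_bead.sum())), 0, None
            )
            for gc in gauss_cols:
                T[:, col[gc]] = np.clip(rng.normal(3.0, 0.25, n), 0, None)

            # barcode channels: cellular events carry the sample's barcode
            barcode_id = key.barcode_for_index(s_i)
            hot = key.barcodes[barcode_id]
            for ch in bc_channels:
                loc, sd = (4.5, 0.35) if ch in hot else (0.15, 0.1)
                T[:, col[ch]] = np.clip(rng.normal(0.15, 0.1, n), 0, None)
                T[cellular, col[ch]] = np.clip(
                    rng.normal(loc, sd, int(cellular.sum())), 0, None
                )
            barcode = np.full(n, None, dtype=object)
            barcode[cellular] = barcode_id

            mats.append(T)
            sids.append(np.full(n, sample, dtype=object))
            truths.append(pd.DataFrame({
                "sample": sample,
                "batch": batch,
                "population": population,
                "barcode": barcode,
                "viability": viability,
                "class": np.where(is_bead, "bead", np.where(is_debris, "debris", "cell")),
            }))

            # realized live CD45+ abundance
            live_cd45 = cd45pos & (viability == "live")
            counts = np.array([
                int(((population == p) & live_cd45).sum()) for p in pops
            ], dtype=float)
            abundance_rows[sample] = counts / counts.sum() if counts.sum() else counts

        T = np.vstack(mats)
        truth = pd.concat(truths, ignore_index=True)
        sid = np.concatenate(sids)

        # inverse transform to ion counts, batch effects, UND randomization
        raw = T.copy()
        mass_idx = [col[c] for c in mass_cols]
        raw[:, mass_idx] = panel.cofactor * np.sinh(T[:, mass_idx])
        for m in markers:
            j = col[panel.by_marker(m).name]
            scale = design.batch_scale.get(batch, {}).get(m, 1.0)
            shift = design.batch_shift.get(batch, {}).get(m, 0.0)
            raw[:, j] = np.clip(raw[:, j] * scale + shift, 0, None)
        counts_int = np.round(raw[:, mass_idx])
        raw[:, mass_idx] = counts_int + batch_rng.uniform(-1, 0, counts_int.shape)

        # acquisition order: samples interleave; time at ~500 events/s
        order = batch_rng.permutation(len(raw))
        raw = raw[order]
        truth = truth.iloc[order].reset_index(drop=True)
        sid = sid[order]
        raw[:, col[time_col]] = np.arange(len(raw)) / EVENT_RATE_HZ

        truth.insert(0, "event_id", [f"{batch}:{i}" for i in range(len(truth))])
        truth_frames.append(truth)
        tables.append(EventTable(
            pd.DataFrame(raw, columns=names), panel, batch_id=batch, sample_ids=sid,
        ))

    truth = SyntheticTruth(
        events=pd.concat(truth_frames, ignore_index=True),
        abundance=pd.DataFrame.from_dict(abundance_rows, orient="index", columns=pops),
    )
    return tables, truth


def write_cohort_fcs(tables: list[EventTable], directory) -> list:
    """Write one FCS 3.1 file per batch table; returns the file paths."""
    from pathlib import Path

    from cytofpipe.io_fcs import write_fcs

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(tables):
        name = f"{t.batch_id or f'batch{i + 1}'}.fcs"
        paths.append(write_fcs(t, directory / name))
    return paths


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    """Truth table as CSV (event_id, sample, batch, population, barcode,
    viability, class)."""
    truth.events.to_csv(path, index=False)
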