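"""End-to-end orchestration with per-stage artifacts and a run manifest.

Stage order: (optional) simulate -> read/harmonize -> debarcode -> gate ->
filter -> transform -> correct -> subsample -> embed -> cluster -> curate
-> MEM -> metacluster -> abundance -> t-tests -> T-cell gates -> CITRUS.
Every numeric output is written as CSV (plus corrected FCS with ``c_``
channels and a Newick rendering of the MEM dendrogram); the JSON manifest
records parameters, seeds and package versions, sufficient to regenerate
every output. Re-running with the same config and seed reproduces all CSV
outputs bit-identically apart from embedding coordinates, which reproduce
on the same platform.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cytofpipe import __version__
from cytofpipe.clustering import (
    curate_clusters,
    embed,
    kmeans_clusters,
    map_gate,
    mem_scores,
    metacluster,
    metacluster_events,
    subsample_equal,
    suggest_merges,
)
from cytofpipe.config import RunConfig
from cytofpipe.core import EventTable, concat_tables
from cytofpipe.correction import apply_correction, arcsinh_transform, fit_correction
from cytofpipe.gating import apply_gates, auto_gate_spec, filter_samples
from cytofpipe.io_fcs import read_fcs, write_fcs
from cytofpipe.panel import Channel, PanelSpec
from cytofpipe.preprocess import debarcode, default_barcode_key, harmonize_panels, split_by_barcode
from cytofpipe.stats import abundance_table, cd4_cd8_stats, citrus_sam, group_ttest
from cytofpipe.synthetic import default_design, simulate_cohort, write_cohort_fcs, write_truth_csv

log = logging.getLogger("cytofpipe")


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage and sample context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage
        self.cause = cause


def _tree_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import to_tree

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        return f"({rec(node.left)}:{node.dist / 2:.6g},{rec(node.right)}:{node.dist / 2:.6g})"

    return rec(to_tree(Z)) + ";"


def _corrected_fcs(table: EventTable, corrected: EventTable, markers: list[str]) -> EventTable:
    """Bind corrected marker channels (``c_`` prefix) next to the originals."""
    chans = list(table.panel.channels)
    df = table.data.copy()
    for m in markers:
        ch = table.panel.by_marker(m)
        chans.append(Channel("c_" + ch.metal, ch.marker, ch.role, ch.embed))
        df["c_" + ch.name] = corrected.data[ch.name].to_numpy()
    panel = PanelSpec(chans, table.panel.cofactor)
    return EventTable(df[panel.names], panel, batch_id=table.batch_id,
                      sample_ids=table.sample_ids)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage described by ``config``; returns the artifact
    directory."""
    config.validate()
    p = config.params
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "params": asdict(p),
        "stages": [],
        "outputs": [],
    }

    def done(stage: str, **info) -> None:
        log.info("stage %s done %s", stage, info or "")
        manifest["stages"].append({"stage": stage, **info})

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, index=index)
        manifest["outputs"].append(name)

    key = default_barcode_key()
    truth = None
    groups = dict(config.group_of_sample)

    # -- simulate ----------------------------------------------------------
    if config.simulate:
        try:
            design = default_design(seed=config.seed, **config.design)
            tables, truth = simulate_cohort(design)
            fcs_dir = out / "fcs"
            write_cohort_fcs(tables, fcs_dir)
            write_truth_csv(truth, out / "truth.csv")
            manifest["outputs"] += ["truth.csv"]
            key = design.barcode_key
            if not groups:
                groups = dict(design.group_of_sample)
            barcode_of_sample = {
                b: {key.barcode_for_index(i): s
                    for i, s in enumerate(design.samples_in_batch(b))}
                for b in design.batch_names()
            }
            done("simulate", batches=len(tables),
                 events=sum(t.n_events for t in tables))
        except Exception as exc:
            raise StageError("simulate", "cohort generation", exc) from exc
    else:
        try:
            paths = sorted(Path(config.input_dir).glob("*.fcs"))
            if not paths:
                raise ValueError(f"no FCS files in {config.input_dir}")
            tables = []
            for fp in paths:
                t = read_fcs(fp)
                t.batch_id = fp.stem
                tables.append(t)
            barcode_of_sample = config.barcode_of_sample
            done("read", files=len(tables))
        except Exception as exc:
            raise StageError("read", str(config.input_dir), exc) from exc

    # -- harmonize ---------------------------------------------------------
    try:
        tables = harmonize_panels(tables, config.rename_map or None, strict=False)
        done("harmonize", channels=len(tables[0].panel.channels))
    except Exception as exc:
        raise StageError("harmonize", "channel alignment", exc) from exc

    # -- debarcode & split -------------------------------------------------
    per_sample: dict[str, EventTable] = {}
    debarcode_rows = []
    for t in tables:
        try:
            res = debarcode(t, key, p.min_separation, p.max_distance,
                            cofactor=p.cofactor)
            mapping = barcode_of_sample.get(t.batch_id, {})
            split = split_by_barcode(t, res, mapping or None)
            for s, sub in split.items():
                if sub.n_events and (not mapping or s in mapping.values()):
                    per_sample[s] = sub
            debarcode_rows.append(res.counts.rename(t.batch_id))
        except Exception as exc:
            raise StageError("debarcode", f"batch {t.batch_id}", exc) from exc
    emit("debarcode_counts.csv", pd.DataFrame(debarcode_rows))
    done("debarcode", samples=len(per_sample))

    # -- transform + gate + filter ----------------------------------------
    gated: dict[str, EventTable] = {}
    counts: dict[str, int] = {}
    for s, t in per_sample.items():
        try:
            tt = arcsinh_transform(t, p.cofactor)
            spec = auto_gate_spec(tt)
            res = apply_gates(tt, spec)
            gated[s] = tt.take(res.final_mask)
            counts[s] = int(res.final_mask.sum())
        except Exception as exc:
            raise StageError("gate", f"sample {s}", exc) from exc
    emit("gating_counts.csv", pd.Series(counts, name="live_cd45").to_frame())
    kept, excluded = filter_samples(counts, p.min_cells)
    done("gate", kept=len(kept), excluded=len(excluded))
    if not kept:
        raise StageError("filter", "all samples", ValueError(
            f"no sample reached {p.min_cells} live CD45+ events"))
    gated = {s: gated[s] for s in kept}
    groups = {s: g for s, g in groups.items() if s in kept}

    # -- batch correction --------------------------------------------------
    try:
        panel = next(iter(gated.values())).panel
        markers = panel.correction_markers()
        by_batch: dict[str, list[EventTable]] = {}
        for s, t in gated.items():
            by_batch.setdefault(t.batch_id, []).append(t)
        batch_pools = {b: concat_tables(ts) for b, ts in by_batch.items()}
        if len(batch_pools) >= 2 and p.correction_method != "none":
            model = fit_correction(batch_pools, markers, p.correction_method,
                                   quantile_pair=p.quantile_pair,
                                   landmark_prominence=p.landmark_prominence,
                                   seed=config.seed)
        else:
            model = fit_correction(batch_pools, markers, "none")
        corrected = {
            s: apply_correction(model, {t.batch_id: t})[t.batch_id]
            for s, t in gated.items()
        }
        fcs_out = out / "corrected_fcs"
        fcs_out.mkdir(exist_ok=True)
        for s, t in gated.items():
            write_fcs(_corrected_fcs(t, corrected[s], markers),
                      fcs_out / f"{s}.fcs")
        done("correct", method=model.method, markers=len(markers))
    except Exception as exc:
        raise StageError("correct", p.correction_method, exc) from exc

    # -- subsample / embed / cluster / MEM / metacluster -------------------
    try:
        n_per = min(p.n_per_file, min(t.n_events for t in corrected.values()))
        if n_per < p.n_per_file:
            log.warning("n_per_file reduced to %d (smallest kept sample)", n_per)
        pooled = subsample_equal(corrected, n_per_file=n_per, seed=config.seed)
        done("subsample", pooled=pooled.n_events, n_per_file=n_per)
    except Exception as exc:
        raise StageError("subsample", "pooling", exc) from exc

    try:
        ts1, ts2, kl = embed(pooled, perplexity=p.perplexity, theta=p.theta,
                             iterations=p.iterations, seed=config.seed)
        done("embed", kl_divergence=kl)
    except Exception as exc:
        raise StageError("embed", "t-SNE", exc) from exc

    try:
        cids = kmeans_clusters(ts1, ts2, k=p.k, seed=config.seed)
        if p.merge_map is not None:
            merge_map = p.merge_map
        elif p.auto_curate:
            merge_map = suggest_merges(ts1, ts2, cids)
        else:
            merge_map = {int(c): int(c) for c in np.unique(cids)}
        cur = curate_clusters(cids, merge_map)
        done("cluster", k=p.k, curated=int(len(np.unique(cur))))
    except Exception as exc:
        raise StageError("cluster", "k-means/curation", exc) from exc

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            mem = mem_scores(pooled, cur, min_cluster_size=p.mem_min_cluster_size)
        meta_map, row_link, col_link = metacluster(mem, n_meta=min(p.n_meta, len(mem.clusters)))
        ev_meta = metacluster_events(cur, meta_map)
        emit("mem_scores.csv", mem.score)
        (out / "mem_dendrogram.nwk").write_text(
            _tree_to_newick(row_link, [str(c) for c in mem.clusters]))
        manifest["outputs"].append("mem_dendrogram.nwk")
        events = pd.DataFrame({
            "sample": pooled.sample_ids, "tsne1": ts1, "tsne2": ts2,
            "cluster": cids, "curated": cur, "metacluster": ev_meta,
        })
        emit("events.csv", events, index=False)
        done("mem_metacluster", n_meta=int(len(set(meta_map.values()))))
    except Exception as exc:
        raise StageError("mem", "scoring/metaclustering", exc) from exc

    # -- abundance & statistics -------------------------------------------
    try:
        tab = abundance_table(ev_meta, pooled.sample_ids, groups)
        emit("abundance.csv", tab.percent)
        tests = group_ttest(tab, adjust=p.adjust_pvalues)
        emit("ttests.csv", tests)
        done("diffab", metaclusters=tab.percent.shape[1])
    except Exception as exc:
        raise StageError("diffab", "abundance/t-tests", exc) from exc

    try:
        masks = map_gate(ts1, ts2, pooled)
        t_counts = pd.DataFrame({
            k: pd.Series(pooled.sample_ids[masks[k]]).value_counts()
            for k in ("CD4_T", "CD8_T", "DN_T", "DP_T")
        }).fillna(0).astype(int)
        t_counts = t_counts.reindex(tab.percent.index, fill_value=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            tstats = cd4_cd8_stats(t_counts, groups, n_cd45=tab.n_events)
        emit("t_subsets.csv", tstats)
        done("t_gates", cd3=int(masks["CD3"].sum()))
    except Exception as exc:
        raise StageError("t_gates", "CD3/CD4/CD8 gating", exc) from exc

    try:
        cit = citrus_sam(
            pooled, pooled.sample_ids, groups,
            min_cluster_frac=p.citrus_min_cluster_frac,
            n_perm=p.citrus_n_perm, seed=config.seed,
            events_per_sample=p.citrus_events_per_sample,
            fdr_threshold=p.citrus_fdr,
        )
        emit("citrus_nodes.csv", cit.nodes)
        done("citrus", nodes=len(cit.nodes), significant=len(cit.significant))
    except Exception as exc:
        raise StageError("citrus", "SAM permutation analysis", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
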