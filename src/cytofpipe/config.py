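"""Run configuration: one YAML document drives the whole pipeline.

Every stage parameter has a default, so a minimal configuration (an
output directory plus either an input FCS directory with a sample sheet,
or ``simulate: true``) runs end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class StageParams:
    """All tunable stage parameters with their pipeline defaults."""

    cofactor: float = 5.0
    # debarcoding
    min_separation: float = 0.12
    max_distance: float = 30.0
    # gating / exclusion
    min_cells: int = 5000
    # batch correction
    correction_method: str = "range"
    quantile_pair: tuple[float, float] = (0.001, 0.999)
    landmark_prominence: float = 0.05
    # embedding / clustering
    n_per_file: int = 5206
    perplexity: float = 30.0
    theta: float = 0.5
    iterations: int = 4000
    k: int = 40
    n_meta: int = 21
    auto_curate: bool = False
    merge_map: dict[int, int] | None = None
    mem_min_cluster_size: int = 20
    # differential abundance
    adjust_pvalues: bool = False
    citrus_min_cluster_frac: float = 0.01
    citrus_n_perm: int = 1000
    citrus_events_per_sample: int = 500
    citrus_fdr: float = 0.05


@dataclass
class RunConfig:
    """Paths, sample sheet, stage parameters and the global seed."""

    output_dir: str
    input_dir: str | None = None
    simulate: bool = False
    design: dict = field(default_factory=dict)  # overrides for default_design
    # sample sheet: file/batch -> {barcode_id -> sample}, sample -> group
    barcode_of_sample: dict[str, dict[str, str]] = field(default_factory=dict)
    group_of_sample: dict[str, str] = field(default_factory=dict)
    rename_map: dict[str, str] = field(default_factory=dict)
    params: StageParams = field(default_factory=StageParams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            if self.input_dir is None:
                raise ValueError("config needs input_dir or simulate: true")
            p = Path(self.input_dir)
            if not p.is_dir():
                raise ValueError(f"input_dir {p} does not exist")
            if not self.group_of_sample:
                raise ValueError("config needs a sample sheet (group_of_sample)")
        if self.params.correction_method not in {"range", "quantile", "warp", "none"}:
            raise ValueError(
                f"unknown correction_method {self.params.correction_method!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = raw.pop("params", {})
        if "quantile_pair" in params:
            params["quantile_pair"] = tuple(params["quantile_pair"])
        if params.get("merge_map"):
            params["merge_map"] = {int(k): int(v) for k, v in params["merge_map"].items()}
        cfg = cls(**{**raw, "params": StageParams(**params)})
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["params"]["quantile_pair"] = list(self.params.quantile_pair)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
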