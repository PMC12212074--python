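"""Pipeline configuration: every tunable threshold in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    """Defaults for the whole phasing/scaffolding/screening stack.

    Lengths are bp of the input graph's coordinate space; ratios are
    dimensionless.
    """

    # match graph
    min_node_len: int = 200_000          # nodes at or below this are ignored
    min_match_len: int = 200_000         # minimum homology alignment span
    match_majority_ratio: float = 1.5    # clear-majority margin for haplotype edges

    # phasing
    negative_multiplier: float = 10.0    # homolog edge weight = -this * max weight
    kl_restarts: int = 1000
    kl_iters: int = 10_000
    short_node_ratio: float = 2.5        # majority margin for leftover nodes
    coverage_long_node: int = 50_000

    # path extraction
    marker_ratio: float = 5.0
    big_node: int = 500_000
    seed_min_len: int = 500_000
    gap_est_len: int = 50_000

    # scaffolding
    window_cap: int = 5_000_000
    max_equiv: int = 5
    prox_bonus: float = 3.0
    hom_bonus: float = 5.0
    prox_dist: int = 500_000
    homology_gap: int = 1_000_000
    join_ratio: float = 1.5
    rescue_big_path: int = 1_000_000
    join_gap_len: int = 100_000

    # screening
    min_isolated_len: int = 100_000
    screen_min_identity: float = 0.975
    screen_min_hit_fraction: float = 0.10
    screen_min_breadth: float = 0.50
    screen_hops: int = 4
    screen_len_ratio: float = 4.0
    screen_trim_overlap: int = 1_000

    # telomere detection
    telomere_motif: str = "TTAGGG"
    telomere_window: int = 10_000
    telomere_min_density: float = 0.3

    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"config field {f.name} must be non-negative, got {v}")

    def header(self) -> str:
        """One-line JSON serialisation for embedding in output headers."""
        return "# config: " + json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
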