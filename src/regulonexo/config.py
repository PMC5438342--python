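"""Run configuration: one flat, serializable record of every tunable threshold."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults.

    The record is flat on purpose: it serializes to a one-level YAML mapping and
    unknown keys are rejected on load, so a stale or misspelled configuration
    fails loudly instead of silently running with defaults.
    """

    seed: int = 42
    preset: str = "paper_scale"

    # peak calling
    peak_k: float = 3.0                 # border threshold, multiples of local background
    peak_bg_window: int = 2000          # bp, centered window for local background
    peak_max_span: int = 100            # bp, max forward->reverse border pairing span
    peak_sn_min: float = 1.0            # minimum signal-to-noise ratio kept

    # motif discovery
    motif_width: int = 10
    motif_flank: int = 10               # bp added on each side of a peak interval
    motif_restarts: int = 20
    motif_max_iter: int = 200
    motif_prior: float = 0.9            # per-sequence occurrence prior (ZOOPS)
    motif_pseudocount: float = 0.25

    # differential expression
    de_lfc_min: float = 1.0             # |log2 fold change| threshold
    de_fdr_max: float = 0.01            # BH q-value threshold
    de_pseudocount: float = 1.0

    # integration
    tss_window_up: int = 500            # bp upstream of TSS
    tss_window_down: int = 200          # bp downstream of TSS
    promoter_bound: int = 100           # upstream/promoter boundary, bp

    # synthetic data
    sim_depth: int = 10_000_000         # ChIP library depth (both strands)
    sim_target_sn: float = 5.0          # planted-site signal-to-noise ratio
    sim_mock_artifacts: int = 2         # artifact sites shared with the mock track
    sim_dispersion: float = 0.01        # RNA-seq negative-binomial dispersion
    sim_jitter: int = 2                 # bp, border jitter half-width

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.peak_sn_min < 0 or self.peak_k <= 0:
            raise ValueError("peak thresholds must be positive")
        if self.motif_width < 4:
            raise ValueError("motif width must be >= 4")
        if not 0 < self.motif_prior <= 1:
            raise ValueError("motif occurrence prior must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("configuration must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)
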