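"""Pipeline configuration.

Every threshold used by the difference classifier, the read-evidence
features and the validation rules lives here, with the defaults the
method was designed around.  All of them can be overridden from a YAML
file (flat mapping of key -> value) or programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Config:
    # --- alignment chaining / difference classification ---
    max_adjacency: int = 1000      # bp; max overlap/gap between chained segments
    misjoin_distance: int = 10_000  # bp; larger reference jumps are misjoins
    indel_min: int = 5             # bp; smaller gap discrepancies are jitter
    end_min: int = 10              # bp; shorter unaligned ends are ignored
    gap_run_min: int = 10          # consecutive N marking an intra-scaffold gap

    # --- read-evidence features ---
    majority_frac: float = 0.8     # disagreement: majority fraction strictly below
    min_depth: int = 5             # min pileup depth for calling a disagreement
    window_cov: int = 50           # bp; coverage-anomaly window
    window_disc: int = 500         # bp; discordant/multi-align ratio sub-region
    anomaly_windows: int = 2       # windows needed to flag high/low coverage
    cov_high_fold: float = 1.5     # high coverage: > fold * scaffold mean
    cov_low_fold: float = 0.5      # low coverage: < fold * scaffold mean
    sc_sd_mult: float = 1.5        # single-cell mode: mean +/- mult * window sd
    single_cell: bool = False
    sd_mult_discordant: float = 3.0  # pair discordant if |frag - mu| > mult*sigma
    min_lib_pairs: int = 1000      # FR pairs needed to estimate the library

    # --- validation rules ---
    multi_ratio_thresh: float = 0.1
    disc_ratio_thresh: float = 0.1
    sd_mult_indel: float = 2.0     # fragment-size closeness for indel errors
    disag_per_kbp: float = 1.0     # fallback rule for large indels
    trim_cap: int = 200            # bp; max misjoin margin trimming per side
    min_region_reads: int = 5      # below this (and no spanning pairs): low evidence
    min_span_pairs: int = 3        # spanning-fragment mean needs at least this many

    # --- correction / evaluation ---
    min_out_len: int = 200         # bp; shorter corrected fragments are dropped
    match_slop: int = 100          # bp; truth-matching tolerance

    def replace(self, **kw) -> "Config":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT = Config()
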