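"""Run configuration: every stage parameter with its protocol default."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunable pipeline parameters.

    Defaults are the protocol's published thresholds: 800 nt minimum read
    length, >= 150 aligned amino acids at > 50% identity, 300 nt upstream
    windows, 98% de-redundancy, 3-5 nt palindromic words with 0-30 nt
    spacers, 20 nt shuffle windows and top-{1,5,10,20,30,40}% bins.
    """

    min_read_length: int = 800
    min_alignment_aa: int = 150
    min_identity: float = 50.0
    upstream_length: int = 300
    require_noncoding: int = 300
    dedup_identity: float = 0.98
    w_min: int = 3
    w_max: int = 5
    spacer_min: int = 0
    spacer_max: int = 30
    shuffle_window: int = 20
    percent_list: tuple = (1, 5, 10, 20, 30, 40)
    counting_mode: str = "distinct_motifs"
    expected_form: str = "frequency"
    n_motif_rule: str = "observed"
    enrichment_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must be in (0, 1]")
        if not (1 <= self.w_min <= self.w_max):
            raise ValueError("need 1 <= w_min <= w_max")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if self.counting_mode not in ("distinct_motifs", "occurrences"):
            raise ValueError(f"unknown counting_mode {self.counting_mode!r}")
        if self.expected_form not in ("frequency", "simple"):
            raise ValueError(f"unknown expected_form {self.expected_form!r}")
        if self.n_motif_rule not in ("observed", "all"):
            raise ValueError(f"unknown n_motif_rule {self.n_motif_rule!r}")
        self.percent_list = tuple(self.percent_list)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["percent_list"] = list(self.percent_list)
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    Unknown keys in either source are errors; ``None`` overrides are
    ignored so CLI flags can pass through unset options.
    """
    values: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)
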