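"""Run configuration: every printed threshold of the analysis in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Thresholds and knobs for the full pipeline.

    Defaults reproduce the published analysis criteria: raw-count filter
    5 (coding) / 2 (non-coding) with the both-groups-low removal rule,
    |log2FC| > 1, FDR < 0.05 for mRNA/lncRNA and p < 0.05 for
    miRNA/circRNA, cis window < 100 kb, lncRNA-target Pearson gate
    |r| > 0.9 with p < 0.05, miRNA-sponge gate r < -0.9, hypergeometric
    p < 0.05, hub degree >= 5.
    """

    filter_coding: float = 5.0
    filter_noncoding: float = 2.0
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05
    p_cut: float = 0.05
    corr_cut: float = 0.9
    cerna_corr_cut: float = -0.9
    cerna_p_cut: float = 0.05
    cis_window_bp: int = 100_000
    hub_degree: int = 5
    # pseudocount for log2FC, in raw-count units (converted to CPM internally)
    pseudocount: float = 0.5
    # novelty scorers
    fickett_max: float = 0.95
    orf_frac_max: float = 0.30
    # miRNA seed matching: weakest site class that counts as a target
    min_site_class: str = "7mer-m8"
    # antisense duplex score gate; None = annotation only
    duplex_max: float | None = None
    # trans candidates: DEL x DEM only (False) or all expressed genes (True)
    trans_all_genes: bool = False
    # sponge pair types; lncRNA-circRNA pairs excluded by default
    allow_lnc_circ_pairs: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if v != v or v in (float("inf"), float("-inf")):
                    raise ValueError(f"{f.name} must be finite")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        return cls.from_dict(d or {})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
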