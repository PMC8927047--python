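"""Core domain types shared across the pipeline.

The pipeline operates on four expression layers (mRNA, miRNA, lncRNA,
circRNA) measured over a two-group design (mechanical stress vs control,
three biological replicates each by default). Counts are raw gene-level
read counts; genomic coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "miRNA", "lncRNA", "circRNA")
GROUPS = ("stress", "control")

#: biotype implied by each expression layer
LAYER_BIOTYPE = {
    "mRNA": "coding",
    "miRNA": "miRNA",
    "lncRNA": "lncRNA",
    "circRNA": "circRNA",
}
BIOTYPES = ("coding", "lncRNA", "miRNA", "circRNA")


@dataclass
class CountMatrix:
    """One expression layer: integer counts (transcripts x samples).

    Parameters
    ----------
    layer
        One of ``mRNA``, ``miRNA``, ``lncRNA``, ``circRNA``.
    counts
        DataFrame indexed by transcript id, columns = sample ids,
        non-negative integer raw read counts.
    group_of
        Mapping sample id -> ``stress`` | ``control``. Every column of
        ``counts`` must appear; each group needs at least two samples.
    """

    layer: str
    counts: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.counts.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate transcript id {dup!r}")
        cols = self.counts.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = [s for s in cols if s not in self.group_of]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(arr < 0):
                raise ValueError("negative counts are not allowed")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        for g in GROUPS:
            if len(self.samples_in(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    # -- convenience accessors -------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]

    def subset(self, transcript_ids) -> "CountMatrix":
        """Row subset preserving order of ``self``."""
        keep = [t for t in self.counts.index if t in set(transcript_ids)]
        return CountMatrix(self.layer, self.counts.loc[keep], dict(self.group_of))


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with genomic coordinates (1-based inclusive) and strand."""

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    known: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegulatoryPair:
    """A lncRNA -> coding-gene link with its structural and correlation evidence.

    ``mode`` is one of ``cis`` (genomic gap < window), ``antisense``
    (opposite-strand overlap), ``trans`` (co-expression only).
    ``distance_bp`` is set for cis pairs, ``duplex_score`` (lower = more
    stable hybrid) for antisense pairs.
    """

    lnc_id: str
    target_gene_id: str
    mode: str
    r: float
    p: float
    distance_bp: int | None = None
    duplex_score: float | None = None


@dataclass(frozen=True)
class CeRNAEdge:
    """A sponge-sponge edge supported by shared miRNAs.

    Both endpoints pass the per-miRNA anti-correlation gate (r < -0.9)
    for every miRNA listed in ``shared_mirnas``; the endpoints themselves
    are positively co-expressed (``r_ab`` > 0) and the shared-miRNA overlap
    is significant under a hypergeometric tail test (``hyper_p`` < 0.05).
    """

    node_a: str
    type_a: str
    node_b: str
    type_b: str
    shared_mirnas: tuple[str, ...]
    r_ab: float
    hyper_p: float
    mirna_r_a: dict[str, float] = field(default_factory=dict)
    mirna_r_b: dict[str, float] = field(default_factory=dict)


@dataclass
class CeRNANetwork:
    """Typed ceRNA network with miRNA-sharing degree semantics.

    ``degree_of`` maps each sponge node to the number of *distinct*
    miRNAs it shares across its edges (the connectivity definition used
    for hub calling); ``edge_degree_of`` is the plain graph degree.
    """

    edges: list[CeRNAEdge]
    node_types: dict[str, str]
    degree_of: dict[str, int]
    edge_degree_of: dict[str, int]
    hubs: list[str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_types)

    def composition(self) -> dict[str, float]:
        """Fraction of network nodes per type (empty dict for empty network)."""
        if not self.node_types:
            return {}
        n = len(self.node_types)
        out: dict[str, float] = {}
        for t in sorted(set(self.node_types.values())):
            out[t] = sum(1 for v in self.node_types.values() if v == t) / n
        return out
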