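"""Novel lncRNA discovery.

A transcript is called *novel* when two independent coding-potential
screens both call it non-coding AND it has no hit in the known-transcript
catalogue AND it is at least 200 nt long — the intersection rule. The two
screens are (1) the Fickett TESTCODE statistic (position-asymmetry and
composition lookup tables) and (2) the longest-ORF coverage fraction.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import TranscriptRecord

MIN_LNC_LENGTH = 200

_STOPS = ("TAA", "TAG", "TGA")

# Fickett (1982) TESTCODE lookup tables.
_POS_PROB = {
    "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
    "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
    "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
    "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
}
_POS_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POS_EDGES = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1]

_CONTENT_PROB = {
    "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_EDGES = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17]


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT symbols in sequence: {sorted(bad)}")
    return seq


def orf_coverage(sequence: str) -> float:
    """Longest forward-frame ATG..stop ORF length (nt, stop included)
    divided by transcript length; 0 when no complete ORF exists."""
    seq = _check_alphabet(sequence)
    if not seq:
        raise ValueError("empty sequence")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best / len(seq)


def _bin(value: float, edges: list[float]) -> int:
    for i, e in enumerate(edges):
        if value >= e:
            return i
    return len(edges)


def fickett_score(sequence: str) -> float:
    """TESTCODE statistic: weighted sum of eight table look-ups.

    Position parameters capture codon-position asymmetry of each base
    (max frame count over min+1), content parameters the base
    composition. Higher scores indicate coding-like sequence; the
    published decision thresholds are <0.74 non-coding, >0.95 coding.
    """
    seq = _check_alphabet(sequence)
    if len(seq) < 10:
        raise ValueError("sequence shorter than 10 nt")
    frame_counts = [Counter(seq[f::3]) for f in range(3)]
    comp = Counter(seq)
    total = len(seq)
    score = 0.0
    for base in "ACGT":
        counts = [fc.get(base, 0) for fc in frame_counts]
        pos_param = max(counts) / (min(counts) + 1.0)
        score += _POS_PROB[base][_bin(pos_param, _POS_EDGES)] * _POS_WEIGHT[base]
        content = comp.get(base, 0) / total
        score += _CONTENT_PROB[base][_bin(content, _CONTENT_EDGES)] * _CONTENT_WEIGHT[base]
    return score


def call_novelty(transcripts: list[TranscriptRecord], known_ids: set[str],
                 config: RunConfig | None = None) -> pd.DataFrame:
    """Intersection novelty call for a set of (lncRNA) transcripts.

    Returns a DataFrame indexed by transcript id with the scorer values,
    the annotation hit, and ``novelty`` in {known, novel, coding}.
    A transcript in the known catalogue is *known* regardless of scores;
    otherwise it is *novel* only if both scorers call non-coding and it
    is >= 200 nt, else *coding*.
    """
    cfg = config or RunConfig()
    rows = []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"transcript {t.transcript_id} lacks a sequence")
        fick = fickett_score(t.sequence)
        orf = orf_coverage(t.sequence)
        s1 = fick < cfg.fickett_max
        s2 = orf < cfg.orf_frac_max
        hit = t.transcript_id in known_ids
        if hit:
            call = "known"
        elif s1 and s2 and len(t.sequence) >= MIN_LNC_LENGTH:
            call = "novel"
        else:
            call = "coding"
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "fickett_score": fick,
                "orf_fraction": orf,
                "scorer1_noncoding": s1,
                "scorer2_noncoding": s2,
                "annotation_hit": hit,
                "novelty": call,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def expression_density_by_class(log_cpm: pd.DataFrame, novelty: pd.Series,
                                group_of: dict[str, str],
                                de_status: pd.Series | None = None) -> pd.DataFrame:
    """Decile summaries of log2(CPM+1) per novelty class and group.

    One row per (class, group) with deciles d0..d10 and, when DE status
    is given, the count of differential transcripts in the class.
    """
    qs = np.linspace(0, 1, 11)
    rows = []
    for cls in sorted(novelty.unique()):
        ids = novelty.index[novelty == cls]
        ids = [i for i in ids if i in log_cpm.index]
        for grp in ("stress", "control"):
            cols = [s for s in log_cpm.columns if group_of[s] == grp]
            vals = log_cpm.loc[ids, cols].to_numpy().ravel()
            row = {"class": cls, "group": grp, "n_transcripts": len(ids)}
            decs = np.quantile(vals, qs) if vals.size else np.full(11, np.nan)
            row.update({f"d{int(q * 100)}": v for q, v in zip(qs, decs)})
            if de_status is not None:
                row["n_de"] = int((de_status.reindex(ids) != "ns").sum())
            rows.append(row)
    return pd.DataFrame(rows)
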