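"""Readers and writers for the pipeline's on-disk formats.

Counts are TSV (first column transcript id, remaining columns samples),
annotation is GTF (1-based inclusive, transcript features only),
sequences are FASTA (T/U normalised to the DNA alphabet at read time so
seed matching and duplex scoring share one alphabet).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .types import CountMatrix, TranscriptRecord

# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, layer: str, design: dict[str, str]) -> CountMatrix:
    """Read a gene x sample TSV into a validated :class:`CountMatrix`.

    ``design`` maps every sample column to its group (stress/control);
    a sample absent from the design is an error, as are duplicate ids,
    negative or non-integer cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise ValueError(f"{path}: samples missing from design: {missing}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated transcript row {dup!r}")
    return CountMatrix(layer, df, {s: design[s] for s in df.columns})


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("transcript_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GTF annotation

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_annotation(path: str | Path, sequences: dict[str, str] | None = None) -> list[TranscriptRecord]:
    """Parse transcript features from a GTF file.

    Coordinates are kept 1-based inclusive exactly as in the file.
    Strand is mandatory ('+' or '-'): downstream antisense logic is
    undefined without it. Errors carry the offending line number.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "transcript":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            attr = dict(_ATTR_RE.findall(attrs))
            for key in ("transcript_id", "gene_id"):
                if key not in attr:
                    raise ValueError(f"{path}:{lineno}: missing mandatory attribute {key!r}")
            tid = attr["transcript_id"]
            if tid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate transcript_id {tid!r}")
            seen.add(tid)
            biotype = attr.get("transcript_biotype", "coding")
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=attr["gene_id"],
                    biotype=biotype,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    known=attr.get("known", "true") == "true",
                    sequence=(sequences or {}).get(tid),
                )
            )
    return records


def write_annotation(records: list[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'transcript_biotype "{r.biotype}"; known "{"true" if r.known else "false"}";'
            )
            fh.write(
                f"{r.chrom}\tstressrna\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# FASTA

_VALID = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence map.

    Ids are truncated at the first whitespace; sequences are uppercased
    and U is normalised to T. Duplicate ids are an error.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else title
            if name in out:
                raise ValueError(f"{path}: duplicate FASTA id {name!r}")
            out[name] = seq.upper().replace("U", "T")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_id_list(path: str | Path) -> set[str]:
    """One transcript id per line; blank lines ignored."""
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


# ---------------------------------------------------------------------------
# stage outputs

EDGE_COLUMNS = ["nodeA", "typeA", "nodeB", "typeB", "shared_mirna_count", "shared_mirnas", "r", "p"]


def write_edge_list(network, path: str | Path) -> None:
    """Tab-separated sponge-edge list (header always written)."""
    rows = [
        {
            "nodeA": e.node_a,
            "typeA": e.type_a,
            "nodeB": e.node_b,
            "typeB": e.type_b,
            "shared_mirna_count": len(e.shared_mirnas),
            "shared_mirnas": ",".join(e.shared_mirnas),
            "r": e.r_ab,
            "p": e.hyper_p,
        }
        for e in network.edges
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_results(tables: dict[str, pd.DataFrame], network, outdir: str | Path,
                  summary: dict | None = None) -> dict[str, Path]:
    """Write per-stage TSVs, the network edge list, and a JSON run summary.

    ``tables`` maps a stage name (e.g. ``de_mRNA``, ``regulatory_pairs``)
    to its DataFrame; each is written as ``<name>.tsv``. Returns the map
    of written paths.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p
    if network is not None:
        p = outdir / "cerna_edges.tsv"
        write_edge_list(network, p)
        written["cerna_edges"] = p
    if summary is not None:
        p = outdir / "run_summary.json"
        p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written["run_summary"] = p
    return written
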