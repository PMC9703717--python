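"""Readers and writers for the formats the pipeline touches.

Strict contracts: readers reject malformed input rather than coerce it, and
every writer's output round-trips through its reader. Coordinates are
0-based half-open internally; GTF converts to 1-based inclusive at the file
boundary, BED is written natively.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_alphabet


# ---------------------------------------------------------------------------
# sequence records


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (DNA or RNA, not mixed)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        validate_alphabet(self.sequence, self.id)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; uppercase-normalizes, rejects duplicate ids and bad alphabets."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# genomic features (internal 0-based half-open; GTF is 1-based inclusive)

GTF_COLUMNS = (
    "chrom", "source", "feature_type", "start", "end",
    "score", "strand", "frame", "attributes",
)


@dataclass
class FeatureRecord:
    """One annotated interval (gene / exon / UTR3), 0-based half-open."""

    chrom: str
    feature_type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.attributes.get('gene_id', '?')}: "
                f"invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def _format_attributes(attrs: Mapping[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gtf(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                "\t".join(
                    (
                        f.chrom, "cewhiten", f.feature_type,
                        str(f.start + 1), str(f.end),  # to 1-based inclusive
                        ".", f.strand, ".", _format_attributes(f.attributes),
                    )
                )
                + "\n"
            )


def read_gtf(path: str | Path) -> list[FeatureRecord]:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            features.append(
                FeatureRecord(
                    chrom, ftype, int(start) - 1, int(end), strand,
                    _parse_attributes(attrs),
                )
            )
    return features


def write_bed(
    intervals: Iterable[tuple[str, int, int, str, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, n, sc, st = line.rstrip("\n").split("\t")[:6]
            out.append((c, int(s), int(e), n, int(sc), st))
    return out


# ---------------------------------------------------------------------------
# count matrices


class CountMatrix:
    """Features x samples of non-negative integers with per-sample stage labels.

    Thin wrapper over a pandas DataFrame that enforces the invariants the
    differential-expression stage relies on: no missing cells, integer
    non-negative counts, and at least two samples per stage.
    """

    def __init__(self, values: pd.DataFrame, stage_of_sample: Mapping[str, str]):
        if values.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        for sample in values.columns:
            if sample not in stage_of_sample:
                raise ValueError(f"sample {sample!r} has no stage label")
        for col in values.columns:
            for feat, v in values[col].items():
                if v != int(v) or v < 0:
                    raise ValueError(
                        f"non-negative integer required: feature {feat!r}, "
                        f"sample {col!r} has value {v!r}"
                    )
        self.values = values.astype(int)
        self.stage_of_sample = dict(stage_of_sample)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_stage(self, stage: str) -> list[str]:
        return [s for s in self.sample_ids if self.stage_of_sample[s] == stage]

    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            st = self.stage_of_sample[s]
            if st not in seen:
                seen.append(st)
        return seen


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table whose header carries ``sample:stage`` labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty count table")
    stage_of_sample = {}
    new_cols = []
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"{path}: column {col!r} lacks a ':stage' suffix")
        sample, _, stage = col.rpartition(":")
        stage_of_sample[sample] = stage
        new_cols.append(sample)
    df.columns = new_cols
    for col in df.columns:
        series = df[col]
        if series.isna().any():
            feat = series.index[series.isna()][0]
            raise ValueError(f"{path}: missing cell at feature {feat!r}, sample {col!r}")
        for feat, v in series.items():
            if v != int(v) or v < 0:
                raise ValueError(
                    f"{path}: invalid count {v!r} at feature {feat!r}, sample {col!r}"
                )
    return CountMatrix(df, stage_of_sample)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{s}:{matrix.stage_of_sample[s]}" for s in df.columns]
    df.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# network exports


def write_network(edges_or_axes: Sequence, path: str | Path) -> None:
    """Write ceRNA edges or triple axes as TSV plus a GraphML sidecar.

    Edges are objects with ``source_id, mirna_id, rho, p``; axes have
    ``cerna_id, mirna_id, mrna_id, cerna_class``. The sidecar gets the
    same stem with a ``.graphml`` suffix.
    """
    path = Path(path)
    graph = nx.DiGraph()
    rows = []
    if edges_or_axes and hasattr(edges_or_axes[0], "mrna_id"):
        header = ["cerna_id", "mirna_id", "mrna_id", "cerna_class"]
        for a in edges_or_axes:
            rows.append([a.cerna_id, a.mirna_id, a.mrna_id, a.cerna_class])
            graph.add_edge(a.cerna_id, a.mirna_id)
            graph.add_edge(a.mirna_id, a.mrna_id)
    else:
        header = ["source_id", "mirna_id", "rho", "p"]
        for e in edges_or_axes:
            rows.append([e.source_id, e.mirna_id, f"{e.rho:.6g}", f"{e.p:.6g}"])
            graph.add_edge(e.source_id, e.mirna_id, rho=e.rho, p=e.p)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    buf = io.BytesIO()
    nx.write_graphml(graph, buf)
    path.with_suffix(".graphml").write_bytes(buf.getvalue())


def read_axes(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Reparse a triple-axis TSV into (cerna, mirna, mrna, class) tuples."""
    df = pd.read_csv(path, sep="\t")
    expected = ["cerna_id", "mirna_id", "mrna_id", "cerna_class"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: not a triple-axis table (columns {list(df.columns)})")
    return [tuple(row) for row in df.itertuples(index=False)]
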