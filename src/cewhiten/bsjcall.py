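"""Back-splice-junction circRNA calling by anchor remapping.

A read that fails full-length linear mapping is split into its first and
last 20 nt (the anchors). If both anchors map uniquely to the same
chromosome with the head anchor *downstream* of the tail anchor — the
reversed order that only a back-splice produces — the anchors are extended
toward the read middle without mismatch. A candidate is emitted when
exactly one breakpoint is consistent with canonical splicing: genomic AG
immediately upstream of the circRNA start and GT immediately downstream of
its end (reverse-complemented on the minus strand).

Candidates then pass two credibility filters taken from the study design:
at least two *unique* supporting read sequences in at least one sample, and
detection in both an enriched circRNA library and the whole-transcriptome
library (exact BSJ coordinate match).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from ._seq import revcomp, to_rna
from .iolib import FastqRead, FeatureRecord

logger = logging.getLogger(__name__)

DEFAULT_ANCHOR = 20
DEFAULT_MAX_SPAN = 50_000


# ---------------------------------------------------------------------------


class GenomeIndex:
    """Exact k-mer index of both genome strands.

    Maps every k-mer to its occurrences as (chrom, position, strand); a
    minus-strand entry at (c, p, '-') means the k-mer is the reverse
    complement of genome[c][p:p+k].
    """

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_ANCHOR):
        if k < 12:
            raise ValueError(f"anchor length {k} < 12")
        shortest = min(len(s) for s in genome.values())
        if k > shortest:
            raise ValueError(f"anchor length {k} exceeds shortest chromosome ({shortest})")
        self.k = k
        self.genome = genome
        index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for p in range(len(seq) - k + 1):
                kmer = seq[p:p + k]
                index[kmer].append((chrom, p, "+"))
                index[revcomp(kmer)].append((chrom, p, "-"))
        self.index = dict(index)

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.index.get(kmer, [])

    def maps_linearly(self, read: str) -> bool:
        """True if the read (either orientation) matches the genome exactly."""
        for seq in (read, revcomp(read)):
            for chrom, p, strand in self.lookup(seq[: self.k]):
                if strand != "+":
                    continue
                if self.genome[chrom][p:p + len(seq)] == seq:
                    return True
        return False


def build_index(genome: dict[str, str], k: int = DEFAULT_ANCHOR) -> GenomeIndex:
    return GenomeIndex(genome, k)


# ---------------------------------------------------------------------------


@dataclass
class BsjCandidate:
    chrom: str
    start: int  # 0-based half-open span of the circularized region
    end: int
    strand: str
    splice_signal: tuple[str, str] = ("GT", "AG")
    supporting_reads: dict[str, set[str]] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    def unique_count(self, sample: str) -> int:
        return len(self.supporting_reads.get(sample, ()))


@dataclass
class CircRNARecord:
    chrom: str
    start: int
    end: int
    strand: str
    circ_id: str = ""
    spliced_sequence: str = ""
    host_gene: str | None = None
    sample_counts: dict[str, int] = field(default_factory=dict)
    evidence: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def extract_anchors(read: str, anchor_len: int = DEFAULT_ANCHOR) -> tuple[str, str] | None:
    """First and last ``anchor_len`` nt of the read; None if the read is short."""
    if len(read) < 2 * anchor_len:
        return None
    return read[:anchor_len], read[-anchor_len:]


def _extension_lengths(read: str, chrom_seq: str, p_head: int, p_tail: int,
                       k: int) -> tuple[int, int]:
    """Maximal exact extensions of the anchors toward the read middle."""
    L = len(read)
    e_h = k
    while e_h < L and p_head + e_h < len(chrom_seq) and read[e_h] == chrom_seq[p_head + e_h]:
        e_h += 1
    e_t = k
    while (
        e_t < L
        and p_tail + k - e_t - 1 >= 0
        and read[L - e_t - 1] == chrom_seq[p_tail + k - e_t - 1]
    ):
        e_t += 1
    return e_h, e_t


def _detect_oriented(read: str, index: GenomeIndex,
                     max_span: int) -> BsjCandidate | None:
    """Back-splice detection treating ``read`` as the forward genomic text."""
    k = index.k
    anchors = extract_anchors(read, k)
    if anchors is None:
        return None
    head, tail = anchors
    head_hits = [h for h in index.lookup(head) if h[2] == "+"]
    tail_hits = [h for h in index.lookup(tail) if h[2] == "+"]
    if len(head_hits) != 1 or len(tail_hits) != 1:
        return None
    (chrom_h, p_head, _), (chrom_t, p_tail, _) = head_hits[0], tail_hits[0]
    if chrom_h != chrom_t or p_head <= p_tail:
        return None  # forward order: linear splice, not a back-splice
    chrom_seq = index.genome[chrom_h]
    L = len(read)
    e_h, e_t = _extension_lengths(read, chrom_seq, p_head, p_tail, k)
    if e_h + e_t < L:
        return None  # extensions do not cover the read: mismatch near breakpoint
    consistent = []
    for s in range(max(k, L - e_t), min(e_h, L - k) + 1):
        circ_end = p_head + s
        circ_start = p_tail + k + s - L
        if circ_start < 2 or circ_end + 2 > len(chrom_seq):
            continue
        span = circ_end - circ_start
        if span < 2 * k or span > max_span:
            continue
        up = chrom_seq[circ_start - 2:circ_start]
        down = chrom_seq[circ_end:circ_end + 2]
        if up == "AG" and down == "GT":
            consistent.append((circ_start, circ_end, "+"))
        elif up == "AC" and down == "CT":  # revcomp(GT/AG): minus strand
            consistent.append((circ_start, circ_end, "-"))
    if len(consistent) != 1:
        if len(consistent) > 1:
            logger.debug("ambiguous breakpoint for read; discarded")
        return None
    start, end, strand = consistent[0]
    return BsjCandidate(chrom_h, start, end, strand)


def detect_bsj(read: str, index: GenomeIndex,
               max_span: int = DEFAULT_MAX_SPAN) -> BsjCandidate | None:
    """Detect a back-splice junction in one read, or None.

    Linearly mapping reads are rejected first; both read orientations are
    then tried against the forward genome text, so stranded and
    reverse-stranded BSJ reads are both recovered.
    """
    read = read.upper()
    if index.maps_linearly(read):
        return None
    cand = _detect_oriented(read, index, max_span)
    if cand is None:
        cand = _detect_oriented(revcomp(read), index, max_span)
    return cand


# ---------------------------------------------------------------------------


def detect_sample(reads: list[FastqRead], index: GenomeIndex, sample_id: str,
                  max_span: int = DEFAULT_MAX_SPAN) -> list[BsjCandidate]:
    """Run detection over one sample's reads and aggregate supporting reads."""
    cands = []
    for r in reads:
        c = detect_bsj(r.sequence, index, max_span)
        if c is not None:
            c.supporting_reads = {sample_id: {r.sequence}}
            cands.append(c)
    return aggregate_candidates(cands, sample_id, min_unique=0)


def aggregate_candidates(candidates: list[BsjCandidate], sample_id: str,
                         min_unique: int = 2) -> list[BsjCandidate]:
    """Merge per-read candidates by exact BSJ key; drop weakly supported ones.

    A candidate survives when it has at least ``min_unique`` distinct
    supporting read sequences in the given sample (``min_unique=0`` keeps
    everything, for cross-sample pooling).
    """
    by_key: dict[tuple, BsjCandidate] = {}
    for c in candidates:
        merged = by_key.get(c.key)
        if merged is None:
            merged = BsjCandidate(c.chrom, c.start, c.end, c.strand, c.splice_signal, {})
            by_key[c.key] = merged
        for sample, seqs in c.supporting_reads.items():
            merged.supporting_reads.setdefault(sample, set()).update(seqs)
    out = [
        c for c in by_key.values()
        if c.unique_count(sample_id) >= min_unique
    ]
    return sorted(out, key=lambda c: c.key)


def combine_samples(per_sample: dict[str, list[BsjCandidate]],
                    min_unique: int = 2) -> list[BsjCandidate]:
    """Pool candidates across samples; keep those with >= ``min_unique``
    distinct read sequences in at least one sample, quantified in all."""
    by_key: dict[tuple, BsjCandidate] = {}
    for sample in sorted(per_sample):
        for c in per_sample[sample]:
            merged = by_key.get(c.key)
            if merged is None:
                merged = BsjCandidate(c.chrom, c.start, c.end, c.strand,
                                      c.splice_signal, {})
                by_key[c.key] = merged
            for s, seqs in c.supporting_reads.items():
                merged.supporting_reads.setdefault(s, set()).update(seqs)
    out = [
        c for c in by_key.values()
        if any(c.unique_count(s) >= min_unique for s in c.supporting_reads)
    ]
    return sorted(out, key=lambda c: c.key)


def merge_dual_evidence(circseq_set: list[BsjCandidate],
                        wholetx_set: list[BsjCandidate]) -> list[CircRNARecord]:
    """Credible circRNAs: exact BSJ present in both libraries.

    Per-sample unique-read counts are carried from the whole-transcriptome
    set (the per-sample arm of the design).
    """
    circseq_keys = {c.key for c in circseq_set}
    records = []
    for i, c in enumerate(sorted(wholetx_set, key=lambda x: x.key)):
        if c.key not in circseq_keys:
            continue
        counts = {s: len(seqs) for s, seqs in sorted(c.supporting_reads.items())}
        records.append(
            CircRNARecord(
                c.chrom, c.start, c.end, c.strand,
                circ_id=f"bsj_{c.chrom}_{c.start}_{c.end}_{c.strand}",
                sample_counts=counts,
                evidence={"circseq_lib", "wholetx_lib"},
            )
        )
    return records


def spliced_sequence(circ: CircRNARecord | BsjCandidate,
                     annotation: list[FeatureRecord] | None,
                     genome: dict[str, str]) -> str:
    """Spliced sequence of a circRNA: exon concatenation inside its span.

    Exons fully inside [start, end) on the circ's chromosome and strand are
    joined in genomic order (reverse-complemented on '-'); with no
    overlapping exon annotation the genomic substring is returned. Exons
    straddling the span boundary are an error.
    """
    chrom_seq = genome[circ.chrom]
    exons = []
    for f in annotation or []:
        if f.feature_type != "exon" or f.chrom != circ.chrom or f.strand != circ.strand:
            continue
        if f.end <= circ.start or f.start >= circ.end:
            continue
        if f.start < circ.start or f.end > circ.end:
            raise ValueError(
                f"exon [{f.start},{f.end}) extends outside circ span "
                f"[{circ.start},{circ.end})"
            )
        exons.append((f.start, f.end))
    if not exons:
        seq = chrom_seq[circ.start:circ.end]
    else:
        seq = "".join(chrom_seq[a:b] for a, b in sorted(set(exons)))
    if circ.strand == "-":
        seq = revcomp(seq)
    return to_rna(seq)
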