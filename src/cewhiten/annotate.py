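"""Conservation filtering by local alignment, and term enrichment.

Conservation emulates a BLAST-based cross-species mapping with exact
Smith-Waterman local alignment (match +1, mismatch -2, gap -2; both
strands searched). A query counts as conserved against a subject database
when alignments to one subject, each with >= 70% identity, cover >= 100 nt
of the query (union of intervals) with a summed identity of >= 75% over
the covered length.

Enrichment is the EASE-penalized hypergeometric upper tail: the observed
overlap is reduced by one (floored at zero) before computing
P(X >= overlap - 1), a deliberately conservative variant of Fisher's test.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from scipy.stats import hypergeom

from ._seq import revcomp, to_dna


@dataclass(frozen=True)
class LocalAlignment:
    query_id: str
    subject_id: str
    score: float
    aligned_length: int  # alignment columns, gaps included
    identical_positions: int
    query_cover_interval: tuple[int, int]  # 0-based half-open on the query
    strand: str = "+"

    @property
    def identity(self) -> float:
        return self.identical_positions / self.aligned_length if self.aligned_length else 0.0


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _align_one(aligner, query: str, subject: str):
    alns = aligner.align(query, subject)
    if len(alns) == 0 or alns.score <= 0:
        return None
    return alns[0]


def local_align(query: str, subject: str, query_id: str = "query",
                subject_id: str = "subject", match: float = 1.0,
                mismatch: float = -2.0, gap: float = -2.0) -> LocalAlignment | None:
    """Best Smith-Waterman local alignment of query vs subject, both strands.

    Linear gap penalty (open == extend). Returns None when no positive-score
    alignment exists. T and U are treated as equivalent.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    q = to_dna(query.upper())
    s = to_dna(subject.upper())
    aligner = _make_aligner(match, mismatch, gap)
    best = None
    for strand, subj in (("+", s), ("-", revcomp(s))):
        aln = _align_one(aligner, q, subj)
        if aln is None:
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    # Biopython's aligner.align(target, query): our query was passed as the
    # "target" sequence, so the first block list indexes into it
    q_blocks, s_blocks = aln.aligned
    subj_text = str(aln.query)
    identical = 0
    columns = 0
    prev_q = prev_s = None
    for (qa, qb), (sa, sb) in zip(q_blocks, s_blocks):
        if prev_q is not None:
            columns += (qa - prev_q) + (sa - prev_s)  # gap columns
        columns += qb - qa
        identical += sum(
            1 for i in range(qb - qa) if q[qa + i] == subj_text[sa + i]
        )
        prev_q, prev_s = qb, sb
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return LocalAlignment(
        query_id, subject_id, float(aln.score), int(columns), int(identical),
        (q_start, q_end), strand,
    )


def conservation_filter(alignments: list[LocalAlignment], query_length: int,
                        min_identity: float = 0.70,
                        min_total_identity: float = 0.75,
                        min_cover: int = 100) -> bool:
    """Conserved iff one subject's kept alignments cover enough of the query.

    Kept alignments each need per-alignment identity >= ``min_identity``;
    the union of their query cover intervals must span >= ``min_cover`` nt,
    and summed identical positions over the covered length must reach
    ``min_total_identity``.
    """
    by_subject: dict[str, list[LocalAlignment]] = {}
    for a in alignments:
        if a.identity >= min_identity:
            by_subject.setdefault(a.subject_id, []).append(a)
    for subject, alns in by_subject.items():
        intervals = sorted(a.query_cover_interval for a in alns)
        covered = 0
        cur_start, cur_end = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_end:
                covered += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        covered += cur_end - cur_start
        covered = min(covered, query_length)
        if covered < min_cover:
            continue
        total_identical = sum(a.identical_positions for a in alns)
        if min(total_identical, covered) / covered >= min_total_identity:
            return True
    return False


# ---------------------------------------------------------------------------
# enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    p: float
    significant: bool


def ease_enrichment(gene_set: set[str], universe: set[str],
                    term_map: dict[str, set[str]],
                    alpha: float = 0.05) -> list[EnrichmentResult]:
    """EASE-penalized hypergeometric enrichment per term.

    p = P(X >= overlap - 1) with X ~ Hypergeom(universe, term, set); the
    penalized overlap is floored at 0 (p = 1). Terms with no universe genes
    are skipped.
    """
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    n_univ, n_set = len(universe), len(gene_set)
    out = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & universe
        if not members:
            continue
        overlap = len(gene_set & members)
        penalized = max(overlap - 1, 0)
        if penalized == 0:
            p = 1.0
        else:
            # upper tail P(X >= penalized)
            p = float(hypergeom.sf(penalized - 1, n_univ, len(members), n_set))
        out.append(
            EnrichmentResult(term_id, overlap, n_set, len(members), n_univ,
                             p, p < alpha)
        )
    return out
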