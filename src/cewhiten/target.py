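"""Seed-anchored miRNA binding-site prediction, including BSJ-spanning sites.

Sites are anchored on perfect Watson-Crick complementarity to the miRNA
seed (positions 2-8, 7mer-m8), then extended over the full miRNA span and
scored with a configurable match/wobble/mismatch scheme. G:U wobble pairs
are allowed in the 3' extension but never in the seed.

Circular RNAs get a second search space: the *BSJ pseudo-sequence* — the
last 100 nt of the spliced circRNA concatenated to its first 100 nt —
linearizes the junction neighbourhood, and sites whose interval straddles
the junction offset exist only in the circular form. A (circRNA, miRNA)
pair is a *novel junction pair* when it has at least one junction-spanning
site and no site anywhere on the linear spliced sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp, to_dna
from .iolib import SequenceRecord


@dataclass(frozen=True)
class ScoreParams:
    """Scoring for the seed-anchored duplex; defaults are permissive
    (a seed match alone suffices)."""

    seed_start: int = 1  # miRNA position 2, 0-based
    seed_end: int = 8    # miRNA position 8 inclusive -> exclusive bound 8
    match_score: float = 5.0
    wobble_score: float = 1.0
    mismatch_score: float = -3.0
    gap_score: float = -8.0
    min_total_score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.match_score > self.wobble_score > 0
                > self.mismatch_score > self.gap_score):
            raise ValueError("require match > wobble > 0 > mismatch > gap")


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        if not 18 <= len(self.sequence) <= 30:
            raise ValueError(f"{self.id}: mature length {len(self.sequence)} not in [18, 30]")
        if not set(self.sequence) <= set("ACGU"):
            raise ValueError(f"{self.id}: mature sequence must be RNA (ACGU)")


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    target_id: str
    start: int  # 0-based half-open on the target sequence
    end: int
    score: float
    pairing: str  # per-position '|' match, ':' wobble, '.' mismatch, ' ' off-target
    spans_junction: bool | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # miRNA G : target U, miRNA U : target G


def _pair_class(mirna_base: str, target_base: str) -> str:
    pair = (to_dna(mirna_base), to_dna(target_base))
    if pair in _WC:
        return "|"
    if pair in _WOBBLE:
        return ":"
    return "."


def seed_sites(mirna: MatureMiRNA, target: SequenceRecord | str,
               params: ScoreParams = ScoreParams()) -> list[TargetSite]:
    """All scored seed-anchored sites of one miRNA on one target sequence.

    The reverse complement of the seed is located exactly (T and U
    equivalent); each hit is extended over the full miRNA span where the
    target allows, scored position-wise (wobble counts as mismatch inside
    the seed), and overlapping sites are deduplicated keeping the best
    score (leftmost on ties).
    """
    if isinstance(target, SequenceRecord):
        target_id, tseq = target.id, target.sequence
    else:
        target_id, tseq = "target", target
    t = to_dna(tseq)
    if len(t) < 7:
        return []
    seed_rc = revcomp(to_dna(mirna.sequence[params.seed_start:params.seed_end]))
    m = len(mirna.sequence)
    sites = []
    at = t.find(seed_rc)
    while at >= 0:
        # antiparallel pairing: the seed occupies target [at, at+7), miRNA
        # index i (0-based) pairs target position at + 7 - i, so the full
        # miRNA span covers target [at + 8 - m, at + 8)
        start = max(0, at + 8 - m)
        end = min(len(t), at + 8)
        pairing = []
        deltas = []
        for i in range(m):
            tpos = at + 7 - i
            if not start <= tpos < end:
                pairing.append(" ")
                deltas.append(None)
                continue
            cls = _pair_class(mirna.sequence[i], t[tpos])
            in_seed = params.seed_start <= i < params.seed_end
            if cls == "|":
                deltas.append(params.match_score)
            elif cls == ":" and not in_seed:
                deltas.append(params.wobble_score)
            else:
                cls = "."
                deltas.append(params.mismatch_score)
            pairing.append(cls)
        # duplex score: the seed block plus the best-scoring contiguous
        # outward extension on each side (never negative), so a bare seed
        # match passes the default min_total_score of 0
        score = sum(deltas[i] for i in range(params.seed_start, params.seed_end)
                    if deltas[i] is not None)
        head = deltas[: params.seed_start]  # miRNA 5' of the seed
        run = best = 0.0
        for d in reversed(head):
            if d is None:
                break
            run += d
            best = max(best, run)
        score += best
        run = best = 0.0
        for d in deltas[params.seed_end:]:  # 3' extension
            if d is None:
                break
            run += d
            best = max(best, run)
        score += best
        if score >= params.min_total_score:
            sites.append(
                TargetSite(mirna.id, target_id, start, end, score, "".join(pairing))
            )
        at = t.find(seed_rc, at + 1)
    return _dedup_overlapping(sites)


def _dedup_overlapping(sites: list[TargetSite]) -> list[TargetSite]:
    """Among overlapping same-miRNA sites keep the best score, leftmost on ties."""
    kept: list[TargetSite] = []
    for s in sorted(sites, key=lambda x: (x.start, x.end)):
        if kept and s.start < kept[-1].end:
            if s.score > kept[-1].score:
                kept[-1] = s
            continue
        kept.append(s)
    return kept


def predict_sites(mirnas: list[MatureMiRNA], targets: list[SequenceRecord],
                  params: ScoreParams = ScoreParams()) -> list[TargetSite]:
    """Sites of every miRNA on every target; order-invariant output."""
    out = []
    for tgt in sorted(targets, key=lambda r: r.id):
        for mir in sorted(mirnas, key=lambda r: r.id):
            out.extend(seed_sites(mir, tgt, params))
    return out


def predict_mirna_mrna(mirnas: list[MatureMiRNA], utr3: list[SequenceRecord],
                       params: ScoreParams = ScoreParams()) -> list[TargetSite]:
    """mRNA target prediction restricted to 3'UTR sequence space."""
    return predict_sites(mirnas, utr3, params)


def bsj_pseudo_sequence(circ_spliced: str) -> tuple[str, int]:
    """Tail-head concatenation linearizing the BSJ.

    Returns ``(last min(100, L) nt + first min(100, L) nt, junction_offset)``;
    the junction offset is the length of the tail window. For L < 100 the
    windows are the whole sequence and the pseudo-sequence is the doubled
    circRNA.
    """
    if len(circ_spliced) < 2:
        raise ValueError("circ spliced sequence shorter than 2 nt")
    w = min(100, len(circ_spliced))
    return circ_spliced[-w:] + circ_spliced[:w], w


def junction_filter(sites: list[TargetSite], junction_offset: int) -> list[TargetSite]:
    """Keep sites whose interval strictly straddles the junction."""
    return [
        TargetSite(s.mirna_id, s.target_id, s.start, s.end, s.score, s.pairing,
                   spans_junction=True)
        for s in sites
        if s.start < junction_offset < s.end
    ]


def junction_sites(circ_id: str, circ_spliced: str, mirnas: list[MatureMiRNA],
                   params: ScoreParams = ScoreParams()) -> list[TargetSite]:
    """Junction-spanning sites on a circRNA's BSJ pseudo-sequence."""
    pseudo, off = bsj_pseudo_sequence(circ_spliced)
    rec = SequenceRecord(circ_id, pseudo)
    sites = []
    for mir in sorted(mirnas, key=lambda r: r.id):
        sites.extend(junction_filter(seed_sites(mir, rec, params), off))
    return sites


def novel_junction_pairs(circs: dict[str, str], mirnas: list[MatureMiRNA],
                         params: ScoreParams = ScoreParams()
                         ) -> list[tuple[str, str]]:
    """(circ_id, mirna_id) pairs bound only across the BSJ.

    Reported iff the pair has >= 1 junction-spanning site on the
    pseudo-sequence and zero sites anywhere on the full linear spliced
    sequence — the interaction exists only under circularization.
    """
    pairs = []
    for circ_id in sorted(circs):
        spliced = circs[circ_id]
        rec = SequenceRecord(circ_id, spliced)
        for mir in sorted(mirnas, key=lambda r: r.id):
            if not junction_filter(
                seed_sites(mir, SequenceRecord(circ_id, bsj_pseudo_sequence(spliced)[0]),
                           params),
                bsj_pseudo_sequence(spliced)[1],
            ):
                continue
            if seed_sites(mir, rec, params):
                continue  # seed also present in the linear body
            pairs.append((circ_id, mir.id))
    return pairs
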