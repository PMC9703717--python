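"""Synthetic multi-omic dataset generator with a ground-truth manifest.

Emulates a 4-stage x 3-replicate brown-adipose-tissue whitening design: a
small multi-chromosome genome carrying multi-exon genes, implanted circRNAs
with genomic AG...GT splice flanks, back-splice-junction (BSJ) and linear
read sets, mature miRNAs whose seed complements are implanted into 3'UTRs,
lncRNAs and circRNA bodies — and, crucially, split across BSJs so the site
exists only in the circular form — plus negative-binomial count matrices
with designed stage-selective expression archetypes and designed negative
miRNA-target correlations.

Everything the generator implants is recorded in a :class:`GroundTruthManifest`,
the oracle for every downstream recovery test. Generation is fully
deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import STAGE_LABELS
from ._seq import revcomp, to_dna, to_rna
from .iolib import (
    CountMatrix,
    FastqRead,
    FeatureRecord,
    SequenceRecord,
    write_bed,
    write_counts,
    write_fasta,
    write_fastq,
    write_gtf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default 3' sequencing adapter on small-RNA reads (Illumina TruSeq)
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

#: the seven expression archetypes implanted in the count design; four
#: stage-selective peaks, two monotone ramps, and one early-stage trough
ARCHETYPE_NAMES = (
    "D0_high", "D15_high", "D85_high", "Y2_high", "up_ramp", "down_ramp", "D0_low",
)


def archetype_multipliers(effect_log2fc: float) -> dict[str, tuple[float, ...]]:
    """Per-stage fold multipliers for each archetype, amplitude 2**effect_log2fc."""
    a = 2.0 ** effect_log2fc
    r1, r2 = a ** (1 / 3), a ** (2 / 3)
    return {
        "D0_high": (a, 1, 1, 1),
        "D15_high": (1, a, 1, 1),
        "D85_high": (1, 1, a, 1),
        "Y2_high": (1, 1, 1, a),
        "up_ramp": (1, r1, r2, a),
        "down_ramp": (a, r2, r1, 1),
        "D0_low": (1, a, a, a),
    }


_MIRROR = {"up_ramp": "down_ramp", "down_ramp": "up_ramp"}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the standard conditions."""

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 100_000
    n_genes: int = 90
    exons_per_gene: tuple[int, int] = (2, 4)
    n_circ: int = 50
    n_mirna: int = 20
    n_lncrna: int = 20
    wholetx_read_length: int = 150
    smallrna_read_length: int = 50
    bsj_coverage: int = 10
    linear_coverage: float = 3.0
    stage_labels: tuple[str, ...] = STAGE_LABELS
    reps_per_stage: int = 3
    nb_dispersion: float = 0.1
    effect_log2fc: float = 2.0
    fraction_junction_only_mres: float = 0.2
    substitution_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    utr3_length: int = 120
    lncrna_length: int = 500

    def validate(self) -> None:
        if self.reps_per_stage < 2:
            raise ValueError("configuration infeasible: reps_per_stage must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("configuration infeasible: nb_dispersion must be > 0")
        if not 0 <= self.fraction_junction_only_mres <= 1:
            raise ValueError(
                "configuration infeasible: fraction_junction_only_mres not in [0, 1]"
            )
        if self.n_circ > self.n_genes:
            raise ValueError(
                "configuration infeasible: n_circ exceeds n_genes "
                "(one host gene per circRNA)"
            )
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("configuration infeasible: bad exons_per_gene range")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{st}_{r + 1}" for st in self.stage_labels
            for r in range(self.reps_per_stage)
        ]

    @property
    def stage_of_sample(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic order, 0-based half-open

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class CircTruth:
    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    spliced_sequence: str
    host_gene: str
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MreTruth:
    mirna_id: str
    target_id: str
    target_class: str  # utr3 | lncrna | circ_body | circ_junction
    site_interval: tuple[int, int]  # on the target sequence (pseudo coords for junction)


@dataclass
class GroundTruthManifest:
    """Record of everything the generator implanted; oracle for recovery tests."""

    circ_truth: list[CircTruth]
    mre_truth: list[MreTruth]
    expression_design: dict[str, pd.DataFrame]  # class -> features x stages means
    de_truth: dict[str, pd.DataFrame]  # class -> features x comparisons sign
    cluster_archetype: dict[str, str]  # feature -> archetype name
    designed_axes: list[tuple[str, str, str, str]]  # (cerna, mirna, mrna, class)
    decoy_junction_pairs: list[tuple[str, str]]  # (circ_id, mirna_id); body+junction

    def junction_pairs(self) -> set[tuple[str, str]]:
        """(circ_id, mirna_id) pairs whose only site is split across the BSJ."""
        return {
            (m.target_id, m.mirna_id)
            for m in self.mre_truth
            if m.target_class == "circ_junction"
        }


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[Gene]
    annotation: list[FeatureRecord]
    mirna_set: list[SequenceRecord]  # RNA
    lncrna_set: list[SequenceRecord]
    utr3_set: list[SequenceRecord]  # one per coding gene, transcript-oriented
    read_sets: dict  # circseq: [reads]; wholetx/smallrna: {sample: [reads]}
    count_matrices: dict[str, CountMatrix]
    manifest: GroundTruthManifest

    def transcript_sequence(self, gene: Gene) -> str:
        s = "".join(self.genome[gene.chrom][a:b] for a, b in gene.exons)
        return revcomp(s) if gene.strand == "-" else s


# ---------------------------------------------------------------------------
# low-level helpers


def _random_dna(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _spliced_to_genomic(exons: Sequence[tuple[int, int]], strand: str,
                        t0: int, length: int) -> tuple[int, int]:
    """Map a spliced-coordinate interval (strand-oriented) to one genomic
    interval; the interval must lie within a single exon."""
    total = sum(b - a for a, b in exons)
    if strand == "-":
        c0 = total - t0 - length  # position in genomic-order concatenation
    else:
        c0 = t0
    off = 0
    for a, b in exons:
        if c0 < off + (b - a):
            if c0 + length > off + (b - a):
                raise ValueError("implant interval spans an exon boundary")
            g = a + (c0 - off)
            return g, g + length
        off += b - a
    raise ValueError("spliced coordinate outside transcript")


def _write_spliced(chrom_seq: bytearray, exons, strand, t0: int, motif: str) -> None:
    """Write ``motif`` (strand-oriented letters) at spliced position ``t0``."""
    g0, g1 = _spliced_to_genomic(exons, strand, t0, len(motif))
    text = revcomp(motif) if strand == "-" else motif
    chrom_seq[g0:g1] = text.encode()


def seed_complement(mature_rna: str) -> str:
    """DNA reverse complement of miRNA seed positions 2-8 (7mer-m8)."""
    return revcomp(to_dna(mature_rna[1:8]))


# ---------------------------------------------------------------------------
# generator internals


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[Gene]:
    genes: list[Gene] = []
    cursor = {f"chr{i + 1}": 200 for i in range(cfg.n_chromosomes)}
    min_exon = max(130, cfg.wholetx_read_length)
    max_exon = min_exon + 100
    for gi in range(cfg.n_genes):
        chrom = f"chr{(gi % cfg.n_chromosomes) + 1}"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        pos = cursor[chrom]
        exons = []
        for e in range(n_ex):
            length = int(rng.integers(min_exon, max_exon + 1))
            exons.append((pos, pos + length))
            pos += length
            if e < n_ex - 1:
                pos += int(rng.integers(80, 151))  # intron
        cursor[chrom] = pos + int(rng.integers(150, 301))  # intergenic gap
        if pos + 300 > cfg.chromosome_length:
            raise ValueError(
                "configuration infeasible: genes do not fit on "
                f"{chrom} (need > {pos} nt, have {cfg.chromosome_length})"
            )
        genes.append(Gene(f"G{gi:04d}", chrom, strand, tuple(exons)))
    longest = max(g.span[1] - g.span[0] for g in genes)
    if cfg.chromosome_length < 10 * longest:
        raise ValueError(
            "configuration infeasible: chromosome_length "
            f"{cfg.chromosome_length} < 10 x longest gene span {longest}"
        )
    return genes


def _draw_mirnas(cfg: SimulationConfig, rng: np.random.Generator) -> list[SequenceRecord]:
    """Random 22-nt mature miRNAs with pairwise-distinct seed complements."""
    mirnas: list[SequenceRecord] = []
    seeds: set[str] = set()
    while len(mirnas) < cfg.n_mirna:
        seq = to_rna(bytes(_random_dna(rng, 22)).decode())
        sc = seed_complement(seq)
        if sc in seeds:
            continue
        seeds.add(sc)
        mirnas.append(SequenceRecord(f"miR-{len(mirnas):03d}", seq))
    return mirnas


def _simulate_reads_from(seq: str, n: int, read_length: int,
                         rng: np.random.Generator, prefix: str,
                         sub_rate: float = 0.0) -> list[FastqRead]:
    reads = []
    if len(seq) < read_length:
        return reads
    starts = rng.integers(0, len(seq) - read_length + 1, n)
    for i, a in enumerate(starts):
        r = seq[a:a + read_length]
        if sub_rate > 0:
            r = _mutate(r, sub_rate, rng)
        reads.append(FastqRead(f"{prefix}_{i}", r, "I" * read_length))
    return reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = bytearray(seq.encode())
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return bytes(arr).decode()


def simulate_bsj_reads(spliced: str, n: int, read_length: int,
                       rng: np.random.Generator, prefix: str = "bsj",
                       rolling: bool = False,
                       sub_rate: float = 0.0) -> list[FastqRead]:
    """Reads straddling the back-splice junction with >= 21 nt on each side.

    Junction offsets are drawn without replacement while enough distinct
    offsets remain, so the number of unique supporting read sequences grows
    linearly with coverage.
    """
    if n == 0:
        return []
    L = len(spliced)
    if L < read_length and not rolling:
        raise ValueError(
            f"spliced length {L} < read length {read_length}; enable rolling mode"
        )
    if rolling:
        reps = math.ceil(read_length / L) + 1
        doubled = spliced * (2 * reps)
        junction = L * reps
    else:
        doubled = spliced * 2
        junction = L
    lo = junction - read_length + 21
    hi = junction - 21  # inclusive; both sides >= 21 nt
    if lo < 0 or hi < lo:
        raise ValueError("spliced sequence too short to straddle the junction")
    offsets = np.arange(lo, hi + 1)
    if n <= len(offsets):
        starts = rng.choice(offsets, size=n, replace=False)
    else:
        starts = rng.choice(offsets, size=n, replace=True)
    reads = []
    for i, a in enumerate(sorted(int(x) for x in starts)):
        r = doubled[a:a + read_length]
        if sub_rate > 0:
            r = _mutate(r, sub_rate, rng)
        reads.append(FastqRead(f"{prefix}_{i}", r, "I" * read_length))
    return reads


def simulate_counts(design: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator,
                    size_factors: np.ndarray | None = None) -> CountMatrix:
    """Draw a negative-binomial count matrix from per-stage mean designs.

    ``design`` is features x stages (positive means). Per-sample library
    size factors default to log-normal(0, 0.1) draws. Dispersion ``alpha``
    gives variance ``mu + alpha * mu**2``; the Poisson limit is used below
    alpha = 1e-8.
    """
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    if (design.values <= 0).any():
        raise ValueError("design means must be > 0")
    samples = config.sample_ids
    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, 0.1, len(samples)))
    alpha = config.nb_dispersion
    out = np.zeros((design.shape[0], len(samples)), dtype=int)
    for j, s in enumerate(samples):
        stage = config.stage_of_sample[s]
        mu = design[stage].values * size_factors[j]
        if alpha < 1e-8:
            out[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            out[:, j] = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(out, index=design.index, columns=samples)
    return CountMatrix(df, config.stage_of_sample)


def archetype_profiles(n_per_cluster: int, reps_per_stage: int, noise_sd: float,
                       rng: np.random.Generator,
                       effect_log2fc: float = 2.0) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample log-space profiles for the seven archetypes plus truth labels.

    Used as the clustering benchmark: each feature's 12 values are its
    archetype's per-stage log2 multiplier repeated per replicate plus
    N(0, noise_sd) noise.
    """
    mult = archetype_multipliers(effect_log2fc)
    rows, labels, index = [], [], []
    for name in ARCHETYPE_NAMES:
        base = np.repeat(np.log2(mult[name]), reps_per_stage)
        for i in range(n_per_cluster):
            rows.append(base + rng.normal(0, noise_sd, len(base)))
            labels.append(name)
            index.append(f"{name}_{i}")
    cols = [f"{st}_{r + 1}" for st in STAGE_LABELS for r in range(reps_per_stage)]
    return pd.DataFrame(rows, index=index, columns=cols), pd.Series(labels, index=index)


# ---------------------------------------------------------------------------
# the generator


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _place_genes(config, rng)
    chrom_seqs = {
        f"chr{i + 1}": _random_dna(rng, config.chromosome_length)
        for i in range(config.n_chromosomes)
    }

    # --- circRNAs: one per host gene, spanning a contiguous exon run -------
    circ_hosts = genes[: config.n_circ]
    free_genes = genes[config.n_circ:]
    circ_defs = []  # (circ_id, gene, exon_lo, exon_hi)
    for ci, gene in enumerate(circ_hosts):
        n_ex = len(gene.exons)
        lo = int(rng.integers(0, n_ex))
        hi = int(rng.integers(lo, n_ex))
        circ_defs.append((f"circ_{ci:04d}", gene, lo, hi))
        start = gene.exons[lo][0]
        end = gene.exons[hi][1]
        seq = chrom_seqs[gene.chrom]
        if gene.strand == "+":
            seq[start - 2:start] = b"AG"  # acceptor upstream of the circ start
            seq[end:end + 2] = b"GT"      # donor downstream of the circ end
        else:
            seq[start - 2:start] = b"AC"  # revcomp(GT): minus-strand donor
            seq[end:end + 2] = b"CT"      # revcomp(AG): minus-strand acceptor

    # --- miRNAs and lncRNAs ------------------------------------------------
    mirnas = _draw_mirnas(config, rng)
    lnc_seqs = {
        f"lnc_{i:03d}": _random_dna(rng, config.lncrna_length)
        for i in range(config.n_lncrna)
    }

    # --- MRE implants -------------------------------------------------------
    # sponge-designed miRNAs get ramp archetypes and implanted targets
    n_sponge = min(config.n_mirna, max(1, config.n_mirna // 2))
    sponge_mirnas = mirnas[:n_sponge]
    n_junction = round(config.fraction_junction_only_mres * config.n_circ)
    n_body = min(n_junction, config.n_circ - n_junction)
    n_decoy = min(3, config.n_circ - n_junction - n_body)

    mre_truth: list[MreTruth] = []
    decoy_pairs: list[tuple[str, str]] = []
    circ_exon_list = {cid: g.exons[lo:hi + 1] for cid, g, lo, hi in circ_defs}
    circ_strand = {cid: g.strand for cid, g, lo, hi in circ_defs}
    circ_chrom = {cid: g.chrom for cid, g, lo, hi in circ_defs}
    circ_mirna_designed: dict[str, list[tuple[str, str]]] = {}  # circ -> [(mirna, kind)]

    def spliced_len(cid: str) -> int:
        return sum(b - a for a, b in circ_exon_list[cid])

    def implant_junction(cid: str, mir: SequenceRecord) -> None:
        sc = seed_complement(mir.sequence)  # 7-nt DNA
        h = int(rng.integers(1, 7))  # tail keeps h nt, head gets 7-h
        exons = circ_exon_list[cid]
        strand = circ_strand[cid]
        seq = chrom_seqs[circ_chrom[cid]]
        L = spliced_len(cid)
        _write_spliced(seq, exons, strand, L - h, sc[:h])
        _write_spliced(seq, exons, strand, 0, sc[h:])
        mre_truth.append(MreTruth(mir.id, cid, "circ_junction", (100 - h, 107 - h)))
        circ_mirna_designed.setdefault(cid, []).append((mir.id, "junction"))

    def implant_body(cid: str, mir: SequenceRecord) -> None:
        sc = seed_complement(mir.sequence)
        L = spliced_len(cid)
        t = int(rng.integers(30, L - 37))  # clear of both spliced ends
        exons = circ_exon_list[cid]
        # retry until the 7-mer sits inside a single exon
        for _ in range(50):
            try:
                _spliced_to_genomic(exons, circ_strand[cid], t, 7)
                break
            except ValueError:
                t = int(rng.integers(30, L - 37))
        _write_spliced(chrom_seqs[circ_chrom[cid]], exons, circ_strand[cid], t, sc)
        mre_truth.append(MreTruth(mir.id, cid, "circ_body", (t, t + 7)))
        circ_mirna_designed.setdefault(cid, []).append((mir.id, "body"))

    circ_ids = [cd[0] for cd in circ_defs]
    for i in range(n_junction):
        implant_junction(circ_ids[i], sponge_mirnas[i % n_sponge])
    for i in range(n_body):
        implant_body(circ_ids[n_junction + i], sponge_mirnas[i % n_sponge])
    for i in range(n_decoy):
        cid = circ_ids[n_junction + n_body + i]
        mir = sponge_mirnas[i % n_sponge]
        implant_junction(cid, mir)
        implant_body(cid, mir)
        # a decoy's junction site is not junction-only: reclassify it
        for k, m in enumerate(mre_truth):
            if m.target_id == cid and m.target_class == "circ_junction":
                mre_truth[k] = MreTruth(m.mirna_id, cid, "circ_body_junction_decoy",
                                        m.site_interval)
        decoy_pairs.append((cid, mir.id))

    # 3'UTR implants in genes that host no circRNA
    if len(free_genes) < 2 * n_sponge:
        raise ValueError(
            "configuration infeasible: need >= 2 circ-free genes per sponge "
            f"miRNA for 3'UTR implants ({len(free_genes)} free, "
            f"{2 * n_sponge} needed)"
        )
    utr_genes: dict[str, list[str]] = {}  # mirna -> target gene ids
    gi = 0
    for mir in sponge_mirnas:
        for _ in range(2):
            gene = free_genes[gi % len(free_genes)]
            gi += 1
            sc = seed_complement(mir.sequence)
            T = sum(b - a for a, b in gene.exons)
            u = int(rng.integers(20, config.utr3_length - 27))
            t = T - config.utr3_length + u
            _write_spliced(chrom_seqs[gene.chrom], gene.exons, gene.strand, t, sc)
            mre_truth.append(MreTruth(mir.id, gene.gene_id, "utr3", (u, u + 7)))
            utr_genes.setdefault(mir.id, []).append(gene.gene_id)

    # lncRNA implants: one designed lncRNA per sponge miRNA
    lnc_ids = sorted(lnc_seqs)
    lnc_of_mir: dict[str, str] = {}
    for i, mir in enumerate(sponge_mirnas):
        lid = lnc_ids[i % len(lnc_ids)]
        sc = seed_complement(mir.sequence)
        u = int(rng.integers(50, config.lncrna_length - 57))
        lnc_seqs[lid][u:u + 7] = sc.encode()
        mre_truth.append(MreTruth(mir.id, lid, "lncrna", (u, u + 7)))
        lnc_of_mir[mir.id] = lid

    # --- decontaminate accidental seed matches around BSJs ------------------
    _decontaminate(chrom_seqs, circ_defs, circ_exon_list, circ_strand, circ_chrom,
                   mirnas, mre_truth, rng)

    # --- annotation ---------------------------------------------------------
    annotation: list[FeatureRecord] = []
    utr3_records: list[SequenceRecord] = []
    genome = {c: bytes(s).decode() for c, s in chrom_seqs.items()}
    for gene in genes:
        attrs = {"gene_id": gene.gene_id, "transcript_id": gene.gene_id + ".t1"}
        s0, s1 = gene.span
        annotation.append(FeatureRecord(gene.chrom, "gene", s0, s1, gene.strand, dict(attrs)))
        for a, b in gene.exons:
            annotation.append(FeatureRecord(gene.chrom, "exon", a, b, gene.strand, dict(attrs)))
        if gene.strand == "+":
            ua, ub = gene.exons[-1][1] - config.utr3_length, gene.exons[-1][1]
        else:
            ua, ub = gene.exons[0][0], gene.exons[0][0] + config.utr3_length
        annotation.append(FeatureRecord(gene.chrom, "UTR3", ua, ub, gene.strand, dict(attrs)))
        useq = genome[gene.chrom][ua:ub]
        if gene.strand == "-":
            useq = revcomp(useq)
        utr3_records.append(SequenceRecord(gene.gene_id, useq))

    # --- circ truth with spliced sequences ----------------------------------
    circ_truth = []
    for cid, gene, lo, hi in circ_defs:
        exons = gene.exons[lo:hi + 1]
        s = "".join(genome[gene.chrom][a:b] for a, b in exons)
        if gene.strand == "-":
            s = revcomp(s)
        circ_truth.append(
            CircTruth(cid, gene.chrom, exons[0][0], exons[-1][1], gene.strand,
                      s, gene.gene_id, exons)
        )
    spliced_of = {c.circ_id: c.spliced_sequence for c in circ_truth}

    # --- expression design ---------------------------------------------------
    mult = archetype_multipliers(config.effect_log2fc)
    stages = list(config.stage_labels)
    archetype: dict[str, str] = {}
    designed_axes: list[tuple[str, str, str, str]] = []

    for i, mir in enumerate(sponge_mirnas):
        archetype[mir.id] = "up_ramp" if i % 2 == 0 else "down_ramp"
    for cid, pairs in sorted(circ_mirna_designed.items()):
        archetype[cid] = _MIRROR[archetype[pairs[0][0]]]
    for mir_id, gids in sorted(utr_genes.items()):
        for g in gids:
            archetype[g] = _MIRROR[archetype[mir_id]]
    for mir_id, lid in sorted(lnc_of_mir.items()):
        archetype[lid] = _MIRROR[archetype[mir_id]]

    all_features = {
        "mirna": [m.id for m in mirnas],
        "mrna": [g.gene_id for g in genes],
        "circ": [c.circ_id for c in circ_truth],
        "lncrna": lnc_ids,
    }
    cyc = 0
    for cls in ("mirna", "mrna", "circ", "lncrna"):
        for fid in all_features[cls]:
            if fid not in archetype:
                archetype[fid] = ARCHETYPE_NAMES[cyc % 7]
                cyc += 1

    expression_design = {}
    for cls, feats in all_features.items():
        base = rng.uniform(100, 400, len(feats))
        rows = [base[i] * np.array(mult[archetype[f]]) for i, f in enumerate(feats)]
        expression_design[cls] = pd.DataFrame(rows, index=feats, columns=stages)

    comparisons = [(a, b) for i, a in enumerate(stages) for b in stages[i + 1:]]
    de_truth = {}
    for cls, design in expression_design.items():
        signs = {}
        for a, b in comparisons:
            signs[f"{b}_vs_{a}"] = np.sign(
                np.log2(design[b].values) - np.log2(design[a].values)
            ).astype(int)
        de_truth[cls] = pd.DataFrame(signs, index=design.index)

    # designed ceRNA axes: sponge miRNA links its ceRNAs to its mRNA targets
    for cid, pairs in sorted(circ_mirna_designed.items()):
        for mir_id, _kind in pairs:
            for g in utr_genes.get(mir_id, []):
                designed_axes.append((cid, mir_id, g, "circRNA"))
    for mir_id, lid in sorted(lnc_of_mir.items()):
        for g in utr_genes.get(mir_id, []):
            designed_axes.append((lid, mir_id, g, "lncRNA"))

    # --- count matrices ------------------------------------------------------
    count_matrices = {
        cls: simulate_counts(expression_design[cls], config, rng)
        for cls in ("mirna", "mrna", "circ", "lncrna")
    }

    # --- reads ---------------------------------------------------------------
    samples = config.sample_ids
    gene_tx = {}
    for gene in genes:
        s = "".join(genome[gene.chrom][a:b] for a, b in gene.exons)
        gene_tx[gene.gene_id] = revcomp(s) if gene.strand == "-" else s

    def linear_reads(tag: str) -> list[FastqRead]:
        reads = []
        for gene in genes:
            tx = gene_tx[gene.gene_id]
            n = rng.poisson(config.linear_coverage * len(tx) / config.wholetx_read_length)
            reads.extend(
                _simulate_reads_from(tx, int(n), config.wholetx_read_length, rng,
                                     f"{tag}_{gene.gene_id}",
                                     config.substitution_rate)
            )
        return reads

    read_sets: dict = {"wholetx": {}, "smallrna": {}}
    circ_reads_pooled = []
    for c in circ_truth:
        circ_reads_pooled.extend(
            simulate_bsj_reads(c.spliced_sequence, config.bsj_coverage,
                               config.wholetx_read_length, rng,
                               prefix=f"circseq_{c.circ_id}",
                               sub_rate=config.substitution_rate)
        )
    read_sets["circseq"] = circ_reads_pooled + linear_reads("circseq_lin")

    mirna_counts = count_matrices["mirna"].values
    for sample in samples:
        stage = config.stage_of_sample[sample]
        si = stages.index(stage)
        reads = linear_reads(f"{sample}_lin")
        for c in circ_truth:
            # per-sample BSJ support follows the circ's designed stage profile
            # scaled by bsj_coverage; multipliers are >= 1, so support never
            # drops below bsj_coverage in any sample
            n = round(config.bsj_coverage * mult[archetype[c.circ_id]][si])
            reads.extend(
                simulate_bsj_reads(c.spliced_sequence, n,
                                   config.wholetx_read_length, rng,
                                   prefix=f"{sample}_{c.circ_id}",
                                   sub_rate=config.substitution_rate)
            )
        read_sets["wholetx"][sample] = reads
        sreads = []
        for m in mirnas:
            n = int(mirna_counts.loc[m.id, sample])
            raw = (to_dna(m.sequence) + config.adapter)[: config.smallrna_read_length]
            raw = raw.ljust(config.smallrna_read_length, "A")
            q = "I" * config.smallrna_read_length
            sreads.extend(
                FastqRead(f"{sample}_{m.id}_{i}", raw, q) for i in range(n)
            )
        read_sets["smallrna"][sample] = sreads

    manifest = GroundTruthManifest(
        circ_truth=circ_truth,
        mre_truth=mre_truth,
        expression_design=expression_design,
        de_truth=de_truth,
        cluster_archetype=archetype,
        designed_axes=designed_axes,
        decoy_junction_pairs=decoy_pairs,
    )
    lnc_records = [SequenceRecord(lid, bytes(lnc_seqs[lid]).decode()) for lid in lnc_ids]
    return SyntheticDataset(
        config=config, genome=genome, genes=genes, annotation=annotation,
        mirna_set=mirnas, lncrna_set=lnc_records, utr3_set=utr3_records,
        read_sets=read_sets, count_matrices=count_matrices, manifest=manifest,
    )


def _decontaminate(chrom_seqs, circ_defs, circ_exon_list, circ_strand, circ_chrom,
                   mirnas, mre_truth, rng) -> None:
    """Remove accidental seed-complement matches that would blur ground truth.

    Two guarantees after this pass: (i) the only seed complements crossing
    any circRNA's BSJ are the designed ones; (ii) a designed junction-only
    pair's seed complement never occurs in the linear spliced sequence.
    Edits are single-base substitutions outside every reserved implant
    interval, applied deterministically until a bounded fixpoint.
    """
    seed_of = {m.id: seed_complement(m.sequence) for m in mirnas}
    designed_cross = {}  # circ -> set of seeds allowed to cross
    junction_only = {}  # circ -> set of seeds that must stay absent linearly
    reserved: dict[str, list[tuple[int, int]]] = {c[0]: [] for c in circ_defs}
    for m in mre_truth:
        if m.target_class in ("circ_junction", "circ_body_junction_decoy"):
            designed_cross.setdefault(m.target_id, set()).add(seed_of[m.mirna_id])
            h = 100 - m.site_interval[0]
            L = sum(b - a for a, b in circ_exon_list[m.target_id])
            reserved[m.target_id].extend([(L - h, L), (0, 7 - h)])
            if m.target_class == "circ_junction":
                junction_only.setdefault(m.target_id, set()).add(seed_of[m.mirna_id])
        elif m.target_class == "circ_body":
            reserved[m.target_id].append(m.site_interval)

    def spliced(cid: str) -> str:
        g = chrom_seqs[circ_chrom[cid]]
        s = "".join(bytes(g[a:b]).decode() for a, b in circ_exon_list[cid])
        return revcomp(s) if circ_strand[cid] == "-" else s

    all_seeds = set(seed_of.values())

    def _violations(cid: str, s: str) -> int:
        """Count non-designed seeds crossing the BSJ plus linear occurrences
        of junction-only seeds."""
        allowed = designed_cross.get(cid, set())
        ctx = s[-6:] + s[:6]
        n = sum(
            1 for off in range(6)
            if len(ctx[off:off + 7]) == 7
            and ctx[off:off + 7] in all_seeds
            and ctx[off:off + 7] not in allowed
        )
        for sd in junction_only.get(cid, set()):
            at = s.find(sd)
            while at >= 0:
                n += 1
                at = s.find(sd, at + 1)
        return n

    def _clean(cid: str, s: str) -> bool:
        return _violations(cid, s) == 0

    def mutate(cid: str, pos: int) -> None:
        """Flip spliced position ``pos`` to the base that best reduces the
        violation count; must strictly improve."""
        exons, strand = circ_exon_list[cid], circ_strand[cid]
        g0, _ = _spliced_to_genomic(exons, strand, pos, 1)
        seq = chrom_seqs[circ_chrom[cid]]
        orig = chr(seq[g0]) if strand == "+" else revcomp(chr(seq[g0]))
        before = _violations(cid, spliced(cid))
        best_base, best_n = None, before
        for base in "ACGT":
            if base == orig:
                continue
            _write_spliced(seq, exons, strand, pos, base)
            n = _violations(cid, spliced(cid))
            if n < best_n:
                best_base, best_n = base, n
        if best_base is None:
            _write_spliced(seq, exons, strand, pos, orig)
            raise RuntimeError(f"decontamination failed at {cid}:{pos}")
        _write_spliced(seq, exons, strand, pos, best_base)

    def _free_positions(cid: str, positions: list[int]) -> list[int]:
        return [p for p in positions
                if not any(a <= p < b for a, b in reserved[cid])]

    for _round in range(200):
        dirty = False
        for cid, *_ in circ_defs:
            s = spliced(cid)
            L = len(s)
            if _clean(cid, s):
                continue
            allowed = designed_cross.get(cid, set())
            ctx = s[-6:] + s[:6]
            fixed = False
            for off in range(6):
                k = ctx[off:off + 7]
                if len(k) < 7 or k in allowed or k not in all_seeds:
                    continue
                cand = [(L - 6 + off + d) % L for d in range(7)]
                free = _free_positions(cid, cand)
                if not free:
                    raise RuntimeError(f"no mutable position at {cid} junction")
                mutate(cid, free[0])
                fixed = dirty = True
                break
            if fixed:
                break
            for sd in sorted(junction_only.get(cid, set())):
                at = s.find(sd)
                if at >= 0:
                    free = _free_positions(cid, list(range(at, at + 7)))
                    if not free:
                        raise RuntimeError(f"no mutable position at {cid}:{at}")
                    mutate(cid, free[0])
                    dirty = True
                    break
            if dirty:
                break
        if not dirty:
            return
    raise RuntimeError("decontamination did not converge")


# ---------------------------------------------------------------------------
# on-disk emission


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write every dataset artifact; returns the emitted paths (sorted)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []

    def _p(name: str) -> Path:
        p = out / name
        paths.append(p)
        return p

    write_fasta(
        [SequenceRecord(c, s) for c, s in sorted(ds.genome.items())],
        _p("genome.fa"),
    )
    write_gtf(ds.annotation, _p("annotation.gtf"))
    write_fasta(ds.mirna_set, _p("mirna.fa"))
    write_fasta(ds.lncrna_set, _p("lncrna.fa"))
    write_fasta(ds.utr3_set, _p("utr3.fa"))
    write_fastq(ds.read_sets["circseq"], _p("circseq.fq"))
    for sample in ds.config.sample_ids:
        write_fastq(ds.read_sets["wholetx"][sample], _p(f"wholetx_{sample}.fq"))
        write_fastq(ds.read_sets["smallrna"][sample], _p(f"smallrna_{sample}.fq"))
    for cls, cm in ds.count_matrices.items():
        write_counts(cm, _p(f"counts_{cls}.tsv"))
    write_bed(
        [(c.chrom, c.start, c.end, c.circ_id, 0, c.strand) for c in ds.manifest.circ_truth],
        _p("circ_truth.bed"),
    )
    with open(_p("manifest.tsv"), "w") as fh:
        fh.write("#section\tfields...\n")
        for c in ds.manifest.circ_truth:
            fh.write(f"circ\t{c.circ_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                     f"{c.strand}\t{c.host_gene}\t{c.spliced_sequence}\n")
        for m in ds.manifest.mre_truth:
            fh.write(f"mre\t{m.mirna_id}\t{m.target_id}\t{m.target_class}\t"
                     f"{m.site_interval[0]}\t{m.site_interval[1]}\n")
        for cid, mid in ds.manifest.decoy_junction_pairs:
            fh.write(f"decoy_junction\t{cid}\t{mid}\n")
        for fid, arch in sorted(ds.manifest.cluster_archetype.items()):
            fh.write(f"archetype\t{fid}\t{arch}\n")
        for ax in ds.manifest.designed_axes:
            fh.write("axis\t" + "\t".join(ax) + "\n")
    return sorted(paths)
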