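"""Caller contracts: anchors, detection, credibility filters, sequences."""

import numpy as np
import pytest

from cewhiten import bsjcall
from cewhiten._seq import revcomp, to_dna
from cewhiten.bsjcall import (
    BsjCandidate,
    aggregate_candidates,
    build_index,
    combine_samples,
    detect_bsj,
    extract_anchors,
    merge_dual_evidence,
    spliced_sequence,
)
from cewhiten.iolib import FeatureRecord
from cewhiten.synthio import simulate_bsj_reads


class TestIndex:
    def test_forward_kmer_hit(self, dataset, genome_index):
        kmer = dataset.genome["chr1"][100:120]
        assert ("chr1", 100, "+") in genome_index.lookup(kmer)

    def test_reverse_complement_hit(self, dataset, genome_index):
        kmer = dataset.genome["chr1"][100:120]
        assert ("chr1", 100, "-") in genome_index.lookup(revcomp(kmer))

    def test_random_kmer_absent_matches_full_text_scan(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
        idx = build_index(genome)
        probe = "".join(rng.choice(list("ACGT"), 20))
        scan_hits = genome["chr1"].find(probe) >= 0 or genome["chr1"].find(
            revcomp(probe)) >= 0
        assert bool(idx.lookup(probe)) == scan_hits

    def test_small_k_rejected(self, dataset):
        with pytest.raises(ValueError):
            build_index(dataset.genome, k=8)

    def test_k_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_index({"c": "ACGTACGTACGTACG"}, k=16)


class TestAnchors:
    def test_150nt_read_anchor_coordinates(self):
        read = "A" * 150
        head, tail = extract_anchors(read)
        assert head == read[0:20] and tail == read[130:150]

    def test_40nt_read_anchors_adjacent(self):
        read = "AC" * 20
        head, tail = extract_anchors(read)
        assert head + tail == read

    def test_short_read_skipped(self):
        assert extract_anchors("A" * 39) is None


class TestDetect:
    def test_linear_read_yields_none(self, dataset, genome_index):
        read = dataset.genome["chr1"][5000:5150]
        assert detect_bsj(read, genome_index) is None

    def test_linear_reverse_read_yields_none(self, dataset, genome_index):
        read = revcomp(dataset.genome["chr2"][4000:4150])
        assert detect_bsj(read, genome_index) is None

    def test_manifest_reads_recover_exact_coordinates(self, dataset, genome_index):
        """Every simulated BSJ read yields its circ's exact BSJ (manifest oracle)."""
        rng = np.random.default_rng(42)
        for c in dataset.manifest.circ_truth[:12]:
            reads = simulate_bsj_reads(c.spliced_sequence, 5, 150, rng)
            for r in reads:
                cand = detect_bsj(r.sequence, genome_index)
                assert cand is not None, c.circ_id
                assert cand.key == (c.chrom, c.start, c.end, c.strand)

    def test_mutated_flank_kills_candidate(self, dataset, genome_index):
        """Breaking the acceptor AG removes the GT/AG-consistent breakpoint."""
        c = next(x for x in dataset.manifest.circ_truth if x.strand == "+")
        genome2 = dict(dataset.genome)
        chrom = genome2[c.chrom]
        genome2[c.chrom] = chrom[: c.start - 2] + "AC" + chrom[c.start:]
        idx2 = build_index(genome2)
        rng = np.random.default_rng(0)
        reads = simulate_bsj_reads(c.spliced_sequence, 5, 150, rng)
        assert all(detect_bsj(r.sequence, idx2) is None for r in reads)

    def test_detection_invariant_to_read_order(self, dataset, genome_index):
        reads = list(dataset.read_sets["wholetx"]["D0_1"])
        keys1 = sorted(
            c.key for r in reads
            if (c := detect_bsj(r.sequence, genome_index)) is not None
        )
        keys2 = sorted(
            c.key for r in reversed(reads)
            if (c := detect_bsj(r.sequence, genome_index)) is not None
        )
        assert keys1 == keys2


def _cand(key, sample_reads):
    c = BsjCandidate(*key)
    c.supporting_reads = {s: set(rs) for s, rs in sample_reads.items()}
    return c


class TestCredibilityFilters:
    def test_two_unique_reads_kept(self):
        c = _cand(("chr1", 100, 500, "+"), {"s1": {"AAA", "CCC"}})
        assert aggregate_candidates([c], "s1") == [c]

    def test_identical_copies_count_once(self):
        per_read = [
            _cand(("chr1", 100, 500, "+"), {"s1": {"AAA"}}) for _ in range(3)
        ]
        assert aggregate_candidates(per_read, "s1") == []

    def test_random_candidates_match_brute_force(self):
        """Survivors equal an independent re-implementation of the >=2-unique
        rule over randomized support."""
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(12)]
        cands = []
        for i in range(100):
            key = ("chr1", 1000 + i * 10, 1000 + i * 10 + 400, "+")
            support = {
                s: {f"read{j}" for j in range(rng.integers(0, 4))}
                for s in samples if rng.random() < 0.7
            }
            cands.append(_cand(key, support))
        got = {c.key for c in combine_samples({"all": cands}, min_unique=2)}
        expected = {
            c.key for c in cands
            if any(len(rs) >= 2 for rs in c.supporting_reads.values())
        }
        assert got == expected

    def test_merge_requires_both_libraries(self):
        in_both = _cand(("chr1", 100, 500, "+"), {"s1": {"A", "B"}})
        wtx_only = _cand(("chr1", 900, 1300, "+"), {"s1": {"A", "B"}})
        credible = merge_dual_evidence([in_both], [in_both, wtx_only])
        assert [r.key for r in credible] == [in_both.key]

    def test_one_nt_shift_not_merged(self):
        a = _cand(("chr1", 100, 500, "+"), {"s1": {"A", "B"}})
        b = _cand(("chr1", 101, 500, "+"), {"s1": {"A", "B"}})
        assert merge_dual_evidence([a], [b]) == []

    def test_counts_carried_from_wholetx(self):
        key = ("chr1", 100, 500, "+")
        circseq = _cand(key, {"pool": {"X", "Y", "Z"}})
        wholetx = _cand(key, {"s1": {"A", "B"}, "s2": {"C"}})
        rec = merge_dual_evidence([circseq], [wholetx])[0]
        assert rec.sample_counts == {"s1": 2, "s2": 1}


class TestSplicedSequence:
    def _genome(self):
        rng = np.random.default_rng(5)
        return {"chr1": "".join(rng.choice(list("ACGT"), 1000))}

    def test_single_exon_genomic_substring(self):
        g = self._genome()
        rec = bsjcall.CircRNARecord("chr1", 100, 400, "+")
        assert to_dna(spliced_sequence(rec, [], g)) == g["chr1"][100:400]

    def test_two_exons_join_omits_intron(self):
        g = self._genome()
        ann = [
            FeatureRecord("chr1", "exon", 100, 200, "+", {"gene_id": "g"}),
            FeatureRecord("chr1", "exon", 300, 400, "+", {"gene_id": "g"}),
        ]
        rec = bsjcall.CircRNARecord("chr1", 100, 400, "+")
        s = to_dna(spliced_sequence(rec, ann, g))
        assert s == g["chr1"][100:200] + g["chr1"][300:400]
        assert len(s) == 200

    def test_minus_strand_reverse_complement(self):
        g = self._genome()
        plus = bsjcall.CircRNARecord("chr1", 100, 400, "+")
        minus = bsjcall.CircRNARecord("chr1", 100, 400, "-")
        ann = []
        assert to_dna(spliced_sequence(minus, ann, g)) == revcomp(
            to_dna(spliced_sequence(plus, ann, g))
        )

    def test_boundary_crossing_exon_fails(self):
        g = self._genome()
        ann = [FeatureRecord("chr1", "exon", 50, 150, "+", {"gene_id": "g"})]
        rec = bsjcall.CircRNARecord("chr1", 100, 400, "+")
        with pytest.raises(ValueError, match="outside"):
            spliced_sequence(rec, ann, g)

    def test_matches_manifest_spliced(self, dataset):
        for c in dataset.manifest.circ_truth[:8]:
            rec = bsjcall.CircRNARecord(c.chrom, c.start, c.end, c.strand)
            s = spliced_sequence(rec, dataset.annotation, dataset.genome)
            assert to_dna(s) == c.spliced_sequence


class TestRecovery:
    def test_full_recall_and_precision(self, dataset, credible_circs):
        truth = {(c.chrom, c.start, c.end, c.strand)
                 for c in dataset.manifest.circ_truth}
        found = {r.key for r in credible_circs}
        assert found == truth

    def test_no_candidates_from_linear_only_reads(self, dataset, genome_index):
        linear = [r for r in dataset.read_sets["wholetx"]["D15_1"]
                  if "_lin_" in r.id]
        assert linear
        assert all(
            detect_bsj(r.sequence, genome_index) is None for r in linear
        )
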