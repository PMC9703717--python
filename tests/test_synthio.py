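"""Generator contracts: determinism, implant invariants, count model."""

import hashlib

import numpy as np
import pandas as pd
import pytest

from cewhiten._seq import revcomp
from cewhiten.cenet import spearman
from cewhiten.quantde import nb_wald_de
from cewhiten.synthio import (
    SimulationConfig,
    archetype_multipliers,
    generate_dataset,
    seed_complement,
    simulate_bsj_reads,
    simulate_counts,
    write_dataset,
)


def _dataset_digest(seed: int, tmpdir) -> str:
    ds = generate_dataset(SimulationConfig(seed=seed))
    paths = write_dataset(ds, tmpdir)
    h = hashlib.sha256()
    for p in paths:
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        d1 = _dataset_digest(11, tmp_path / "a")
        d2 = _dataset_digest(11, tmp_path / "b")
        assert d1 == d2

    def test_different_seed_differs(self, tmp_path):
        assert _dataset_digest(11, tmp_path / "a") != _dataset_digest(12, tmp_path / "b")


class TestImplants:
    def test_manifest_lists_exactly_n_circ(self, dataset):
        assert len(dataset.manifest.circ_truth) == dataset.config.n_circ

    def test_genomic_splice_flanks(self, dataset):
        """AG before the start and GT after the end on the annotated strand."""
        for c in dataset.manifest.circ_truth:
            chrom = dataset.genome[c.chrom]
            up = chrom[c.start - 2:c.start]
            down = chrom[c.end:c.end + 2]
            if c.strand == "+":
                assert (up, down) == ("AG", "GT"), c.circ_id
            else:
                # minus strand: donor/acceptor reverse-complemented in place
                assert (revcomp(down), revcomp(up)) == ("AG", "GT"), c.circ_id

    def test_spliced_sequence_matches_genome_exons(self, dataset):
        for c in dataset.manifest.circ_truth[:10]:
            s = "".join(dataset.genome[c.chrom][a:b] for a, b in c.exons)
            if c.strand == "-":
                s = revcomp(s)
            assert s == c.spliced_sequence

    def test_junction_mres_split_across_bsj(self, dataset):
        """Independent substring-scan oracle: the seed complement of every
        junction-only MRE is absent from head and tail alone but present
        across the junction of the doubled sequence."""
        mirna = {m.id: m.sequence for m in dataset.mirna_set}
        spliced = {c.circ_id: c.spliced_sequence for c in dataset.manifest.circ_truth}
        n_junction = 0
        for m in dataset.manifest.mre_truth:
            if m.target_class != "circ_junction":
                continue
            n_junction += 1
            sc = seed_complement(mirna[m.mirna_id])
            s = spliced[m.target_id]
            assert sc not in s  # absent from the whole linear sequence
            doubled = s + s
            window = doubled[len(s) - 6:len(s) + 6]
            assert sc in window  # present only across the junction
        expected = round(
            dataset.config.fraction_junction_only_mres * dataset.config.n_circ
        )
        assert n_junction == expected

    def test_utr3_mres_present_at_recorded_interval(self, dataset):
        mirna = {m.id: m.sequence for m in dataset.mirna_set}
        utr = {r.id: r.sequence for r in dataset.utr3_set}
        checked = 0
        for m in dataset.manifest.mre_truth:
            if m.target_class != "utr3":
                continue
            sc = seed_complement(mirna[m.mirna_id])
            a, b = m.site_interval
            assert utr[m.target_id][a:b] == sc
            checked += 1
        assert checked > 0

    def test_decoy_pairs_have_body_occurrence(self, dataset):
        mirna = {m.id: m.sequence for m in dataset.mirna_set}
        spliced = {c.circ_id: c.spliced_sequence for c in dataset.manifest.circ_truth}
        assert dataset.manifest.decoy_junction_pairs
        for cid, mid in dataset.manifest.decoy_junction_pairs:
            assert seed_complement(mirna[mid]) in spliced[cid]


class TestBsjReads:
    def test_reads_are_windows_of_doubled_sequence_crossing_junction(self):
        rng = np.random.default_rng(0)
        spliced = "".join(rng.choice(list("ACGT"), 500))
        reads = simulate_bsj_reads(spliced, 10, 150, rng)
        doubled = spliced * 2
        assert len(reads) == 10
        for r in reads:
            at = doubled.find(r.sequence)
            assert at >= 0
            # straddles the junction at offset 500 with >= 21 nt on each side
            assert at + 21 <= 500 <= at + 150 - 21

    def test_zero_reads(self):
        assert simulate_bsj_reads("ACGT" * 50, 0, 150, np.random.default_rng(0)) == []

    def test_too_short_without_rolling_fails(self):
        with pytest.raises(ValueError, match="rolling"):
            simulate_bsj_reads("ACGT" * 10, 5, 150, np.random.default_rng(0))

    def test_rolling_mode_produces_junction_reads(self):
        rng = np.random.default_rng(0)
        spliced = "".join(rng.choice(list("ACGT"), 60))
        reads = simulate_bsj_reads(spliced, 5, 150, rng, rolling=True)
        assert all(len(r.sequence) == 150 for r in reads)
        for r in reads:
            assert r.sequence in spliced * 5

    def test_unique_reads_scale_linearly_with_coverage(self):
        """Offsets are drawn without replacement, so doubling coverage
        doubles the unique supporting-read count exactly (while distinct
        offsets remain)."""
        spliced = "".join(np.random.default_rng(3).choice(list("ACGT"), 400))
        n10 = len({r.sequence for r in
                   simulate_bsj_reads(spliced, 10, 150, np.random.default_rng(5))})
        n20 = len({r.sequence for r in
                   simulate_bsj_reads(spliced, 20, 150, np.random.default_rng(5))})
        assert (n10, n20) == (10, 20)


class TestCounts:
    def test_poisson_limit_variance(self):
        """Dispersion -> 0: variance approaches the mean (oracle: mu + a*mu^2)."""
        cfg = SimulationConfig(seed=0, nb_dispersion=1e-10, reps_per_stage=2500)
        design = pd.DataFrame([[100.0] * 4], index=["f"],
                              columns=list(cfg.stage_labels))
        rng = np.random.default_rng(0)
        cm = simulate_counts(design, cfg, rng, size_factors=np.ones(10000))
        draws = cm.values.loc["f"].to_numpy()
        assert abs(draws.var() - 100) / 100 < 0.05

    def test_nb_variance_matches_formula(self):
        cfg = SimulationConfig(seed=0, nb_dispersion=0.2, reps_per_stage=2500)
        design = pd.DataFrame([[100.0] * 4], index=["f"],
                              columns=list(cfg.stage_labels))
        cm = simulate_counts(design, cfg, np.random.default_rng(1),
                             size_factors=np.ones(10000))
        draws = cm.values.loc["f"].to_numpy()
        expected = 100 + 0.2 * 100 ** 2
        assert abs(draws.var() - expected) / expected < 0.10

    def test_mirrored_pairs_anticorrelate_at_low_dispersion(self):
        """Designed sponge pairs reach rho < -0.6 in >= 90% of simulations."""
        cfg = SimulationConfig(seed=0, nb_dispersion=0.05)
        mult = archetype_multipliers(2.0)
        design = pd.DataFrame(
            [np.array(mult["up_ramp"]) * 200, np.array(mult["down_ramp"]) * 200],
            index=["mir", "tgt"], columns=list(cfg.stage_labels),
        )
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(200):
            cm = simulate_counts(design, cfg, rng)
            rho, _ = spearman(cm.values.loc["mir"], cm.values.loc["tgt"])
            hits += rho < -0.6
        assert hits / 200 >= 0.90

    def test_flat_design_rarely_called_de(self):
        """All-stage-equal design: |log2FC| > 1 at p < 0.05 for <= 10%."""
        cfg = SimulationConfig(seed=0, nb_dispersion=0.1)
        design = pd.DataFrame(
            np.full((2000, 4), 150.0), columns=list(cfg.stage_labels),
            index=[f"f{i}" for i in range(2000)],
        )
        cm = simulate_counts(design, cfg, np.random.default_rng(9))
        res = nb_wald_de(cm, cm.samples_of_stage("D0"), cm.samples_of_stage("D15"))
        assert np.mean([r.significant for r in res]) <= 0.10

    def test_non_positive_dispersion_fails(self):
        cfg = SimulationConfig(seed=0)
        cfg.nb_dispersion = 0.0
        design = pd.DataFrame([[10.0] * 4], index=["f"], columns=list(cfg.stage_labels))
        with pytest.raises(ValueError):
            simulate_counts(design, cfg, np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"reps_per_stage": 1}, "reps_per_stage"),
            ({"n_circ": 200, "n_genes": 90}, "n_circ"),
            ({"nb_dispersion": -1}, "nb_dispersion"),
            ({"fraction_junction_only_mres": 1.5}, "fraction"),
        ],
    )
    def test_infeasible_configs_name_the_constraint(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            generate_dataset(SimulationConfig(seed=0, **kwargs))

    def test_sample_layout(self, default_config):
        assert len(default_config.sample_ids) == 12
        assert default_config.stage_of_sample["D85_2"] == "D85"
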