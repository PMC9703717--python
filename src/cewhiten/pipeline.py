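"""File-level pipeline stages and the run-all orchestration.

Each stage reads and writes plain-text artifacts (FASTA/FASTQ/GTF/BED/TSV/
GraphML) so the chain simulate -> detect -> quantify -> de -> target ->
network -> annotate can be driven from the CLI or reproduced piecemeal.
Every run writes a provenance record (parameters, seeds, input checksums —
no wall-clock state), so re-running an identical configuration yields
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import STAGE_LABELS, annotate as annotate_mod, bsjcall, cenet, quantde, synthio, target as target_mod
from ._seq import to_dna
from .iolib import (
    CountMatrix,
    SequenceRecord,
    read_counts,
    read_fasta,
    read_fastq,
    read_gtf,
    write_bed,
    write_counts,
    write_fasta,
    write_network,
)

logger = logging.getLogger(__name__)

_COMPARISONS = [
    (a, b) for i, a in enumerate(STAGE_LABELS) for b in STAGE_LABELS[i + 1:]
]


@dataclass
class PipelineConfig:
    """Validated configuration for the full chain."""

    outdir: str = "cewhiten_run"
    seed: int = 1
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    anchor_len: int = 20
    min_unique_reads: int = 2
    max_span: int = 50_000
    alpha: float = 0.05
    lfc: float = 1.0
    rho_max: float = -0.6
    p_max: float = 0.05
    k: int = 7
    kmeans_seed: int = 0
    min_identity: float = 0.70
    min_total_identity: float = 0.75
    min_cover: int = 100

    def validate(self) -> None:
        problems = []
        if self.anchor_len < 12:
            problems.append(f"anchor_len {self.anchor_len} < 12")
        if self.min_unique_reads < 1:
            problems.append("min_unique_reads must be >= 1")
        if not self.rho_max < 0:
            problems.append(
                f"rho_max {self.rho_max} must be negative (anticorrelation gate)"
            )
        for name, v in (("alpha", self.alpha), ("p_max", self.p_max)):
            if not 0 < v < 1:
                problems.append(f"{name} {v} outside (0, 1)")
        if self.k < 1:
            problems.append("k must be >= 1")
        if not 0 < self.min_identity <= 1 or not 0 < self.min_total_identity <= 1:
            problems.append("identity thresholds must be in (0, 1]")
        if self.max_span < 2 * self.anchor_len:
            problems.append("max_span smaller than twice the anchor length")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: PipelineConfig, outdir: Path) -> synthio.SyntheticDataset:
    sim_cfg = synthio.SimulationConfig(seed=config.seed, **config.simulate)
    ds = synthio.generate_dataset(sim_cfg)
    synthio.write_dataset(ds, outdir / "data")
    return ds


def stage_detect(data_dir: Path, outdir: Path, sample_ids: list[str],
                 anchor_len: int = 20, min_unique: int = 2,
                 max_span: int = 50_000) -> list[bsjcall.CircRNARecord]:
    """Call credible circRNAs from the circRNA-seq and whole-tx libraries."""
    genome = {r.id: r.sequence for r in read_fasta(data_dir / "genome.fa")}
    annotation = read_gtf(data_dir / "annotation.gtf")
    index = bsjcall.build_index(genome, anchor_len)
    per_sample = {}
    for s in sample_ids:
        reads = read_fastq(data_dir / f"wholetx_{s}.fq")
        per_sample[s] = bsjcall.detect_sample(reads, index, s, max_span)
    wholetx = bsjcall.combine_samples(per_sample, min_unique)
    circseq_reads = read_fastq(data_dir / "circseq.fq")
    circseq = bsjcall.combine_samples(
        {"pool": bsjcall.detect_sample(circseq_reads, index, "pool", max_span)},
        min_unique,
    )
    credible = bsjcall.merge_dual_evidence(circseq, wholetx)
    for rec in credible:
        rec.spliced_sequence = bsjcall.spliced_sequence(rec, annotation, genome)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(
        [(r.chrom, r.start, r.end, r.circ_id,
          sum(r.sample_counts.values()), r.strand) for r in credible],
        outdir / "credible_circ.bed",
    )
    counts = pd.DataFrame(
        {s: [r.sample_counts.get(s, 0) for r in credible] for s in sample_ids},
        index=[r.circ_id for r in credible],
    )
    counts.columns = [f"{s}:{s.rsplit('_', 1)[0]}" for s in sample_ids]
    counts.to_csv(outdir / "bsj_counts.tsv", sep="\t", index_label="feature")
    write_fasta(
        [SequenceRecord(r.circ_id, to_dna(r.spliced_sequence)) for r in credible],
        outdir / "circ_spliced.fa",
    )
    return credible


def stage_quantify(data_dir: Path, outdir: Path,
                   sample_ids: list[str]) -> CountMatrix:
    """Trim small-RNA libraries and count exact mature-miRNA matches."""
    matures = read_fasta(data_dir / "mirna.fa")
    policy = quantde.TrimPolicy()
    cols = {}
    stats_rows = []
    for s in sample_ids:
        reads = read_fastq(data_dir / f"smallrna_{s}.fq")
        trimmed, st = quantde.trim_small_rna(reads, policy)
        counts = quantde.count_mirna(trimmed, matures)
        cols[s] = counts.round().astype(int)
        stats_rows.append((s, st.total, st.retained, st.too_short, st.too_long))
    df = pd.DataFrame(cols)
    cm = CountMatrix(df, {s: s.rsplit("_", 1)[0] for s in sample_ids})
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(cm, outdir / "mirna_quant.tsv")
    pd.DataFrame(
        stats_rows, columns=["sample", "total", "retained", "too_short", "too_long"]
    ).to_csv(outdir / "trim_stats.tsv", sep="\t", index=False)
    return cm


def stage_de(count_files: dict[str, Path], outdir: Path, alpha: float = 0.05,
             lfc: float = 1.0) -> dict[str, set[str]]:
    """All pairwise stage comparisons per feature class; returns DE unions."""
    outdir.mkdir(parents=True, exist_ok=True)
    de_features: dict[str, set[str]] = {}
    for cls, path in sorted(count_files.items()):
        cm = read_counts(path)
        sig: set[str] = set()
        for a, b in _COMPARISONS:
            res = quantde.nb_wald_de(
                cm, cm.samples_of_stage(a), cm.samples_of_stage(b), alpha, lfc
            )
            quantde.de_table(res).to_csv(outdir / f"de_{cls}_{b}_vs_{a}.tsv", sep="\t")
            sig.update(r.feature_id for r in res if r.significant)
        de_features[cls] = sig
        with open(outdir / f"de_{cls}_union.txt", "w") as fh:
            fh.write("\n".join(sorted(sig)) + "\n")
    return de_features


def _sites_frame(sites: list[target_mod.TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [s.mirna_id for s in sites],
            "target": [s.target_id for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "score": [s.score for s in sites],
            "spans_junction": [bool(s.spans_junction) for s in sites],
        }
    )


def stage_target(data_dir: Path, detect_dir: Path, outdir: Path,
                 params: target_mod.ScoreParams = target_mod.ScoreParams()) -> pd.DataFrame:
    """Predict miRNA sites on 3'UTRs, lncRNAs and circRNAs (linear + BSJ)."""
    mirnas = [target_mod.MatureMiRNA(r.id, r.sequence)
              for r in read_fasta(data_dir / "mirna.fa")]
    utr3 = read_fasta(data_dir / "utr3.fa")
    lnc = read_fasta(data_dir / "lncrna.fa")
    circ = read_fasta(detect_dir / "circ_spliced.fa")
    frames = []
    for label, targets in (("mrna", utr3), ("lncrna", lnc), ("circ", circ)):
        df = _sites_frame(target_mod.predict_sites(mirnas, targets, params))
        df.insert(0, "target_class", label)
        frames.append(df)
    junction = []
    for rec in circ:
        junction.extend(
            target_mod.junction_sites(rec.id, rec.sequence, mirnas, params)
        )
    jdf = _sites_frame(junction)
    jdf.insert(0, "target_class", "circ_junction")
    frames.append(jdf)
    sites = pd.concat(frames, ignore_index=True)
    outdir.mkdir(parents=True, exist_ok=True)
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    pairs = target_mod.novel_junction_pairs(
        {r.id: r.sequence for r in circ}, mirnas, params
    )
    pd.DataFrame(pairs, columns=["circ_id", "mirna_id"]).to_csv(
        outdir / "novel_junction_pairs.tsv", sep="\t", index=False
    )
    return sites


def stage_network(sites: pd.DataFrame, counts: dict[str, CountMatrix],
                  outdir: Path, rho_max: float = -0.6, p_max: float = 0.05,
                  k: int = 7, kmeans_seed: int = 0,
                  de_features: dict[str, set[str]] | None = None) -> dict:
    """Correlation-gate edges, assemble both triple networks, cluster."""
    outdir.mkdir(parents=True, exist_ok=True)
    mirna_prof = counts["mirna"].values
    edges = {}
    for cls, cerna_cls in (("circ", "circRNA"), ("lncrna", "lncRNA"), ("mrna", "mRNA")):
        sub = sites[sites.target_class.isin(
            [cls, "circ_junction"] if cls == "circ" else [cls])]
        pairs = sorted({(t, m) for t, m in zip(sub.target, sub.mirna)})
        edges[cls] = cenet.corr_filter(pairs, counts[cls].values, mirna_prof,
                                       rho_max, p_max)
        write_network(edges[cls], outdir / f"edges_{cls}.tsv")
    axes_circ = cenet.assemble_triples(edges["circ"], edges["mrna"], "circRNA")
    axes_lnc = cenet.assemble_triples(edges["lncrna"], edges["mrna"], "lncRNA")
    write_network(axes_circ, outdir / "axes_circ.tsv")
    write_network(axes_lnc, outdir / "axes_lnc.tsv")
    overlap = cenet.network_overlap(axes_circ, axes_lnc)
    with open(outdir / "overlap.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"shared_mirnas\t{len(overlap.shared)}\n")
        fh.write(f"fraction_vs_circ\t{overlap.fraction_vs_a:.6g}\n")
        fh.write(f"fraction_vs_lnc\t{overlap.fraction_vs_b:.6g}\n")
        fh.write(f"circ_only\t{','.join(sorted(overlap.only_a))}\n")
        fh.write(f"lnc_only\t{','.join(sorted(overlap.only_b))}\n")
    # stage-selective clustering of DE miRNAs (all miRNAs when too few are DE)
    mir_feats = sorted(de_features.get("mirna", set())) if de_features else []
    prof = mirna_prof.loc[mir_feats] if len(mir_feats) >= k else mirna_prof
    assign = cenet.kmeans_stage_clusters(
        prof, counts["mirna"].stage_of_sample, k=k, seed=kmeans_seed
    )
    rows = [
        (f, c, assign.selective_stage[c])
        for f, c in sorted(assign.cluster_of_feature.items())
    ]
    pd.DataFrame(rows, columns=["feature", "cluster", "selective_stage"]).to_csv(
        outdir / "clusters_mirna.tsv", sep="\t", index=False
    )
    return {"edges": edges, "axes_circ": axes_circ, "axes_lnc": axes_lnc,
            "overlap": overlap, "clusters": assign}


def stage_annotate(detect_dir: Path, data_dir: Path, outdir: Path,
                   axes_circ: list, seed: int,
                   min_identity: float = 0.70, min_total_identity: float = 0.75,
                   min_cover: int = 100,
                   term_map: dict[str, set[str]] | None = None,
                   archetypes: dict[str, str] | None = None) -> None:
    """Conservation of network circRNAs and enrichment of network mRNAs.

    With no user reference database, a synthetic ortholog set is derived
    from half the circRNAs by seeded 15% base substitution — a stand-in
    subject database exercising the threshold rule, labelled as such.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    circ = read_fasta(detect_dir / "circ_spliced.fa")
    rng = np.random.default_rng(seed + 7919)
    subjects = []
    for rec in circ[::2]:
        subjects.append(SequenceRecord(
            "synthetic_ortholog_" + rec.id,
            synthio._mutate(rec.sequence, 0.15, rng),
        ))
    rows = []
    for rec in circ:
        alns = []
        for subj in subjects:
            a = annotate_mod.local_align(rec.sequence, subj.sequence,
                                         rec.id, subj.id)
            if a is not None:
                alns.append(a)
        conserved = annotate_mod.conservation_filter(
            alns, len(rec.sequence), min_identity, min_total_identity, min_cover
        )
        rows.append((rec.id, int(conserved)))
    pd.DataFrame(rows, columns=["circ_id", "conserved"]).to_csv(
        outdir / "conservation_circ.tsv", sep="\t", index=False
    )
    if term_map is None and archetypes is not None:
        universe = {r.id for r in read_fasta(data_dir / "utr3.fa")}
        term_map = {}
        for g in sorted(universe):
            term_map.setdefault("arch_" + archetypes.get(g, "none"), set()).add(g)
    if term_map:
        universe = set().union(*term_map.values())
        gene_set = {a.mrna_id for a in axes_circ} & universe
        res = annotate_mod.ease_enrichment(gene_set, universe, term_map)
        pd.DataFrame(
            [(r.term_id, r.overlap, r.term_size, r.set_size, r.universe_size,
              r.p, r.significant) for r in res],
            columns=["term", "overlap", "term_size", "set_size",
                     "universe_size", "p", "significant"],
        ).to_csv(outdir / "enrichment_mrna.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> Path:
    """Run the full chain; returns the provenance record path."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    ds = stage_simulate(config, out)
    sample_ids = ds.config.sample_ids
    data_dir = out / "data"

    stage_detect(data_dir, out / "detect", sample_ids,
                 config.anchor_len, config.min_unique_reads, config.max_span)
    stage_quantify(data_dir, out / "quantify", sample_ids)
    count_files = {
        "mirna": out / "quantify" / "mirna_quant.tsv",
        "mrna": data_dir / "counts_mrna.tsv",
        "lncrna": data_dir / "counts_lncrna.tsv",
        "circ": out / "detect" / "bsj_counts.tsv",
    }
    de_features = stage_de(count_files, out / "de", config.alpha, config.lfc)
    sites = stage_target(data_dir, out / "detect", out / "target")
    counts = {cls: read_counts(p) for cls, p in count_files.items()}
    net = stage_network(sites, counts, out / "network", config.rho_max,
                        config.p_max, config.k, config.kmeans_seed, de_features)
    stage_annotate(out / "detect", data_dir, out / "annotate",
                   net["axes_circ"], config.seed,
                   config.min_identity, config.min_total_identity,
                   config.min_cover, archetypes=ds.manifest.cluster_archetype)

    provenance = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "input_checksums": {
            p.name: _sha256(p) for p in sorted(data_dir.iterdir())
        },
        "outputs": sorted(
            str(p.relative_to(out))
            for p in out.rglob("*") if p.is_file() and p.name != "provenance.json"
        ),
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return prov_path
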