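"""Correlation-gated ceRNA network assembly and stage-selective clustering.

A ceRNA edge (circRNA/lncRNA/mRNA -- miRNA) requires a predicted binding
site *and* opposite expression across the 12 samples: Spearman rho < -0.6
with p < 0.05 (strict inequalities, two-sided t-approximation). miRNAs
bound on both the ceRNA side and the mRNA side yield (ceRNA, miRNA, mRNA)
triple axes. Expression features are clustered on z-scored per-stage means
with k-means (k = 7), and each cluster is labelled with the stage its
centroid peaks at when the margin over the runner-up exceeds 0.5 z-units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from . import STAGE_LABELS

logger = logging.getLogger(__name__)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided t-approximation p (ties averaged).

    Raises on zero variance in either vector (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class CeRNAEdge:
    source_id: str
    mirna_id: str
    rho: float
    p: float


def corr_filter(candidate_pairs: list[tuple[str, str]],
                profiles: pd.DataFrame,
                mirna_profiles: pd.DataFrame,
                rho_max: float = -0.6, p_max: float = 0.05) -> list[CeRNAEdge]:
    """Keep site-supported pairs with rho < rho_max and p < p_max (strict).

    ``candidate_pairs`` are (source_id, mirna_id) pairs that already have a
    predicted target site; pairs with a missing profile or undefined
    correlation are skipped and logged.
    """
    edges = []
    for source_id, mirna_id in candidate_pairs:
        if source_id not in profiles.index or mirna_id not in mirna_profiles.index:
            logger.debug("skipping pair without profile: %s / %s", source_id, mirna_id)
            continue
        x = profiles.loc[source_id].to_numpy(dtype=float)
        y = mirna_profiles.loc[mirna_id].to_numpy(dtype=float)
        try:
            rho, p = spearman(x, y)
        except ValueError:
            logger.debug("undefined correlation: %s / %s", source_id, mirna_id)
            continue
        if rho < rho_max and p < p_max:
            edges.append(CeRNAEdge(source_id, mirna_id, rho, p))
    return edges


@dataclass(frozen=True)
class TripleAxis:
    cerna_id: str
    mirna_id: str
    mrna_id: str
    cerna_class: str  # circRNA | lncRNA


def assemble_triples(cerna_mirna_edges: list[CeRNAEdge],
                     mirna_mrna_edges: list[CeRNAEdge],
                     cerna_class: str) -> list[TripleAxis]:
    """One axis per (ceRNA, miRNA, mRNA) sharing the miRNA.

    The axis count equals sum over shared miRNAs of
    ceRNA-degree x mRNA-degree.
    """
    by_mirna: dict[str, list[str]] = {}
    for e in mirna_mrna_edges:
        by_mirna.setdefault(e.mirna_id, []).append(e.source_id)
    axes = []
    for e in cerna_mirna_edges:
        for mrna in by_mirna.get(e.mirna_id, []):
            axes.append(TripleAxis(e.source_id, e.mirna_id, mrna, cerna_class))
    return sorted(axes, key=lambda a: (a.cerna_id, a.mirna_id, a.mrna_id))


# ---------------------------------------------------------------------------
# stage-selective clustering


@dataclass
class ClusterAssignment:
    cluster_of_feature: dict[str, int]  # feature -> 1..k
    selective_stage: dict[int, str]  # cluster -> stage label or "none"
    centroids: pd.DataFrame  # k x stages, z-units


def stage_mean_zscores(profiles: pd.DataFrame,
                       stage_of_sample: dict[str, str]) -> pd.DataFrame:
    """Per-feature z-scores of per-stage mean expression (the cluster space)."""
    stages = []
    for s in profiles.columns:
        st = stage_of_sample[s]
        if st not in stages:
            stages.append(st)
    means = pd.DataFrame(
        {st: profiles[[c for c in profiles.columns if stage_of_sample[c] == st]]
         .mean(axis=1) for st in stages}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    sd = sd.replace(0, 1.0)
    return means.sub(mu, axis=0).div(sd, axis=0)


def kmeans_stage_clusters(profiles: pd.DataFrame,
                          stage_of_sample: dict[str, str],
                          k: int = 7, seed: int = 0,
                          margin: float = 0.5) -> ClusterAssignment:
    """k-means over z-scored stage means with stage-selectivity labelling.

    k-means++ initialization, 50 restarts, Euclidean distance, fixed seed.
    A cluster is selective for the stage its centroid peaks at when the
    margin over the runner-up exceeds ``margin`` z-units; several clusters
    may share a selective stage.
    """
    if len(profiles) < k:
        raise ValueError(f"{len(profiles)} features < k = {k}")
    z = stage_mean_zscores(profiles, stage_of_sample)
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=z.columns,
                             index=range(1, k + 1))
    selective = {}
    for ci in range(k):
        c = km.cluster_centers_[ci]
        order = np.argsort(c)[::-1]
        if k == 1 or len(c) < 2 or c[order[0]] - c[order[1]] > margin:
            selective[ci + 1] = z.columns[order[0]]
        else:
            selective[ci + 1] = "none"
    return ClusterAssignment(
        cluster_of_feature={f: int(l) + 1 for f, l in zip(profiles.index, labels)},
        selective_stage=selective,
        centroids=centroids,
    )


def selective_stage_of_centroid(centroid, stage_labels=STAGE_LABELS,
                                margin: float = 0.5) -> str:
    """Stage-selectivity rule on one centroid z-profile."""
    c = np.asarray(centroid, dtype=float)
    order = np.argsort(c)[::-1]
    if len(c) >= 2 and c[order[0]] - c[order[1]] <= margin:
        return "none"
    return stage_labels[order[0]]


# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    shared: set[str]
    fraction_vs_a: float
    fraction_vs_b: float
    only_a: set[str]
    only_b: set[str]


def network_overlap(axes_a: list[TripleAxis], axes_b: list[TripleAxis]) -> OverlapReport:
    """miRNA-set overlap between two triple networks."""
    mir_a = {a.mirna_id for a in axes_a}
    mir_b = {a.mirna_id for a in axes_b}
    shared = mir_a & mir_b
    return OverlapReport(
        shared=shared,
        fraction_vs_a=len(shared) / len(mir_a) if mir_a else 0.0,
        fraction_vs_b=len(shared) / len(mir_b) if mir_b else 0.0,
        only_a=mir_a - shared,
        only_b=mir_b - shared,
    )
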