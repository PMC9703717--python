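"""Small-RNA quantification and differential expression.

The trimming policy mirrors a strict cutadapt invocation (exact 3' adapter
match, >= 3 nt overlap, retained length 18-30 nt). Counting is exact-match
against the mature miRNA set with T/U equivalence and fractional assignment
of multi-matching reads.

Differential expression is a deliberately simplified DESeq2-like procedure:
median-of-ratios size factors, per-feature method-of-moments dispersion,
and a Wald test on log2 fold change via the delta method. It preserves the
decision rule (p < 0.05 and |log2FC| > 1) while remaining fully specified;
numerical agreement with DESeq2 is not claimed. BH-adjusted q-values are
emitted alongside but the significance call uses raw p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import to_dna
from .iolib import CountMatrix, FastqRead

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"


@dataclass(frozen=True)
class TrimPolicy:
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 30
    min_overlap: int = 3

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class TrimStats:
    total: int = 0
    retained: int = 0
    too_short: int = 0
    too_long: int = 0


def trim_read(seq: str, policy: TrimPolicy) -> str:
    """Remove the 3' adapter at its leftmost exact occurrence.

    Suffix overlaps count when at least ``min_overlap`` adapter bases match
    at the read end; an untrimmable read is returned unchanged.
    """
    n, a = len(seq), policy.adapter
    for i in range(n):
        chunk = min(len(a), n - i)
        if chunk < policy.min_overlap:
            break
        if seq[i:i + chunk] == a[:chunk]:
            return seq[:i]
    return seq


def trim_small_rna(reads: list[FastqRead], policy: TrimPolicy = TrimPolicy()
                   ) -> tuple[list[FastqRead], TrimStats]:
    """Trim and length-filter single-end small-RNA reads."""
    stats_ = TrimStats()
    out = []
    for r in reads:
        stats_.total += 1
        trimmed = trim_read(r.sequence, policy)
        if len(trimmed) < policy.min_len:
            stats_.too_short += 1
        elif len(trimmed) > policy.max_len:
            stats_.too_long += 1
        else:
            stats_.retained += 1
            out.append(FastqRead(r.id, trimmed, r.quality[: len(trimmed)]))
    return out, stats_


def count_mirna(reads: list[FastqRead], mature_set: list) -> pd.Series:
    """Exact-match counts per mature miRNA (T/U equivalent, mature orientation).

    Multi-matching reads (identical mature sequences would be an input
    error; equal-length distinct matches cannot co-occur under exact
    matching, but the fractional 1/n rule is applied for safety).
    """
    by_id: dict[str, str] = {}
    by_seq: dict[str, list[str]] = {}
    for m in mature_set:
        if m.id in by_id:
            raise ValueError(f"duplicate mature miRNA id {m.id!r}")
        by_id[m.id] = to_dna(m.sequence).upper()
    for mid, seq in by_id.items():
        if seq in by_seq:
            raise ValueError(
                f"duplicate mature sequence shared by {by_seq[seq][0]!r} and {mid!r}"
            )
        by_seq[seq] = [mid]
    counts = pd.Series(0.0, index=list(by_id))
    for r in reads:
        hits = by_seq.get(to_dna(r.sequence).upper())
        if hits:
            for mid in hits:
                counts[mid] += 1.0 / len(hits)
    return counts


# ---------------------------------------------------------------------------
# normalization and DE


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    The reference is the per-feature geometric mean over zero-free features;
    fails when no feature is zero-free.
    """
    df = counts.values if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; supply a "
            "pseudo-reference or filter samples"
        )
    sub = mat[nonzero]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=df.columns)


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    base_mean_a: float
    base_mean_b: float
    log2fc: float
    p_value: float
    padj: float
    significant: bool


def nb_wald_de(counts: CountMatrix, group_a: list[str], group_b: list[str],
               alpha: float = 0.05, lfc_threshold: float = 1.0,
               pseudocount: float = 0.5,
               factors: pd.Series | None = None) -> list[DEResult]:
    """Simplified negative-binomial Wald test of group B over group A.

    Normalized group means; ``log2fc = log2((meanB + c) / (meanA + c))``
    with pseudo-count ``c``; per-feature dispersion by pooled within-group
    method of moments, moderated by flooring at the across-feature mean
    dispersion (raw per-feature moment estimates at n = 3 are so noisy
    that the Wald test is badly anti-conservative without moderation) and
    at 1e-8; Wald statistic via the delta method with a two-sided normal
    p-value. Significant iff ``p < alpha`` and ``|log2fc| > lfc_threshold``.

    ``factors`` overrides median-of-ratios size-factor estimation (e.g.
    all-ones for libraries known to be equal-depth).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    df = counts.values[group_a + group_b].astype(float)
    if (df[group_a].sum(axis=0) == 0).all() or (df[group_b].sum(axis=0) == 0).all():
        raise ValueError("a group consists entirely of all-zero libraries")
    sf = size_factors(counts) if factors is None else factors
    norm = df / sf[df.columns]
    a, b = norm[group_a].to_numpy(), norm[group_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # pooled within-group method-of-moments dispersion
    var_pool = (a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    mean_pool = (mean_a * na + mean_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_pool - mean_pool) / np.where(mean_pool > 0, mean_pool**2, 1.0)
    disp = np.nan_to_num(disp)
    disp = np.clip(np.maximum(disp, disp.mean()), 1e-8, None)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    var_a = (mean_a + disp * mean_a**2) / na
    var_b = (mean_b + disp * mean_b**2) / nb
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_a / np.maximum(mean_a + pseudocount, 1e-12) ** 2
        + var_b / np.maximum(mean_b + pseudocount, 1e-12) ** 2
    ) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    out = []
    for i, fid in enumerate(df.index):
        out.append(
            DEResult(
                fid, float(mean_a[i]), float(mean_b[i]), float(log2fc[i]),
                float(p[i]), float(padj[i]),
                bool(p[i] < alpha and abs(log2fc[i]) > lfc_threshold),
            )
        )
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "baseMeanA": [r.base_mean_a for r in results],
            "baseMeanB": [r.base_mean_b for r in results],
            "log2FC": [r.log2fc for r in results],
            "pvalue": [r.p_value for r in results],
            "padj": [r.padj for r in results],
            "significant": [r.significant for r in results],
        }
    ).set_index("feature")


# ---------------------------------------------------------------------------
# RT-qPCR relative quantification


def delta_delta_ct(cq_target: dict[str, list[float]],
                   cq_reference: dict[str, list[float]],
                   calibrator_group: str) -> dict[str, float]:
    """Relative expression per group by the 2^-ddCt method.

    dCt = Cq(target) - Cq(reference) per matched replicate; ddCt subtracts
    the calibrator group's mean dCt; relative expression is 2**-ddCt, so the
    calibrator is exactly 1.
    """
    if calibrator_group not in cq_target:
        raise ValueError(f"calibrator group {calibrator_group!r} missing")
    d_ct: dict[str, float] = {}
    for group, targets in cq_target.items():
        refs = cq_reference.get(group)
        if refs is None or len(refs) != len(targets):
            raise ValueError(f"group {group!r}: missing or unmatched reference Cq values")
        d_ct[group] = float(np.mean(np.asarray(targets) - np.asarray(refs)))
    cal = d_ct[calibrator_group]
    return {g: float(2.0 ** -(d - cal)) for g, d in d_ct.items()}
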