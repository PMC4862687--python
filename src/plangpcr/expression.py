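"""Biotype-comparison expression screen.

Reads are mapped to the receptor gene set under minimum similarity and
coverage fractions (default 0.9/0.9, inclusive), expression is
quantified as RPKM, the two biotypes (sexual vs asexual) are compared
with a weighted t-test on per-replicate read proportions, p-values are
FDR-corrected, and fold changes are corrected for an abundance-dependent
composition bias by subtracting a linear trend of log2 fold change
against log10 RPKM fitted on the middle 75% of significant genes.  A
zero denominator in the fold-change ratio is encoded by a sentinel ratio
(default 10000, i.e. log2 value 13.29).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SequenceRecord

#: ratio substituted when the fold-change denominator is zero
SENTINEL_RATIO = 10000.0

#: the fixed trend coefficients of the published normalization preset
PRESET_TREND_SLOPE = 0.411
PRESET_TREND_INTERCEPT = 2.29


@dataclass
class CountTable:
    genes: list[str]
    gene_lengths: dict[str, int]  # nt
    samples: list[str]
    groups: dict[str, str]  # sample -> "sexual" | "asexual"
    counts: pd.DataFrame  # genes x samples, non-negative
    total_mapped: dict[str, float]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.samples:
            if self.total_mapped[s] < self.counts[s].sum() - 1e-6:
                raise ValueError(f"total_mapped[{s}] below column sum")
        for g in self.genes:
            if self.gene_lengths[g] <= 0:
                raise ValueError(f"non-positive length for gene {g}")

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class TrendFit:
    slope: float
    intercept: float
    n_used: int
    x_range_used: tuple[float, float]


# ---------------------------------------------------------------------------
# read mapping


def _kmer_index(references: Sequence[SequenceRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ri, ref in enumerate(references):
        s = ref.seq
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((ri, pos))
    return index


def map_reads(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    groups: dict[str, str] | None = None,
    min_similarity: float = 0.9,
    min_coverage: float = 0.9,
    k: int = 15,
    sample_of_read=None,
) -> CountTable:
    """Map reads to reference genes by k-mer-seeded ungapped alignment.

    For each read, every exact k-mer seed defines a diagonal on a
    reference; the read is compared ungapped along the best diagonal.
    similarity = identities / aligned length, coverage = aligned length /
    read length; a read counts iff both reach their thresholds
    (inclusive).  Multi-mapping reads go to the best-similarity gene;
    exact ties split the count fractionally.

    ``sample_of_read`` maps a read id to its sample name (default: the
    prefix of the read id before the last "/").  ``groups`` maps samples
    to biotypes; unknown samples default to "sexual".
    """
    if not references:
        raise ValueError("empty reference set")
    if sample_of_read is None:
        sample_of_read = lambda rid: rid.rsplit("/", 1)[0]
    index = _kmer_index(references, k)

    per_sample: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    n_ref = len(references)
    for read in reads:
        sample = sample_of_read(read.id)
        if sample not in per_sample:
            per_sample[sample] = np.zeros(n_ref)
            totals[sample] = 0.0
        totals[sample] += 1.0
        rseq = read.seq
        rlen = len(rseq)
        # candidate (reference, offset) diagonals from seed matches
        diagonals: set[tuple[int, int]] = set()
        for pos in range(0, rlen - k + 1):
            for ri, rpos in index.get(rseq[pos : pos + k], ()):  # offset of read start
                diagonals.add((ri, rpos - pos))
        best_sim = -1.0
        best_refs: list[int] = []
        for ri, off in diagonals:
            ref = references[ri].seq
            lo = max(0, -off)
            hi = min(rlen, len(ref) - off)
            aligned = hi - lo
            if aligned <= 0:
                continue
            ident = sum(
                1 for t in range(lo, hi) if rseq[t] == ref[off + t]
            )
            sim = ident / aligned
            cov = aligned / rlen
            if sim >= min_similarity and cov >= min_coverage:
                if sim > best_sim + 1e-12:
                    best_sim = sim
                    best_refs = [ri]
                elif abs(sim - best_sim) <= 1e-12 and ri not in best_refs:
                    best_refs.append(ri)
        if best_refs:
            share = 1.0 / len(best_refs)
            for ri in best_refs:
                per_sample[sample][ri] += share

    samples = sorted(per_sample)
    counts = pd.DataFrame(
        {s: per_sample[s] for s in samples}, index=[r.id for r in references]
    )
    groups = groups or {}
    return CountTable(
        genes=[r.id for r in references],
        gene_lengths={r.id: len(r.seq) for r in references},
        samples=samples,
        groups={s: groups.get(s, "sexual") for s in samples},
        counts=counts,
        total_mapped=totals,
    )


# ---------------------------------------------------------------------------
# quantification


def rpkm(counts: float, gene_length_nt: float, total_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_nt <= 0:
        raise ValueError("gene length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if counts < 0:
        raise ValueError("counts must be non-negative")
    return 1e9 * counts / (gene_length_nt * total_mapped)


def rpkm_table(table: CountTable) -> pd.DataFrame:
    lengths = np.array([table.gene_lengths[g] for g in table.genes], dtype=float)
    out = {}
    for s in table.samples:
        out[s] = 1e9 * table.counts[s].to_numpy() / (lengths * table.total_mapped[s])
    return pd.DataFrame(out, index=table.genes)


def fold_change(
    mean_rpkm_sex: float, mean_rpkm_asex: float, sentinel_ratio: float = SENTINEL_RATIO
) -> tuple[float, bool]:
    """log2 sexual/asexual RPKM ratio with the division-by-zero sentinel.

    Returns ``(log2fc, defined)``; both-zero genes come back undefined
    (log2fc NaN) and are excluded downstream.
    """
    if mean_rpkm_sex < 0 or mean_rpkm_asex < 0:
        raise ValueError("RPKM means must be non-negative")
    if mean_rpkm_sex == 0 and mean_rpkm_asex == 0:
        return float("nan"), False
    if mean_rpkm_asex == 0:
        return math.log2(sentinel_ratio), True
    if mean_rpkm_sex == 0:
        return -math.log2(sentinel_ratio), True
    return math.log2(mean_rpkm_sex / mean_rpkm_asex), True


# ---------------------------------------------------------------------------
# differential test


def _weighted_group_stats(props: np.ndarray, totals: np.ndarray) -> tuple[float, float]:
    """Weighted mean of proportions and its variance estimate.

    Weights are the per-replicate totals (inverse-variance weighting for
    binomial sampling); the variance of the weighted mean uses the
    between-replicate scatter, so biological overdispersion is respected.
    """
    w = totals / totals.sum()
    mean = float((w * props).sum())
    m = len(props)
    var = float((w**2 * (props - mean) ** 2).sum()) * m / (m - 1)
    return mean, var


def de_test(table: CountTable) -> pd.DataFrame:
    """Per-gene two-sided weighted t-test on per-replicate read proportions.

    The statistic compares group means of count/total proportions with
    per-replicate binomial-variance weights and between-replicate variance
    estimation (a weighted two-sample t in the style of count-proportion
    tests for replicated libraries); degrees of freedom by Satterthwaite.
    Genes with zero counts everywhere get p = 1 and are flagged.
    """
    sex = table.group_samples("sexual")
    asex = table.group_samples("asexual")
    if len(sex) < 2 or len(asex) < 2:
        raise ValueError("need >= 2 replicates per group")
    for s in table.samples:
        if table.total_mapped[s] <= 0:
            raise ValueError(f"sample {s} has zero total mapped reads")

    tot_s = np.array([table.total_mapped[s] for s in sex])
    tot_a = np.array([table.total_mapped[s] for s in asex])
    p_values = np.ones(len(table.genes))
    stat = np.zeros(len(table.genes))
    flagged = np.zeros(len(table.genes), dtype=bool)
    counts = table.counts
    for gi, gene in enumerate(table.genes):
        cs = counts.loc[gene, sex].to_numpy(dtype=float)
        ca = counts.loc[gene, asex].to_numpy(dtype=float)
        if cs.sum() == 0 and ca.sum() == 0:
            flagged[gi] = True
            continue
        ms, vs = _weighted_group_stats(cs / tot_s, tot_s)
        ma, va = _weighted_group_stats(ca / tot_a, tot_a)
        if vs + va == 0:
            p_values[gi] = 1.0 if ms == ma else 0.0
            continue
        t = (ms - ma) / math.sqrt(vs + va)
        df_num = (vs + va) ** 2
        df_den = vs**2 / (len(sex) - 1) + va**2 / (len(asex) - 1)
        df = df_num / df_den if df_den > 0 else len(sex) + len(asex) - 2
        stat[gi] = t
        p_values[gi] = 2.0 * stats.t.sf(abs(t), df)
    return pd.DataFrame(
        {"statistic": stat, "p_value": p_values, "all_zero": flagged},
        index=table.genes,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# trend normalization


def fit_trend(
    points: Sequence[tuple[float, float]], middle_fraction: float = 0.75
) -> TrendFit:
    """OLS trend of log2 fold change against log10 RPKM on the middle points.

    Points are sorted by x; ``(1 - middle_fraction)/2`` of them are
    discarded from each end (count rounded down per side) before ordinary
    least squares.
    """
    if not (0.0 < middle_fraction <= 1.0):
        raise ValueError("middle_fraction must lie in (0, 1]")
    pts = sorted(points, key=lambda t: t[0])
    n = len(pts)
    drop = int(n * (1.0 - middle_fraction) / 2.0)
    kept = pts[drop : n - drop] if drop else pts
    if len(kept) < 3:
        raise ValueError("fewer than 3 points retained for the trend fit")
    x = np.array([p[0] for p in kept])
    y = np.array([p[1] for p in kept])
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        n_used=len(kept),
        x_range_used=(float(x.min()), float(x.max())),
    )


def normalize_fc(
    log2fc: float,
    rpkm_value: float,
    slope: float = PRESET_TREND_SLOPE,
    intercept: float = PRESET_TREND_INTERCEPT,
) -> float:
    """Abundance-bias-corrected fold change.

    normalized log2FC = log2FC - slope * log10(RPKM) + intercept.  The
    defaults are the published preset coefficients (0.411, 2.29); fitted
    coefficients from :func:`fit_trend` can be substituted, with the
    intercept applied under the same sign convention (for a fitted trend
    y = a*x + b the correction subtracting the trend uses slope=a,
    intercept=-b).
    """
    if rpkm_value <= 0:
        raise ValueError("RPKM must be positive for trend normalization")
    return log2fc - slope * math.log10(rpkm_value) + intercept


def trend_coefficients(fit: TrendFit) -> tuple[float, float]:
    """Convert a fitted trend into normalize_fc (slope, intercept) arguments."""
    return fit.slope, -fit.intercept


# ---------------------------------------------------------------------------
# screen assembly


def expression_screen(
    table: CountTable,
    middle_fraction: float = 0.75,
    sentinel_ratio: float = SENTINEL_RATIO,
    use_preset_trend: bool = False,
) -> pd.DataFrame:
    """Full screen: RPKM -> fold change -> test -> BH -> trend normalization.

    The trend is fitted on significant genes only (q < 0.05) with defined,
    non-sentinel fold changes, as positive-RPKM points.  Returns one row
    per gene with raw and normalized fold change, p and q values.
    """
    r = rpkm_table(table)
    sex = table.group_samples("sexual")
    asex = table.group_samples("asexual")
    mean_sex = r[sex].mean(axis=1)
    mean_asex = r[asex].mean(axis=1)
    max_control = r.max(axis=1)

    fc = np.empty(len(table.genes))
    defined = np.empty(len(table.genes), dtype=bool)
    for i, g in enumerate(table.genes):
        fc[i], defined[i] = fold_change(mean_sex[g], mean_asex[g], sentinel_ratio)

    tests = de_test(table)
    q = bh_fdr(tests["p_value"].to_numpy())

    out = pd.DataFrame(
        {
            "mean_rpkm_sexual": mean_sex,
            "mean_rpkm_asexual": mean_asex,
            "max_control_rpkm": max_control,
            "log2fc_raw": fc,
            "fc_defined": defined,
            "p_value": tests["p_value"].to_numpy(),
            "q_value": q,
        },
        index=table.genes,
    )

    sentinel_l2 = math.log2(sentinel_ratio)
    sig = (out["q_value"] < 0.05) & out["fc_defined"] & (out["max_control_rpkm"] > 0)
    trend_pts = [
        (math.log10(row.max_control_rpkm), row.log2fc_raw)
        for row in out[sig].itertuples()
        if abs(row.log2fc_raw) < sentinel_l2
    ]
    if use_preset_trend:
        slope, intercept = PRESET_TREND_SLOPE, PRESET_TREND_INTERCEPT
        fit = None
    elif len(trend_pts) < 3:
        slope, intercept = 0.0, 0.0  # no usable trend information: identity
        fit = None
    else:
        fit = fit_trend(trend_pts, middle_fraction)
        slope, intercept = trend_coefficients(fit)
    norm = np.full(len(table.genes), np.nan)
    for i, g in enumerate(table.genes):
        if defined[i] and max_control[g] > 0:
            norm[i] = normalize_fc(fc[i], max_control[g], slope, intercept)
    out["log2fc_normalized"] = norm
    out.attrs["trend_fit"] = fit
    out.attrs["trend_slope"] = slope
    out.attrs["trend_intercept"] = intercept
    return out


def select_enriched(
    rows: pd.DataFrame,
    min_fold: float = 4.0,
    alpha: float = 0.05,
    use_normalized: bool = True,
) -> list[str]:
    """Sexually enriched genes: q < alpha (strict) and fold >= min_fold (inclusive).

    Selection applies to the normalized fold change by default; set
    ``use_normalized=False`` to select on the raw fold change.
    """
    col = "log2fc_normalized" if use_normalized else "log2fc_raw"
    thr = math.log2(min_fold)
    mask = (rows["q_value"] < alpha) & (rows[col] >= thr) & rows["fc_defined"]
    return list(rows.index[mask.fillna(False)])
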