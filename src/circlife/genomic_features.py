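"""Genomic features of circRNAs and their host genes, and nonparametric
comparison of those features across trajectory clusters.

Features per circRNA: mature length, total exonic length and exon span
(member exons fully contained in the circle interval), GC content of the
mature (concatenated exonic) sequence and the unweighted mean per-exon GC,
flanking intron lengths and GC (5'/3' in transcript orientation, so the
labels swap on the minus strand), host-gene exon statistics, and mean
normalized host mRNA expression.

Cluster comparison: Kruskal-Wallis per feature; for features with p < 0.05,
Dunn's pairwise rank test with Benjamini-Hochberg adjustment across the
pairs of one feature, plus the signed Z tile summary.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CircAnnotation, CountMatrix, GeneModel

__all__ = [
    "gc_content",
    "extract_features",
    "compare_clusters",
    "zscore_summary",
    "dunn_test",
    "significance_stars",
]

MIN_SPAN_NT = 20

FEATURE_COLUMNS = [
    "length_circRNA", "genomic_span", "total_exonic_length", "exon_span",
    "circ_gc", "circ_avg_exonic_gc",
    "upstream_intron_length", "downstream_intron_length",
    "upstream_intron_gc", "downstream_intron_gc",
    "host_mean_exon_length", "host_total_exons", "linear_average_expression",
]


def gc_content(seq: str) -> float:
    """Fraction of G/C bases (case-insensitive); NaN for empty sequences."""
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def _flank_introns(
    gene: GeneModel, circ: CircAnnotation
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Introns abutting the circle boundaries, in transcript orientation.

    Genomically, the left flank is the intron ending at circ.start and the
    right flank the intron starting at circ.end; on the minus strand the
    upstream/downstream roles swap.
    """
    left = next((iv for iv in gene.introns if iv[1] == circ.start), None)
    right = next((iv for iv in gene.introns if iv[0] == circ.end), None)
    if circ.strand == "+":
        return left, right
    return right, left


def extract_features(
    annotations: list[CircAnnotation],
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    linear_expression: CountMatrix | None = None,
) -> pd.DataFrame:
    """Per-circRNA genomic feature table.

    circRNAs with sentinel host labels or genomic span < 20 nt are excluded
    up front.  A circle boundary that does not coincide with a host exon
    boundary yields NA flanks with a warning rather than an error.
    """
    lin_mean = (
        linear_expression.values.mean(axis=1) if linear_expression is not None else None
    )
    rows = {}
    for circ in annotations:
        if circ.has_sentinel_host or circ.span < MIN_SPAN_NT:
            continue
        gene = genes.get(circ.host_gene)
        if gene is None:
            warnings.warn(f"{circ.circ_id}: host gene {circ.host_gene!r} not in gene models")
            continue
        chrom_seq = genome[circ.chrom]

        member = [e for e in gene.exons if e[0] >= circ.start and e[1] <= circ.end]
        partial = [
            e for e in gene.exons
            if e[1] > circ.start and e[0] < circ.end and e not in member
        ]
        if partial:
            warnings.warn(f"{circ.circ_id}: {len(partial)} exon(s) partially overlap the circle")
        if member:
            mature_seq = "".join(chrom_seq[s:e] for s, e in member)
            exon_gcs = [gc_content(chrom_seq[s:e]) for s, e in member]
            avg_exonic_gc = float(np.mean(exon_gcs))
        else:
            mature_seq = chrom_seq[circ.start:circ.end]
            avg_exonic_gc = float("nan")

        upstream, downstream = _flank_introns(gene, circ)
        if upstream is None or downstream is None:
            warnings.warn(
                f"{circ.circ_id}: circle boundary without a flanking intron "
                "(first/last exon or unannotated boundary); NA flank"
            )

        def _len(iv):
            return iv[1] - iv[0] if iv else np.nan

        def _gc(iv):
            return gc_content(chrom_seq[iv[0]:iv[1]]) if iv else np.nan

        rows[circ.circ_id] = {
            "length_circRNA": circ.length_nt,
            "genomic_span": circ.span,
            "total_exonic_length": sum(e - s for s, e in member),
            "exon_span": len(member),
            "circ_gc": gc_content(mature_seq),
            "circ_avg_exonic_gc": avg_exonic_gc,
            "upstream_intron_length": _len(upstream),
            "downstream_intron_length": _len(downstream),
            "upstream_intron_gc": _gc(upstream),
            "downstream_intron_gc": _gc(downstream),
            "host_mean_exon_length": gene.mean_exon_length,
            "host_total_exons": gene.n_exons,
            "linear_average_expression": (
                float(lin_mean.get(circ.host_gene, np.nan)) if lin_mean is not None else np.nan
            ),
        }
    out = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_COLUMNS)
    out.index.name = "circ_id"
    return out


# ---------------------------------------------------------------------------
# cluster comparison
# ---------------------------------------------------------------------------


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def dunn_test(groups: dict, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise rank comparison after Kruskal-Wallis.

    Z for clusters (i, j) is the difference of mean ranks over the pooled
    sample, standardized by sqrt((N(N+1)/12 - tie correction)(1/n_i + 1/n_j)).
    P-values are two-sided and adjusted across all pairs with the requested
    method (Benjamini-Hochberg by default).
    """
    from statsmodels.stats.multitest import multipletests

    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        n_g = len(groups[g])
        mean_rank[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for gi, gj in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
        rows.append({"cluster_i": gi, "cluster_j": gj, "dunn_z": float(z),
                     "p": float(2.0 * stats.norm.sf(abs(z)))})
    out = pd.DataFrame(rows)
    out["dunn_p_adj"] = multipletests(out["p"], method=adjust)[1]
    out["stars"] = out["dunn_p_adj"].map(significance_stars)
    return out.drop(columns="p")


def compare_clusters(
    features: pd.DataFrame,
    assignments: pd.Series,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Kruskal-Wallis per feature across clusters, with Dunn post-hocs.

    Returns a long frame: one row per feature for the KW test (pair columns
    NA) and, for features with kw_p < ``alpha``, one row per cluster pair
    with the Dunn Z and adjusted p.  Constant features get kw_p = NA.
    """
    shared = features.index.intersection(assignments.index)
    feats = features.loc[shared]
    clusters = assignments.loc[shared]
    sizes = clusters.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("need at least 2 clusters with >= 2 members")
    rows = []
    for name in feats.columns:
        col = feats[name]
        groups = {
            c: col[clusters == c].dropna().to_numpy()
            for c in sorted(sizes.index)
        }
        groups = {c: v for c, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        pooled = np.concatenate(list(groups.values()))
        if np.all(pooled == pooled[0]):
            rows.append({"feature_name": name, "kw_h": np.nan, "kw_p": np.nan})
            continue
        kw = stats.kruskal(*groups.values())
        rows.append({"feature_name": name, "kw_h": float(kw.statistic),
                     "kw_p": float(kw.pvalue)})
        if kw.pvalue < alpha:
            dunn = dunn_test(groups, adjust=adjust)
            for rec in dunn.to_dict("records"):
                rows.append({"feature_name": name, "kw_h": float(kw.statistic),
                             "kw_p": float(kw.pvalue), **rec})
    out = pd.DataFrame(rows)
    for col in ("cluster_i", "cluster_j", "dunn_z", "dunn_p_adj", "stars"):
        if col not in out.columns:
            out[col] = np.nan
    return out


def zscore_summary(comparison: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-feature antisymmetric matrix of pairwise Dunn Z scores.

    Tile (i, j) holds the Z of cluster i versus cluster j (so (j, i) is its
    negation), with stars per adjusted p available in the comparison frame.
    """
    out: dict[str, pd.DataFrame] = {}
    pairs = comparison.dropna(subset=["dunn_z"])
    for name, sub in pairs.groupby("feature_name"):
        clusters = sorted(set(sub["cluster_i"]) | set(sub["cluster_j"]))
        mat = pd.DataFrame(0.0, index=clusters, columns=clusters)
        for rec in sub.itertuples(index=False):
            mat.loc[rec.cluster_i, rec.cluster_j] = rec.dunn_z
            mat.loc[rec.cluster_j, rec.cluster_i] = -rec.dunn_z
        out[name] = mat
    return out
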