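"""Library-size normalization, circRNA expression filters, and read-share
summaries.

Size factors follow the median-of-ratios scheme: each sample's factor is
the median, over features whose geometric mean across samples is positive,
of that sample's count divided by the feature's geometric mean.  circRNA
and linear (and optionally intronic) rows are normalized jointly so that
both compartments share one library-size estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    AnnotatedCounts,
    CircAnnotation,
    CountMatrix,
    SampleSheet,
    annotation_index,
    join_samples,
)

__all__ = [
    "size_factors_median_of_ratios",
    "normalize_counts",
    "combine_matrices",
    "filter_aging_circrnas",
    "filter_temperature_circrnas",
    "circ_linear_ratio",
    "brain_head_ratio",
    "quantile_shares",
    "count_expressed_isoforms",
]


def combine_matrices(*matrices: CountMatrix) -> pd.DataFrame:
    """Stack matrices row-wise for joint normalization.

    Feature ids are prefixed by kind to keep rows unique when a circRNA and
    its host gene share an identifier.
    """
    parts = []
    for m in matrices:
        part = m.values.copy()
        part.index = [f"{m.kind}:{f}" for f in part.index]
        parts.append(part)
    combined = pd.concat(parts, axis=0)
    if combined.isna().any().any():
        raise ValueError("matrices must share an identical sample set")
    return combined


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample median-of-ratios size factors.

    For sample j: ``factor_j = median over features f of count(f, j) /
    geomean_f``, restricted to features with a positive geometric mean
    (i.e. expressed in every sample).
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    arr = values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValueError(
            "no feature is expressed in all samples; pre-filter the matrix "
            "before computing size factors"
        )
    log_geomean = logs[finite].mean(axis=1)
    ratios = logs[finite] - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_counts(counts: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    """Divide each column by its size factor."""
    sf = size_factors.reindex(counts.sample_ids)
    if sf.isna().any():
        missing = list(sf.index[sf.isna()])
        raise ValueError(f"no size factor for samples: {missing}")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return CountMatrix(counts.values / sf, kind=counts.kind, normalized=True)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_aging_circrnas(
    circ: CountMatrix,
    annotations: list[CircAnnotation],
    sheet: SampleSheet,
    min_length: int = 50,
    min_mean_per_age: float = 1.0,
    min_single_sample: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """High-confidence circRNA filter for the aging design.

    A circRNA is retained iff its mature length is >= ``min_length`` AND
    (its mean raw count is >= ``min_mean_per_age`` within every age group
    OR at least one sample has >= ``min_single_sample`` reads).

    Returns the retained ids plus a per-feature rejection log with one
    boolean column per rule.
    """
    ann = annotation_index(annotations)
    missing = [f for f in circ.feature_ids if f not in ann]
    if missing:
        raise ValueError(f"circRNAs absent from annotation: {missing[:10]}")
    joined = join_samples(circ, sheet)
    age_groups = joined.groupby("age_days")
    lengths = pd.Series({f: ann[f].length_nt for f in circ.feature_ids})

    age_means = pd.DataFrame(
        {age: sub.values.mean(axis=1) for age, sub in age_groups.items()}
    )
    pass_length = lengths >= min_length
    pass_age_means = (age_means >= min_mean_per_age).all(axis=1)
    pass_single = circ.values.max(axis=1) >= min_single_sample
    retained = pass_length & (pass_age_means | pass_single)

    log = pd.DataFrame(
        {
            "length_nt": lengths,
            "pass_length": pass_length,
            "pass_mean_every_age": pass_age_means,
            "pass_single_sample": pass_single,
            "retained": retained,
        }
    )
    return list(log.index[retained]), log


def filter_temperature_circrnas(
    circ: CountMatrix,
    sheet: SampleSheet,
    min_count: float = 3,
) -> list[str]:
    """Keep circRNAs with at least one condition where every replicate has a
    count strictly greater than ``min_count``."""
    joined = join_samples(circ, sheet)
    cond_groups = joined.groupby("condition")
    keep = pd.Series(False, index=circ.values.index)
    for _, sub in cond_groups.items():
        keep |= (sub.values > min_count).all(axis=1)
    return list(keep.index[keep])


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------


def circ_linear_ratio(
    circ: CountMatrix,
    linear: CountMatrix,
    annotations: list[CircAnnotation],
    method: str = "all_reads",
) -> pd.DataFrame:
    """Per-sample circRNA / host-mRNA ratios.

    ``all_reads``: circRNA reads divided by total host-gene reads; circRNAs
    with sentinel host labels are excluded, and hosts missing from the
    linear matrix yield NA with a warning.

    ``junction_reads``: circRNA reads divided by linear junction reads;
    when the linear junction count is zero the linear value is taken as 1,
    so the ratio equals the circRNA read count itself.
    """
    if method not in {"all_reads", "junction_reads"}:
        raise ValueError(f"unknown method {method!r}")
    if not (circ.normalized and linear.normalized) and method == "all_reads":
        warnings.warn("circ/linear ratios are intended for normalized matrices")
    ann = annotation_index(annotations)
    rows = {}
    for circ_id in circ.feature_ids:
        a = ann.get(circ_id)
        if a is None or a.has_sentinel_host:
            if method == "all_reads":
                continue
            host = circ_id  # junction counts are keyed per circRNA
        else:
            host = a.host_gene
        circ_vals = circ.values.loc[circ_id]
        if method == "junction_reads":
            key = circ_id if circ_id in linear.values.index else host
            if key not in linear.values.index:
                warnings.warn(f"no linear junction counts for {circ_id}; NA")
                rows[circ_id] = pd.Series(np.nan, index=circ.values.columns)
                continue
            lin = linear.values.loc[key].replace(0, 1.0)
            rows[circ_id] = circ_vals / lin
        else:
            if host not in linear.values.index:
                warnings.warn(f"host gene {host!r} of {circ_id} missing from linear matrix; NA")
                rows[circ_id] = pd.Series(np.nan, index=circ.values.columns)
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                rows[circ_id] = circ_vals / linear.values.loc[host]
    out = pd.DataFrame(rows).T
    out.index.name = "circ_id"
    out.insert(0, "method", method)
    return out


def brain_head_ratio(brain: pd.Series | pd.DataFrame, head: pd.Series | pd.DataFrame) -> pd.Series:
    """Brain / head expression ratio with the zero-head substitution.

    Features with zero normalized reads in the head library get a head
    value of 1, so the ratio equals the normalized brain reads.
    """
    b = brain.mean(axis=1) if isinstance(brain, pd.DataFrame) else brain.astype(float)
    h = head.mean(axis=1) if isinstance(head, pd.DataFrame) else head.astype(float)
    b, h = b.align(h, join="inner")
    h = h.where(h > 0, 1.0)
    out = b / h
    out.name = "brain_head_ratio"
    return out


# ---------------------------------------------------------------------------
# read-share and diversity summaries
# ---------------------------------------------------------------------------


def quantile_shares(
    circ: CountMatrix,
    n_quantiles: int = 4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of total reads carried by each expression quantile.

    Quantiles are assigned separately per replicate (sample); shares are
    then averaged over replicates.  Quantile 1 is the lowest-expressed
    stratum, quantile ``n_quantiles`` the top.  Ties are broken by stable
    feature order, assigning tied features to the lower quantile.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    n = circ.values.shape[0]
    per_sample = {}
    for sample in circ.sample_ids:
        col = circ.values[sample]
        total = col.sum()
        if total == 0:
            warnings.warn(f"sample {sample!r} has zero total reads; NA shares")
            per_sample[sample] = pd.Series(np.nan, index=range(1, n_quantiles + 1))
            continue
        order = np.argsort(col.to_numpy(), kind="stable")
        qbin = np.empty(n, dtype=int)
        qbin[order] = np.floor(np.arange(n) * n_quantiles / n).astype(int) + 1
        shares = (
            pd.Series(col.to_numpy(), index=qbin).groupby(level=0).sum() / total
        )
        per_sample[sample] = shares.reindex(range(1, n_quantiles + 1), fill_value=0.0)
    table = pd.DataFrame(per_sample)
    table.index.name = "quantile"
    return table, table.mean(axis=1).rename("mean_share")


def count_expressed_isoforms(circ: CountMatrix) -> pd.Series:
    """Number of distinct circRNAs with reads strictly above 0, per sample."""
    out = (circ.values > 0).sum(axis=0)
    out.name = "n_expressed_circrnas"
    return out
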