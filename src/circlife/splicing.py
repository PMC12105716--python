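"""Alternative-splicing screens: delta-PSI, the change-event selection
rule, and correlation of circRNA fold changes with flanking intron
retention.

An event changes between two conditions when the absolute difference of
mean PSI is at least 15 percentage points AND the per-replicate [min, max]
intervals of the two conditions are disjoint (closed intervals: a shared
endpoint counts as overlap).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PSI_META_COLUMNS, SampleSheet

__all__ = [
    "delta_psi",
    "select_events",
    "correlate_circ_vs_retention",
    "stratify_circ_by_host_splicing",
]


def _psi_samples(psi: pd.DataFrame) -> list[str]:
    return [c for c in psi.columns if c not in PSI_META_COLUMNS]


def delta_psi(
    psi: pd.DataFrame,
    sheet: SampleSheet,
    age_a: int,
    age_b: int,
) -> pd.DataFrame:
    """Per-event PSI difference of means, age_b minus age_a.

    Also retains the per-condition replicate min/max needed by the
    selection rule.  Events missing every replicate in a condition get NA.
    """
    samples_a = [s for s in sheet.samples_where(age_days=age_a) if s in psi.columns]
    samples_b = [s for s in sheet.samples_where(age_days=age_b) if s in psi.columns]
    if not samples_a or not samples_b:
        raise ValueError(f"no PSI samples for ages {age_a} and/or {age_b}")
    a = psi[samples_a].astype(float)
    b = psi[samples_b].astype(float)
    out = psi[PSI_META_COLUMNS].copy()
    out["mean_a"] = a.mean(axis=1)
    out["mean_b"] = b.mean(axis=1)
    out["delta_psi"] = out["mean_b"] - out["mean_a"]
    out["min_a"], out["max_a"] = a.min(axis=1), a.max(axis=1)
    out["min_b"], out["max_b"] = b.min(axis=1), b.max(axis=1)
    return out


def select_events(deltas: pd.DataFrame, min_delta: float = 15.0) -> pd.DataFrame:
    """Events with |delta PSI| >= ``min_delta`` and disjoint replicate ranges.

    Single-replicate conditions have point intervals; the rule applies
    unchanged.
    """
    d = deltas.dropna(subset=["delta_psi"])
    big_enough = d["delta_psi"].abs() >= min_delta
    disjoint = (d["max_a"] < d["min_b"]) | (d["max_b"] < d["min_a"])
    return d[big_enough & disjoint].copy()


def correlate_circ_vs_retention(
    circ_log2fc: pd.Series,
    deltas: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate circRNA log2 fold changes with flanking-intron delta PSI.

    ``deltas`` must carry ``flank_of`` entries of the form
    ``circ_id:upstream`` / ``circ_id:downstream``.  Pearson r (primary) and
    Spearman rho (secondary) are computed separately per flank side; fewer
    than 3 matched pairs, or zero variance on either axis, yields NA.
    """
    flank = deltas[deltas["flank_of"].notna() & (deltas["flank_of"] != ".")].copy()
    if flank.empty:
        warnings.warn("no flank-annotated events; nothing to correlate")
    parts = flank["flank_of"].str.rsplit(":", n=1, expand=True)
    flank["circ_id"], flank["side"] = parts[0], parts[1]
    rows = []
    for side in ("upstream", "downstream"):
        sub = flank[flank["side"] == side]
        matched = sub.set_index("circ_id")["delta_psi"]
        shared = matched.index.intersection(circ_log2fc.index)
        x = circ_log2fc.loc[shared].to_numpy(dtype=float)
        y = matched.loc[shared].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            if len(x) < 3:
                warnings.warn(f"{side}: fewer than 3 matched pairs; NA")
            rows.append({"flank": side, "n": len(x), "pearson_r": np.nan,
                         "pearson_p": np.nan, "spearman_rho": np.nan,
                         "spearman_p": np.nan})
            continue
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        rows.append({
            "flank": side, "n": len(x),
            "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
        })
    return pd.DataFrame(rows).set_index("flank")


def stratify_circ_by_host_splicing(
    traj_values: pd.DataFrame,
    selected_events: pd.DataFrame,
    host_map: pd.Series,
) -> pd.DataFrame:
    """Mean trajectory +/- SEM for circRNAs whose host genes do or do not
    carry significant splicing changes.

    ``host_map`` maps circ_id -> host gene; strata are formed per event
    type plus a combined "any_change" stratum and the complementary
    "unchanged" stratum.  Empty strata are reported with n = 0.
    """
    changed_hosts = set(selected_events["host_gene"].dropna())
    hosts = host_map.reindex(traj_values.index)
    strata: dict[str, pd.Index] = {}
    for etype, sub in selected_events.groupby("event_type"):
        hs = set(sub["host_gene"].dropna())
        strata[etype] = traj_values.index[hosts.isin(hs)]
    strata["any_change"] = traj_values.index[hosts.isin(changed_hosts)]
    strata["unchanged"] = traj_values.index[~hosts.isin(changed_hosts)]
    rows = []
    for name, ids in strata.items():
        sub = traj_values.loc[ids]
        for age in traj_values.columns:
            rows.append({
                "stratum": name, "age": age, "n": len(sub),
                "fc_mean": float(sub[age].mean()) if len(sub) else np.nan,
                "fc_sem": float(sub[age].sem()) if len(sub) >= 2 else np.nan,
            })
    return pd.DataFrame(rows).set_index(["stratum", "age"])
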