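"""One-call synthetic study: every pipeline stage run end to end on
generated data with known ground truth.

Chains: simulate -> filter -> joint normalization -> per-age NB-GLM fold
changes -> trajectories -> consensus clustering with k selection ->
cluster summaries -> genomic features and cluster comparison -> splicing
screen and circ-vs-retention correlation -> temperature DE with the
chained pre-treatment rule -> pulse-chase half-life estimation.  All stage
outputs can be written as TSV artifacts.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, counts_norm, diffexp, genomic_features, halflife, splicing
from .core_io import write_counts, write_sample_sheet
from .synthetic_data import (
    DEFAULT_ARCHETYPES,
    PulseConfig,
    SimConfig,
    aging_annotations,
    make_genome_fixture,
    psi_sample_sheet,
    simulate_aging,
    simulate_psi,
    simulate_pulse_chase_qpcr,
    simulate_temperature,
)

__all__ = ["run_synthetic_study"]


def run_synthetic_study(
    seed: int,
    out_dir: str | Path | None = None,
    n_circ_per_cluster: int = 60,
    n_rep_consensus: int = 100,
    k_range: range = range(2, 8),
    n_psi_events: int = 200,
    n_genes_fixture: int = 40,
) -> dict:
    """Run the full pipeline on one synthetic study; returns all results.

    Deterministic for a fixed seed.  ``out_dir`` (optional) receives one
    TSV per stage output.
    """
    rng_seed = int(seed) % (2**31 - 1)
    results: dict = {"seed": rng_seed}
    artifacts: dict[str, pd.DataFrame] = {}

    # --- aging study -------------------------------------------------------
    config = SimConfig(seed=rng_seed, n_circ_per_cluster=n_circ_per_cluster)
    sim = simulate_aging(config)
    anns = aging_annotations(sim.truth)
    results["aging_truth"] = sim.truth

    retained, filter_log = counts_norm.filter_aging_circrnas(sim.circ, anns, sim.sheet)
    circ_f = sim.circ.subset_features(retained)
    artifacts["filter_log"] = filter_log

    combined = counts_norm.combine_matrices(circ_f, sim.linear, sim.intron)
    size_factors = counts_norm.size_factors_median_of_ratios(combined)
    circ_n = counts_norm.normalize_counts(circ_f, size_factors)
    linear_n = counts_norm.normalize_counts(sim.linear, size_factors)
    results["size_factors"] = size_factors
    artifacts["size_factors"] = size_factors.to_frame()

    results["age_regression"] = diffexp.age_regression_total(circ_n, sim.sheet)
    results["pca"] = diffexp.pca_with_contributors(circ_n, top_n=25)
    shares, mean_shares = counts_norm.quantile_shares(circ_n, n_quantiles=4)
    results["quantile_shares"] = mean_shares
    results["n_isoforms"] = counts_norm.count_expressed_isoforms(circ_n)
    ratio = counts_norm.circ_linear_ratio(circ_n, linear_n, anns, method="all_reads")
    artifacts["circ_linear_ratio"] = ratio
    artifacts["quantile_shares"] = shares

    # --- trajectories and clustering --------------------------------------
    ages = [a for a in sim.sheet.ages if a != 0]
    traj_by_sex, fc_store = {}, {}
    for sex in ("female", "male"):
        fcs = {}
        group0 = sim.sheet.samples_where(sex=sex, age_days=0)
        for age in ages:
            group_b = sim.sheet.samples_where(sex=sex, age_days=age)
            fcs[age] = diffexp.nb_glm_foldchange(circ_f, size_factors, group0, group_b)
        traj_by_sex[sex] = clustering.build_trajectories(fcs)
        fc_store[sex] = fcs
    diag = clustering.cross_sex_diagnostics(
        traj_by_sex, k_range=k_range, n_rep=n_rep_consensus, seed=rng_seed
    )
    chosen_k, k_report = clustering.select_k(diag)
    consensus = clustering.consensus_kmeans(
        traj_by_sex["female"], chosen_k, n_rep=n_rep_consensus, seed=rng_seed + 1
    )
    results["k_diagnostics"] = diag
    results["chosen_k"] = chosen_k
    results["k_report"] = k_report
    results["assignments"] = consensus.assignments
    results["rand_vs_truth"] = clustering.rand_index(
        consensus.assignments,
        sim.truth["cluster"].loc[consensus.assignments.index],
    )

    # host trajectories (matched to circ ids) for the cluster summaries
    host_fcs = {}
    for age in ages:
        fc = diffexp.nb_glm_foldchange(
            sim.linear, size_factors,
            sim.sheet.samples_where(sex="female", age_days=0),
            sim.sheet.samples_where(sex="female", age_days=age),
        )
        fc.index = sim.truth.index  # host genes are 1:1 with circRNAs here
        host_fcs[age] = fc
    host_traj = clustering.build_trajectories(host_fcs)
    expr = circ_n.values.T.groupby(
        sim.sheet.data.set_index("sample_id")["age_days"]
    ).mean().T
    summaries = clustering.cluster_summaries(
        traj_by_sex["female"], consensus.assignments,
        linear_traj=host_traj, expression=expr,
    )
    artifacts["k_diagnostics"] = diag
    artifacts["assignments"] = consensus.assignments.to_frame()
    artifacts["cluster_summaries"] = summaries.reset_index()

    # --- genomic features --------------------------------------------------
    fixture = make_genome_fixture(n_genes_fixture, seed=rng_seed)
    features = genomic_features.extract_features(fixture.circs, fixture.genes, fixture.genome)
    fixture_clusters = pd.Series(
        (np.arange(len(features)) % max(chosen_k, 2)) + 1, index=features.index
    )
    comparison = genomic_features.compare_clusters(features, fixture_clusters)
    results["features"] = features
    results["feature_comparison"] = comparison
    artifacts["features"] = features.reset_index()
    artifacts["feature_comparison"] = comparison

    # --- splicing -----------------------------------------------------------
    psi, psi_truth = simulate_psi(
        n_psi_events, list(sim.sheet.ages), config.n_replicates,
        changed_fraction=0.2, seed=rng_seed + 2, circ_ids=list(circ_f.feature_ids),
    )
    psi_sheet = psi_sample_sheet(list(sim.sheet.ages), config.n_replicates)
    deltas = splicing.delta_psi(psi, psi_sheet, sim.sheet.ages[0], sim.sheet.ages[-1])
    selected = splicing.select_events(deltas)
    corr = splicing.correlate_circ_vs_retention(
        fc_store["female"][ages[-1]]["log2fc"], deltas
    )
    strata = splicing.stratify_circ_by_host_splicing(
        traj_by_sex["female"].values, selected, sim.truth["host_gene"]
    )
    results["psi_truth"] = psi_truth
    results["selected_events"] = selected
    results["circ_psi_correlation"] = corr
    artifacts["delta_psi"] = deltas
    artifacts["selected_events"] = selected
    artifacts["circ_psi_correlation"] = corr.reset_index()
    artifacts["splicing_strata"] = strata.reset_index()

    # --- temperature pulse --------------------------------------------------
    n_temp = 5 * n_circ_per_cluster
    induced = tuple(f"circ_t{i:04d}" for i in range(0, n_temp, 10))
    pulse = PulseConfig(induced_ids=induced, pulse_fold=4.0, true_halflife_days=math.inf)
    # the temperature-exposure arm of the study used up to five replicates
    temp_config = SimConfig(seed=rng_seed + 3, n_circ_per_cluster=n_circ_per_cluster,
                            n_replicates=5, pulse=pulse)
    temp = simulate_temperature(temp_config)
    kept = counts_norm.filter_temperature_circrnas(temp.circ, temp.sheet)
    temp_circ = temp.circ.subset_features(kept)
    temp_combined = counts_norm.combine_matrices(temp_circ, temp.linear)
    temp_sf = counts_norm.size_factors_median_of_ratios(temp_combined)
    contrasts = {}
    for name, (num, den) in {
        "29v18": ("29C", "18C"), "29vpre": ("29C", "pre"), "18vpre": ("18C", "pre"),
    }.items():
        contrasts[name] = diffexp.nb_glm_foldchange(
            temp_circ, temp_sf,
            temp.sheet.samples_where(condition=den),
            temp.sheet.samples_where(condition=num),
        )
    chained = diffexp.call_de_temperature_chained(
        contrasts["29v18"], contrasts["29vpre"], contrasts["18vpre"]
    )
    results["temperature_truth"] = temp.truth
    results["temperature_de"] = chained
    artifacts["temperature_de"] = chained.reset_index()

    # --- half-life -----------------------------------------------------------
    # baseline accumulation of a mid-rate circRNA from the male aging arm
    target = sim.truth.index[sim.truth["archetype"] == "mid_increase"][0]
    base = halflife.fit_baseline(circ_n.values.loc[target], sim.sheet, sex="male")
    chase_pulse = PulseConfig(
        induced_ids=(str(target),), pulse_fold=3.0, true_halflife_days=20.0
    )
    qpcr, chase_truth = simulate_pulse_chase_qpcr(
        SimConfig(seed=rng_seed + 4, pulse=chase_pulse), base, noise_sigma=0.1
    )
    obs = [
        (float(r.day), float(r.fold_change))
        for r in qpcr.itertuples() if r.day > 10
    ]
    fc10_obs = float(qpcr.loc[qpcr["day"] == 10, "fold_change"].iloc[0])
    model = halflife.estimate_halflife(
        base, halflife.combine_fc10(chase_pulse.pulse_fold, fc10_obs),
        obs, target_id=str(target),
    )
    results["halflife_truth"] = chase_truth
    results["decay_model"] = model
    artifacts["halflife"] = pd.DataFrame([{
        "target_id": model.target_id, "fc10": model.fc10, "excess0": model.excess0,
        "h_hat": model.h_hat, "h_reported": model.h_reported,
        "fit_error": model.fit_error,
    }])

    # --- artifacts ------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(sim.circ, out / "circ_counts.tsv")
        write_counts(sim.linear, out / "linear_counts.tsv")
        write_counts(sim.intron, out / "intron_counts.tsv")
        write_counts(circ_n, out / "circ_normalized.tsv")
        write_sample_sheet(sim.sheet, out / "sample_sheet.tsv")
        traj_by_sex["female"].values.to_csv(out / "trajectories_female.tsv", sep="\t")
        for name, frame in artifacts.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t")
        results["artifact_dir"] = str(out)
        results["n_artifacts"] = len(artifacts) + 6

    return results
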