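"""Synthetic data generators with known ground truth for every pipeline
stage.

The aging generator emulates the structure of a fly-head aging study: six
ages (0-50 days in 10-day steps), two sexes drawn from shared truth, three
replicates, and negative-binomial backsplice counts around linear mean
trajectories.  Five trajectory archetypes are planted: three increasing at
distinct rates, one decreasing together with its host gene's transcription,
and one flat.  Companion generators produce a temperature pulse experiment
with a known induced circRNA subset, pulse-chase qPCR fold changes under
known half-lives, beta-distributed PSI tables, and a small genome/GTF
fixture with circRNAs on annotated exon boundaries.

All generators are seed-deterministic; raw counts are integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CircAnnotation, CountMatrix, GeneModel, SampleSheet
from .halflife import Baseline, predict_fc

__all__ = [
    "TrajectoryArchetype",
    "DEFAULT_ARCHETYPES",
    "PulseConfig",
    "SimConfig",
    "SimulatedAging",
    "simulate_aging",
    "simulate_temperature",
    "simulate_pulse_chase_qpcr",
    "simulate_psi",
    "GenomeFixture",
    "make_genome_fixture",
    "write_genome_fasta",
    "write_gtf",
]

MEAN_FLOOR = 0.5  # keeps NB means positive for decreasing trajectories


@dataclass(frozen=True)
class TrajectoryArchetype:
    """A planted expression trajectory: linear in age on the mean scale.

    ``host_coupled`` marks archetypes whose host mRNA and intronic signal
    follow the same relative trajectory (the developmental decrease);
    otherwise host and intron means stay flat with age.
    """

    name: str
    baseline_mean: float
    slope_per_day: float
    host_coupled: bool = False

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.name == "decrease" and not (self.slope_per_day < 0 and self.host_coupled):
            raise ValueError("decrease archetype must have negative slope and host coupling")
        if self.name == "flat" and abs(self.slope_per_day) > 1e-9:
            raise ValueError("flat archetype must have ~zero slope")

    def mean_at(self, age: float) -> float:
        return max(self.baseline_mean + self.slope_per_day * age, MEAN_FLOOR)


#: Default study conditions: three increasing archetypes with clearly
#: distinct accumulation rates (~21x, ~7x, ~3x over 50 days, spanning the
#: range seen for strongly age-accumulating circRNAs), one sharp
#: developmental decrease coupled to host transcription, and one flat
#: cluster.  Adjacent increasing clusters are spaced comparably in log
#: fold-change space, as in real data where accumulation rates form a
#: continuum.
DEFAULT_ARCHETYPES: tuple[TrajectoryArchetype, ...] = (
    TrajectoryArchetype("fast_increase", baseline_mean=100.0, slope_per_day=40.0),
    TrajectoryArchetype("mid_increase", baseline_mean=100.0, slope_per_day=12.0),
    TrajectoryArchetype("slow_increase", baseline_mean=100.0, slope_per_day=4.0),
    TrajectoryArchetype("decrease", baseline_mean=200.0, slope_per_day=-3.8, host_coupled=True),
    TrajectoryArchetype("flat", baseline_mean=150.0, slope_per_day=0.0),
)


@dataclass(frozen=True)
class PulseConfig:
    """Temperature pulse: which circRNAs respond, how strongly, and their
    true decay half-life (days; ``inf`` = no decay)."""

    induced_ids: tuple[str, ...]
    pulse_fold: float = 3.0
    true_halflife_days: float = math.inf

    def __post_init__(self) -> None:
        if self.pulse_fold <= 1:
            raise ValueError("pulse_fold must be > 1")
        if not (self.true_halflife_days > 0):
            raise ValueError("true_halflife_days must be positive or infinite")


@dataclass(frozen=True)
class SimConfig:
    """Shared generator settings.

    The defaults mirror the study design: 6 ages at 10-day spacing, 3
    replicates, NB dispersion 0.1 (a conventional bulk RNA-seq value; the
    study reports none), unit library size factors.
    """

    n_circ_per_cluster: int = 200
    ages: tuple[int, ...] = (0, 10, 20, 30, 40, 50)
    n_replicates: int = 3
    nb_dispersion: float = 0.1
    library_size_factors: Mapping[str, float] | None = None
    seed: int = 0
    pulse: PulseConfig | None = None

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if len(self.ages) < 2 or list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be sorted with at least 2 entries")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) draws; dispersion -> 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _size_factor(config: SimConfig, sample: str) -> float:
    if config.library_size_factors is None:
        return 1.0
    sf = config.library_size_factors.get(sample)
    if sf is None or sf <= 0:
        raise ValueError(f"missing/invalid size factor for sample {sample!r}")
    return sf


# ---------------------------------------------------------------------------
# aging study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedAging:
    circ: CountMatrix
    linear: CountMatrix
    intron: CountMatrix
    sheet: SampleSheet
    truth: pd.DataFrame


HOST_EXPR_MULTIPLIER = 10.0    # host mRNAs ~10x the circRNA baseline
INTRON_EXPR_MULTIPLIER = 0.5   # intronic signal fraction of circ baseline


def simulate_aging(
    config: SimConfig,
    archetypes: Sequence[TrajectoryArchetype] = DEFAULT_ARCHETYPES,
    sexes: Sequence[str] = ("female", "male"),
) -> SimulatedAging:
    """Aging study with planted trajectory clusters.

    Both sexes share the same per-feature truth (means) and differ only in
    sampling noise, matching a design where cluster structure is expected
    to replicate across sexes.  Counts are NB around
    ``size_factor * max(baseline + slope * age, 0.5)``.  Host mRNA and
    intronic means are flat with age except for host-coupled archetypes,
    which share the circRNA's relative trajectory.
    """
    rng = np.random.default_rng(config.seed)
    circ_ids, truth_rows = [], []
    for a_idx, arch in enumerate(archetypes, start=1):
        for i in range(config.n_circ_per_cluster):
            cid = f"circ_{arch.name}_{i:04d}"
            circ_ids.append(cid)
            truth_rows.append({
                "circ_id": cid,
                "archetype": arch.name,
                "cluster": a_idx,
                "baseline_mean": arch.baseline_mean,
                "slope_per_day": arch.slope_per_day,
                "host_coupled": arch.host_coupled,
                "host_gene": f"gene_{arch.name}_{i:04d}",
            })
    truth = pd.DataFrame(truth_rows).set_index("circ_id")

    samples, rows = [], []
    for sex in sexes:
        for age in config.ages:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{sex[0]}_age{age}_r{rep}"
                samples.append((sid, age, sex, rep))
                rows.append({
                    "sample_id": sid, "age_days": age, "sex": sex,
                    "condition": "aging", "replicate": rep, "tissue": "head",
                })
    sheet = SampleSheet(pd.DataFrame(rows))

    arch_by_circ = truth["archetype"].map({a.name: a for a in archetypes})
    circ_cols, lin_cols, int_cols = {}, {}, {}
    for sid, age, _sex, _rep in samples:
        sf = _size_factor(config, sid)
        circ_mu = np.array([a.mean_at(age) for a in arch_by_circ]) * sf
        rel = np.array([
            a.mean_at(age) / a.mean_at(config.ages[0]) if a.host_coupled else 1.0
            for a in arch_by_circ
        ])
        lin_mu = np.array([a.baseline_mean for a in arch_by_circ]) * HOST_EXPR_MULTIPLIER * rel * sf
        int_mu = np.array([a.baseline_mean for a in arch_by_circ]) * INTRON_EXPR_MULTIPLIER * rel * sf
        circ_cols[sid] = _nb_draw(rng, circ_mu, config.nb_dispersion)
        lin_cols[sid] = _nb_draw(rng, lin_mu, config.nb_dispersion)
        int_cols[sid] = _nb_draw(rng, int_mu, config.nb_dispersion)

    host_ids = list(truth["host_gene"])
    circ = CountMatrix(pd.DataFrame(circ_cols, index=circ_ids), kind="circ")
    linear = CountMatrix(pd.DataFrame(lin_cols, index=host_ids), kind="linear")
    intron = CountMatrix(pd.DataFrame(int_cols, index=host_ids), kind="intron")
    return SimulatedAging(circ=circ, linear=linear, intron=intron, sheet=sheet, truth=truth)


def aging_annotations(truth: pd.DataFrame, length_nt: int = 400) -> list[CircAnnotation]:
    """Placeholder genomic annotations for simulated aging circRNAs.

    Coordinates are synthetic (non-overlapping tiles on one chromosome);
    lengths default to 400 nt so every feature passes the length filter.
    """
    anns = []
    for i, (cid, row) in enumerate(truth.iterrows()):
        start = 1000 + i * 2000
        anns.append(CircAnnotation(
            circ_id=cid, chrom="chrSim", start=start, end=start + 800,
            strand="+", host_gene=row["host_gene"],
            n_annotated_junctions=2, length_nt=length_nt,
        ))
    return anns


# ---------------------------------------------------------------------------
# temperature pulse
# ---------------------------------------------------------------------------

TEMPERATURE_CONDITIONS = ("pre", "18C", "25C", "29C")


@dataclass
class SimulatedTemperature:
    circ: CountMatrix
    linear: CountMatrix
    sheet: SampleSheet
    truth: pd.DataFrame


def simulate_temperature(
    config: SimConfig,
    n_features: int | None = None,
) -> SimulatedTemperature:
    """Temperature experiment: pre-treatment plus 10 days at 18/25/29C.

    All features share one baseline mean across conditions except the
    configured induced set, whose mean is multiplied by ``pulse_fold`` at
    29C only.  Male flies only (the design does not stratify by sex).
    """
    if config.pulse is None:
        raise ValueError("simulate_temperature requires a pulse configuration")
    rng = np.random.default_rng(config.seed)
    n = n_features or 5 * config.n_circ_per_cluster
    circ_ids = [f"circ_t{i:04d}" for i in range(n)]
    unknown = set(config.pulse.induced_ids) - set(circ_ids)
    if unknown:
        raise ValueError(f"induced ids not among simulated features: {sorted(unknown)}")
    base_mu = np.exp(rng.normal(np.log(50.0), 1.0, size=n))
    induced = np.isin(circ_ids, config.pulse.induced_ids)

    rows, circ_cols, lin_cols = [], {}, {}
    for cond in TEMPERATURE_CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            sid = f"temp_{cond}_r{rep}"
            rows.append({
                "sample_id": sid, "age_days": 0 if cond == "pre" else 10,
                "sex": "male", "condition": cond, "replicate": rep,
                "tissue": "head",
            })
            sf = _size_factor(config, sid)
            mu = base_mu * sf
            if cond == "29C":
                mu = mu * np.where(induced, config.pulse.pulse_fold, 1.0)
            circ_cols[sid] = _nb_draw(rng, mu, config.nb_dispersion)
            lin_cols[sid] = _nb_draw(rng, base_mu * HOST_EXPR_MULTIPLIER * sf,
                                     config.nb_dispersion)
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = pd.DataFrame({
        "circ_id": circ_ids, "baseline_mean": base_mu, "induced": induced,
        "pulse_fold": np.where(induced, config.pulse.pulse_fold, 1.0),
    }).set_index("circ_id")
    circ = CountMatrix(pd.DataFrame(circ_cols, index=circ_ids), kind="circ")
    linear = CountMatrix(
        pd.DataFrame(lin_cols, index=[f"gene_t{i:04d}" for i in range(n)]), kind="linear"
    )
    return SimulatedTemperature(circ=circ, linear=linear, sheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# pulse-chase qPCR
# ---------------------------------------------------------------------------


def simulate_pulse_chase_qpcr(
    config: SimConfig,
    baseline: Baseline,
    days: tuple[float, ...] = (10.0, 31.0, 52.0),
    noise_sigma: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR 29C/18C fold changes at recovery days under known half-lives.

    Fold changes follow the closed-form decay model around the supplied
    accumulation baseline, with multiplicative lognormal noise
    (``noise_sigma`` on the log scale; 0 gives exact model values).
    ``true_halflife_days`` applies to every induced target.
    """
    if config.pulse is None:
        raise ValueError("simulate_pulse_chase_qpcr requires a pulse configuration")
    for day in days:
        if baseline(day) <= 0:
            raise ValueError(f"baseline non-positive at day {day}")
    rng = np.random.default_rng(config.seed)
    h = config.pulse.true_halflife_days
    fc10 = config.pulse.pulse_fold
    rows = []
    for target in config.pulse.induced_ids:
        for day in days:
            fc = predict_fc(baseline, fc10, day, h)
            if noise_sigma > 0:
                fc *= float(np.exp(rng.normal(0.0, noise_sigma)))
            rows.append({"target_id": target, "day": day, "fold_change": fc})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "target_id": list(config.pulse.induced_ids),
        "true_halflife_days": h,
        "fc10": fc10,
    }).set_index("target_id")
    return table, truth


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------


def simulate_psi(
    n_events: int,
    ages: Sequence[int],
    n_replicates: int,
    changed_fraction: float,
    seed: int = 0,
    delta: float = 30.0,
    concentration: float = 300.0,
    circ_ids: Sequence[str] | None = None,
    event_type: str = "intron_retention",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta-distributed PSI table with a planted changed-event subset.

    Changed events shift their mean PSI linearly with age, reaching
    ``delta`` points at the last age (direction chosen to stay inside
    [5, 95]); unchanged events are stationary.  Replicate tightness is set
    by the beta ``concentration``.  When ``circ_ids`` is given, events are
    tied round-robin to circRNA flanks via ``flank_of``.
    """
    if not 0 <= changed_fraction <= 1:
        raise ValueError("changed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ages = list(ages)
    n_changed = int(round(changed_fraction * n_events))
    base = rng.uniform(20.0, 70.0, size=n_events)
    changed = np.zeros(n_events, dtype=bool)
    changed[:n_changed] = True
    direction = np.where(base + delta <= 95.0, 1.0, -1.0)

    meta_rows, data = [], {}
    max_age = max(ages) - min(ages) or 1
    for i in range(n_events):
        eid = f"event_{i:05d}"
        flank = "."
        if circ_ids is not None and len(circ_ids):
            side = "upstream" if i % 2 == 0 else "downstream"
            flank = f"{circ_ids[(i // 2) % len(circ_ids)]}:{side}"
        meta_rows.append({
            "event_id": eid, "event_type": event_type,
            "host_gene": f"gene_psi_{i:05d}", "flank_of": flank,
        })
    for age in ages:
        frac = (age - min(ages)) / max_age
        mean = base + np.where(changed, direction * delta * frac, 0.0)
        mean = np.clip(mean, 1.0, 99.0) / 100.0
        for rep in range(1, n_replicates + 1):
            draws = rng.beta(mean * concentration, (1 - mean) * concentration)
            data[f"psi_age{age}_r{rep}"] = np.clip(draws * 100.0, 0.0, 100.0)
    psi = pd.concat([pd.DataFrame(meta_rows), pd.DataFrame(data)], axis=1)
    truth = pd.DataFrame({
        "event_id": [m["event_id"] for m in meta_rows],
        "changed": changed,
        "base_psi": base,
        "planted_delta": np.where(changed, direction * delta, 0.0),
    }).set_index("event_id")
    return psi, truth


def psi_sample_sheet(ages: Sequence[int], n_replicates: int) -> SampleSheet:
    """Design sheet matching the column names simulate_psi emits."""
    rows = [
        {"sample_id": f"psi_age{age}_r{rep}", "age_days": age, "sex": "NA",
         "condition": "aging", "replicate": rep, "tissue": "head"}
        for age in ages for rep in range(1, n_replicates + 1)
    ]
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------


@dataclass
class GenomeFixture:
    genome: dict[str, str]
    genes: dict[str, GeneModel]
    circs: list[CircAnnotation]
    truth: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def make_genome_fixture(
    n_genes: int,
    seed: int = 0,
    exon_count_range: tuple[int, int] = (4, 6),
    exon_length_range: tuple[int, int] = (100, 300),
    intron_length_range: tuple[int, int] = (80, 200),
    gc_range: tuple[float, float] = (0.35, 0.65),
) -> GenomeFixture:
    """Random genome with multi-exon genes and one circRNA per gene.

    Each circRNA spans exons 2-3 (1-based) of its host, so its flanking
    introns are intron 1 (genomically upstream) and intron 3 (genomically
    downstream); on minus-strand genes the transcript-orientation labels
    swap.  The truth table records member exons and flank intervals.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom = "chrSim"
    pieces: list[str] = []
    cursor = 0
    genes: dict[str, GeneModel] = {}
    circs: list[CircAnnotation] = []
    truth_rows = []
    spacer = 500
    for g in range(n_genes):
        gene_id = f"gene{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        gc = float(rng.uniform(*gc_range))
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        pieces.append(_random_seq(rng, spacer, 0.5))
        cursor += spacer
        exons = []
        for e in range(n_exons):
            if e > 0:
                ilen = int(rng.integers(*intron_length_range))
                pieces.append(_random_seq(rng, ilen, gc))
                cursor += ilen
            elen = int(rng.integers(*exon_length_range))
            exons.append((cursor, cursor + elen))
            pieces.append(_random_seq(rng, elen, gc))
            cursor += elen
        gene = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)
        genes[gene_id] = gene

        member = exons[1:3]  # exons 2-3, 1-based
        start, end = member[0][0], member[-1][1]
        length_nt = sum(e - s for s, e in member)
        circ_id = f"circ_{gene_id}"
        circs.append(CircAnnotation(
            circ_id=circ_id, chrom=chrom, start=start, end=end, strand=strand,
            host_gene=gene_id, n_annotated_junctions=2, length_nt=length_nt,
        ))
        left, right = gene.introns[0], gene.introns[2]
        up, down = (left, right) if strand == "+" else (right, left)
        truth_rows.append({
            "circ_id": circ_id, "host_gene": gene_id, "strand": strand,
            "n_member_exons": len(member), "length_nt": length_nt,
            "upstream_intron_start": up[0], "upstream_intron_end": up[1],
            "downstream_intron_start": down[0], "downstream_intron_end": down[1],
            "target_gc": gc,
        })
    pieces.append(_random_seq(rng, spacer, 0.5))
    genome = {chrom: "".join(pieces)}
    truth = pd.DataFrame(truth_rows).set_index("circ_id")
    return GenomeFixture(genome=genome, genes=genes, circs=circs, truth=truth)


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gtf(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (converting to 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gene in genes.values():
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
            fh.write("\t".join([
                gene.chrom, "circlife_sim", "gene", str(gene.start + 1),
                str(gene.end), ".", gene.strand, ".", f'gene_id "{gene.gene_id}";',
            ]) + "\n")
            for s, e in gene.exons:
                fh.write("\t".join([
                    gene.chrom, "circlife_sim", "exon", str(s + 1), str(e),
                    ".", gene.strand, ".", attrs,
                ]) + "\n")
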