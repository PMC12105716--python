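"""Data model and tabular I/O for the circRNA aging pipeline.

All genomic coordinates are handled internally as 0-based half-open
(BED-style) intervals.  GTF input (1-based, end-inclusive) is converted on
read; a ``one_based`` flag on the circRNA-annotation reader performs the
same conversion for tables exported from 1-based tools.

Tables are plain TSV: count matrices have a header row of sample ids and
feature ids in the first column; the sample sheet carries the six design
columns (sample_id, age_days, sex, condition, replicate, tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENTINEL_HOSTS",
    "SampleSheet",
    "CountMatrix",
    "CircAnnotation",
    "GeneModel",
    "AnnotatedCounts",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_circ_annotation",
    "write_circ_annotation",
    "read_gene_models",
    "read_genome",
    "read_psi_table",
    "write_psi_table",
    "join_samples",
    "to_zero_based",
    "to_one_based",
]

#: host-gene labels marking circRNAs without a resolvable single host gene;
#: these are excluded from host-relative analyses (circ/mRNA ratios,
#: feature extraction).
SENTINEL_HOSTS = frozenset({"intergenic", "ambiguous", "no_single_host"})

VALID_SEX = frozenset({"male", "female", "NA"})
VALID_CONDITION = frozenset({"aging", "pre", "18C", "25C", "29C", "recovery"})
VALID_TISSUE = frozenset({"head", "brain"})
VALID_KIND = frozenset({"circ", "linear", "linear_junction", "intron"})

SAMPLE_SHEET_COLUMNS = ["sample_id", "age_days", "sex", "condition", "replicate", "tissue"]


class ParseError(ValueError):
    """Raised when an input table violates its format contract."""


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based end-inclusive interval to 0-based half-open."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based end-inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Experimental design: one row per sequenced library.

    ``age_days`` counts days post-eclosion (0 denotes the 2-3 day old
    "newly eclosed" collection).  ``sex`` may be ``NA`` for designs that do
    not stratify by sex (e.g. the male-only temperature experiment).
    Arbitrary age grids are allowed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"sample sheet missing columns: {missing}")
        df = df[SAMPLE_SHEET_COLUMNS].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ParseError(f"duplicate sample ids: {dups}")
        df["age_days"] = df["age_days"].astype(int)
        if (df["age_days"] < 0).any():
            raise ParseError("age_days must be non-negative")
        df["sex"] = df["sex"].fillna("NA").astype(str)
        bad = set(df["sex"]) - VALID_SEX
        if bad:
            raise ParseError(f"invalid sex values: {sorted(bad)}")
        bad = set(df["condition"].astype(str)) - VALID_CONDITION
        if bad:
            raise ParseError(f"invalid condition values: {sorted(bad)}")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise ParseError("replicate must be a positive integer")
        bad = set(df["tissue"].astype(str)) - VALID_TISSUE
        if bad:
            raise ParseError(f"invalid tissue values: {sorted(bad)}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def ages(self) -> list[int]:
        return sorted(self.data["age_days"].unique())

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        keep = self.data[self.data["sample_id"].isin(set(sample_ids))]
        return SampleSheet(keep.copy())

    def samples_where(self, **criteria) -> list[str]:
        """Sample ids matching equality criteria on sheet columns."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in criteria.items():
            mask &= self.data[col] == val
        return list(self.data.loc[mask, "sample_id"])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Non-negative feature x sample table of read counts.

    ``kind`` records what the rows quantify: circRNA backsplice-junction
    reads (``circ``), all linear host-gene reads (``linear``), linear
    splice-junction reads (``linear_junction``), or intronic reads
    (``intron``).  Raw matrices must be integer-valued; normalized matrices
    hold positive reals.
    """

    values: pd.DataFrame
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KIND:
            raise ParseError(f"unknown feature kind {self.kind!r}")
        df = self.values
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise ParseError(f"duplicate feature ids: {dups}")
        if df.shape[0] == 0:
            raise ParseError("no features")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("non-numeric values in count matrix")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise ParseError(
                f"missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count {arr[r, c]} at feature {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        if not self.normalized and not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ParseError(
                f"raw counts must be integers; found {arr[r, c]} at feature "
                f"{df.index[r]!r}, sample {df.columns[c]!r}"
            )
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(feature_ids)].copy(), self.kind, self.normalized)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values[list(sample_ids)].copy(), self.kind, self.normalized)


def read_counts(path: str | Path, kind: str, normalized: bool = False) -> CountMatrix:
    """Read a feature x sample TSV (header = sample ids, first column = feature ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError(f"no features in {path}") from None
    if df.shape[0] == 0:
        raise ParseError(f"no features in {path}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any():
            row = df.index[bad.isna()][0]
            raise ParseError(f"non-numeric cell at feature {row!r}, sample {col!r}")
        df[col] = bad
    return CountMatrix(df, kind=kind, normalized=normalized)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# circRNA annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircAnnotation:
    """One circRNA: genomic interval of the backsplice, host gene, and
    mature length.

    ``length_nt`` is the mature circle length (sum of member exons), which
    for multi-exon circles differs from the genomic span ``end - start``.
    ``host_gene`` is a gene id or one of the :data:`SENTINEL_HOSTS` labels.
    """

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene: str
    n_annotated_junctions: int
    length_nt: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"{self.circ_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ParseError(f"{self.circ_id}: negative start")
        if self.strand not in {"+", "-"}:
            raise ParseError(f"{self.circ_id}: unknown strand {self.strand!r}")
        if self.length_nt < 1:
            raise ParseError(f"{self.circ_id}: length_nt must be >= 1")
        if not 0 <= self.n_annotated_junctions <= 2:
            raise ParseError(f"{self.circ_id}: n_annotated_junctions must be 0-2")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def has_sentinel_host(self) -> bool:
        return self.host_gene in SENTINEL_HOSTS


ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "strand", "circ_id", "host_gene",
    "n_annotated_junctions", "length_nt",
]


def read_circ_annotation(path: str | Path, one_based: bool = False) -> list[CircAnnotation]:
    """Read the 8-column circRNA annotation TSV.

    ``one_based=True`` converts 1-based end-inclusive coordinates (as
    exported by some backsplice callers) to the internal 0-based half-open
    convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS, comment="#")
    out: list[CircAnnotation] = []
    seen: set[str] = set()
    for rec in df.itertuples(index=False):
        start, end = int(rec.start), int(rec.end)
        if one_based:
            start, end = to_zero_based(start, end)
        ann = CircAnnotation(
            circ_id=str(rec.circ_id),
            chrom=str(rec.chrom),
            start=start,
            end=end,
            strand=str(rec.strand),
            host_gene=str(rec.host_gene),
            n_annotated_junctions=int(rec.n_annotated_junctions),
            length_nt=int(rec.length_nt),
        )
        if ann.circ_id in seen:
            raise ParseError(f"duplicate circ_id {ann.circ_id!r}")
        seen.add(ann.circ_id)
        out.append(ann)
    return out


def write_circ_annotation(anns: Iterable[CircAnnotation], path: str | Path) -> None:
    rows = [
        (a.chrom, a.start, a.end, a.strand, a.circ_id, a.host_gene,
         a.n_annotated_junctions, a.length_nt)
        for a in anns
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def annotation_index(anns: Iterable[CircAnnotation]) -> dict[str, CircAnnotation]:
    return {a.circ_id: a for a in anns}


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene as a merged exon chain; introns are the gaps between exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = _merge_intervals(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def mean_exon_length(self) -> float:
        return float(np.mean([e - s for s, e in self.exons]))


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if s >= e:
            raise ParseError(f"empty interval ({s}, {e})")
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_gene_models(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Parse exon records from a GTF into per-gene merged exon chains.

    GTF coordinates (1-based, end-inclusive) are converted to 0-based
    half-open on read.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    raw: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ParseError(f"exon without gene_id at {exon.seqid}:{exon.start}")
        start, end = to_zero_based(exon.start, exon.end)
        entry = raw.setdefault(
            gene_id, {"chrom": exon.seqid, "strand": exon.strand, "exons": []}
        )
        entry["exons"].append((start, end))
    for gene_id, entry in raw.items():
        genes[gene_id] = GeneModel(
            gene_id=gene_id, chrom=entry["chrom"], strand=entry["strand"],
            exons=entry["exons"],
        )
    return genes


def read_genome(fasta_path: str | Path) -> Mapping[str, str]:
    """Open a FASTA genome; returned mapping yields sequence strings."""
    from pyfaidx import Fasta

    class _FastaView(Mapping):
        def __init__(self, fa):
            self._fa = fa

        def __getitem__(self, key):
            return str(self._fa[key][:].seq)

        def __iter__(self):
            return iter(self._fa.keys())

        def __len__(self):
            return len(self._fa.keys())

    return _FastaView(Fasta(str(fasta_path), as_raw=False))


# ---------------------------------------------------------------------------
# PSI tables
# ---------------------------------------------------------------------------

PSI_EVENT_TYPES = frozenset({
    "alt_acceptor", "alt_donor", "exon_inclusion", "exon_exclusion",
    "intron_retention", "intron_exclusion",
})

PSI_META_COLUMNS = ["event_id", "event_type", "host_gene", "flank_of"]


def read_psi_table(path: str | Path) -> pd.DataFrame:
    """Read a PSI table: metadata columns then one PSI column per sample.

    ``flank_of`` ties intron-retention events to a circRNA flank, encoded
    as ``circ_id:upstream`` / ``circ_id:downstream`` (or ``.`` for none).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PSI_META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"PSI table missing columns: {missing}")
    bad = set(df["event_type"]) - PSI_EVENT_TYPES
    if bad:
        raise ParseError(f"unknown event types: {sorted(bad)}")
    sample_cols = [c for c in df.columns if c not in PSI_META_COLUMNS]
    vals = df[sample_cols].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ParseError("PSI values must lie in [0, 100]")
    return df


def write_psi_table(psi: pd.DataFrame, path: str | Path) -> None:
    psi.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# joining counts to the design
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedCounts:
    """A count matrix joined to its sample sheet, with grouping accessors."""

    counts: CountMatrix
    sheet: SampleSheet

    def __post_init__(self) -> None:
        missing = set(self.counts.sample_ids) - set(self.sheet.sample_ids)
        if missing:
            raise ParseError(
                f"samples absent from sample sheet: {sorted(missing)}"
            )
        # restrict the sheet view to the matrix's samples, matrix order
        self.sheet = self.sheet.subset(self.counts.sample_ids)

    def groupby(self, column: str) -> dict:
        """Map each level of a design column to the sub-matrix of its samples."""
        out = {}
        for level, sub in self.sheet.data.groupby(column):
            out[level] = self.counts.subset_samples(list(sub["sample_id"]))
        return out

    def samples_where(self, **criteria) -> list[str]:
        return self.sheet.samples_where(**criteria)


def join_samples(counts: CountMatrix, sheet: SampleSheet) -> AnnotatedCounts:
    """Attach design metadata to a count matrix.

    Samples in the sheet but not in the matrix are ignored; matrix samples
    missing from the sheet are an error (listing the missing ids).
    """
    return AnnotatedCounts(counts, sheet)
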