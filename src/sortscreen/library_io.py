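"""Reference library, sample metadata, count-table and gene-list I/O.

All on-disk formats are tab-separated UTF-8 text; lines starting with ``#``
are comments and are ignored on read. The canonical row order of a count
table is the library order, so serialisation is deterministic and
diff-friendly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL_GENE = "CONTROL"
CATEGORIES = ("druggable", "driver", "control")
TIMEPOINTS = ("t0", "t1", "t2")
POPULATIONS = ("low", "intermediate", "high", "unsorted")

_DNA = frozenset("ACGT")


class ValidationError(ValueError):
    """Structurally invalid library, metadata or count input."""


@dataclass(frozen=True)
class ShRNAConstruct:
    shrna_id: str
    gene: str
    sense_seq: str
    category: str


@dataclass
class ShRNALibrary:
    """A validated reference shRNA library.

    The backing frame has columns ``shrna_id, gene, sense_seq, category``
    and preserves library order; nontargeting controls carry
    ``gene == "CONTROL"`` and ``category == "control"``.
    """

    table: pd.DataFrame
    seq_len: int = 21

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.table["shrna_id"])

    @property
    def genes(self) -> pd.Index:
        """Unique targeted genes, controls excluded, in library order."""
        g = self.table.loc[self.table["gene"] != CONTROL_GENE, "gene"]
        return pd.Index(g.unique())

    @property
    def control_ids(self) -> pd.Index:
        return pd.Index(
            self.table.loc[self.table["gene"] == CONTROL_GENE, "shrna_id"]
        )

    def gene_of(self) -> pd.Series:
        """shrna_id -> gene symbol mapping."""
        return self.table.set_index("shrna_id")["gene"]

    def category_counts(self) -> dict:
        return self.table["category"].value_counts().to_dict()

    def __len__(self) -> int:
        return len(self.table)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        t = self.table
        required = ["shrna_id", "gene", "sense_seq", "category"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"library missing columns: {missing}")
        dup = t["shrna_id"][t["shrna_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate shrna_id values: {sorted(set(dup))[:10]}"
            )
        for row in t.itertuples():
            seq = row.sense_seq
            if len(seq) != self.seq_len or not _DNA.issuperset(seq):
                raise ValidationError(
                    f"row {row.Index} ({row.shrna_id}): sense_seq {seq!r} is "
                    f"not a {self.seq_len}-nt ACGT string"
                )
        bad_cat = set(t["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValidationError(f"unknown categories: {sorted(bad_cat)}")
        ctrl = t["category"] == "control"
        if not (t.loc[ctrl, "gene"] == CONTROL_GENE).all():
            raise ValidationError("control constructs must have gene CONTROL")
        if not (t.loc[~ctrl, "gene"] != CONTROL_GENE).all():
            raise ValidationError("non-control constructs map to gene CONTROL")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    timepoint: str
    population: str
    total_reads: int
    n_cells: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.population not in POPULATIONS:
            raise ValidationError(f"unknown population {self.population!r}")
        if self.total_reads <= 0 or self.n_cells <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: total_reads and n_cells must be > 0"
            )


@dataclass
class ScreenCounts:
    """Raw shRNA x sample count matrix with its sample metadata.

    Rows follow library order; every column corresponds to one SampleMeta.
    """

    matrix: pd.DataFrame
    samples: list[SampleMeta]
    library: ShRNALibrary

    def __post_init__(self) -> None:
        self.validate()

    def sample(self, timepoint: str, population: str) -> str:
        """Return the sample_id for a (timepoint, population) pair."""
        hits = [
            s.sample_id
            for s in self.samples
            if s.timepoint == timepoint and s.population == population
        ]
        if not hits:
            raise ValidationError(
                f"no sample for timepoint={timepoint}, population={population}"
            )
        return hits[0]

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise ValidationError(f"unknown sample_id {sample_id!r}")

    def validate(self) -> None:
        m = self.matrix
        lib_ids = self.library.shrna_ids
        if not m.index.equals(lib_ids):
            extra = m.index.difference(lib_ids)
            if len(extra):
                raise ValidationError(
                    f"count rows not in library: {list(extra[:10])}"
                )
            raise ValidationError("count rows must follow library order")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample_id in metadata")
        pairs = [(s.timepoint, s.population) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (timepoint, population) pair")
        unknown = m.columns.difference(sample_ids)
        if len(unknown):
            raise ValidationError(f"count columns not in metadata: {list(unknown)}")
        if not all(np.issubdtype(d, np.integer) for d in m.dtypes):
            raise ValidationError("counts must be integers")
        if (m.to_numpy() < 0).any():
            raise ValidationError("counts must be >= 0")


@dataclass
class GeneListPair:
    """Gold-standard essential (CCE) and nonessential (NE) gene sets."""

    cce: set = field(default_factory=set)
    ne: set = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.cce & self.ne
        if overlap:
            raise ValidationError(
                f"CCE and NE lists overlap: {sorted(overlap)[:10]}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _write_tsv(df: pd.DataFrame, path, comment: str | None = None,
               float_format: str = "%.10g") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  lineterminator="\n")


def read_library(path, seq_len: int = 21) -> ShRNALibrary:
    """Read a library TSV (columns shrna_id, gene, sense_seq, category)."""
    t = _read_tsv(path)
    lib = ShRNALibrary(t.reset_index(drop=True), seq_len=seq_len)
    logger.info("read library of %d constructs: %s", len(lib),
                lib.category_counts())
    return lib


def write_library(library: ShRNALibrary, path, comment: str | None = None) -> None:
    _write_tsv(library.table, path, comment)


def read_samples(path) -> list[SampleMeta]:
    t = _read_tsv(path)
    return [
        SampleMeta(r.sample_id, r.timepoint, r.population,
                   int(r.total_reads), int(r.n_cells))
        for r in t.itertuples()
    ]


def write_samples(samples: Sequence[SampleMeta], path,
                  comment: str | None = None) -> None:
    df = pd.DataFrame([vars(s) for s in samples])
    _write_tsv(df, path, comment)


def read_counts(path, meta: Sequence[SampleMeta],
                library: ShRNALibrary) -> ScreenCounts:
    """Read a count matrix TSV (first column shrna_id, one column per sample).

    Library shRNAs absent from the file become all-zero rows (with a logged
    warning): absence from sequencing is biological dropout, not missing
    data, so the low-count filter must see those rows.
    """
    t = _read_tsv(path)
    if t.columns[0] != "shrna_id":
        raise ValidationError("first column of a count table must be shrna_id")
    t = t.set_index("shrna_id")
    unknown_rows = t.index.difference(library.shrna_ids)
    if len(unknown_rows):
        raise ValidationError(
            f"count rows not in library: {list(unknown_rows[:10])}"
        )
    sample_ids = [s.sample_id for s in meta]
    unknown_cols = t.columns.difference(sample_ids)
    if len(unknown_cols):
        raise ValidationError(f"unknown sample ids: {list(unknown_cols)}")
    for col in t.columns:
        vals = pd.to_numeric(t[col], errors="coerce")
        if vals.isna().any() or (vals % 1 != 0).any() or (vals < 0).any():
            bad = t[col][vals.isna() | (vals % 1 != 0) | (vals < 0)]
            raise ValidationError(
                f"non-integer or negative count in column {col}: "
                f"{bad.iloc[0]!r} at {bad.index[0]}"
            )
        t[col] = vals.astype(np.int64)
    missing = library.shrna_ids.difference(t.index)
    if len(missing):
        logger.warning(
            "%d library shRNAs absent from count file; imputed as zero rows",
            len(missing),
        )
    t = t.reindex(library.shrna_ids, fill_value=0)
    t.index.name = "shrna_id"
    keep = [s for s in meta if s.sample_id in t.columns]
    return ScreenCounts(t[[s.sample_id for s in keep]], list(keep), library)


def write_counts(counts: ScreenCounts, path, comment: str | None = None) -> None:
    df = counts.matrix.reset_index()
    _write_tsv(df, path, comment)


def read_gene_lists(path) -> GeneListPair:
    """Read a two-column TSV: gene, set (CCE or NE)."""
    t = _read_tsv(path)
    if list(t.columns[:2]) != ["gene", "set"]:
        raise ValidationError("gene list file needs columns: gene, set")
    bad = set(t["set"]) - {"CCE", "NE"}
    if bad:
        raise ValidationError(f"unknown gene set labels: {sorted(bad)}")
    return GeneListPair(
        cce=set(t.loc[t["set"] == "CCE", "gene"]),
        ne=set(t.loc[t["set"] == "NE", "gene"]),
    )


def write_gene_lists(lists: GeneListPair, path, comment: str | None = None) -> None:
    df = pd.DataFrame(
        [(g, "CCE") for g in sorted(lists.cce)]
        + [(g, "NE") for g in sorted(lists.ne)],
        columns=["gene", "set"],
    )
    _write_tsv(df, path, comment)
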