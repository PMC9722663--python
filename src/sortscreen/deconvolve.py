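"""Paired-end read deconvolution against the hairpin library.

A read pair is counted for hairpin *s* only when the trimmed read-1 insert
and the reverse-complemented read-2 insert both match *s* uniquely within
the mismatch budget (concordant unique mapping). Matching is
substitution-only Hamming distance at fixed insert length; the classic
pigeonhole partition index makes it fast while a brute-force scan serves as
the test oracle.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library_io import ScreenCounts, ShRNALibrary, ValidationError
from .simulate import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, revcomp


@dataclass(frozen=True)
class MatchResult:
    status: str  # unique | ambiguous | unmatched
    shrna_id: str | None
    mismatches: int


@dataclass
class DeconvConfig:
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    insert_len: int = 21
    max_mismatch: int = 3
    adapter_window: int = 16  # adapter5 may start anywhere in the first 16 nt
    adapter_max_mismatch: int = 1
    barcodes: dict | None = None  # sample_id -> exact read-2 barcode


@dataclass
class DeconvStats:
    """Exact bookkeeping: every pair lands in exactly one bucket."""

    total: int = 0
    counted: int = 0
    discordant: int = 0
    ambiguous: int = 0
    unmatched: int = 0
    untrimmed: int = 0
    barcode_mismatch: int = 0

    def check(self) -> None:
        parts = (self.counted + self.discordant + self.ambiguous
                 + self.unmatched + self.untrimmed + self.barcode_mismatch)
        if parts != self.total:
            raise AssertionError(
                f"bookkeeping leak: {parts} classified != {self.total} total"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def trim_insert(read: str, adapter5: str, adapter3: str = "",
                insert_len: int = 21, window: int = 16,
                max_adapter_mismatch: int = 1) -> str | None:
    """Extract the hairpin insert that follows the 5' adapter.

    The adapter may start anywhere within the first ``window`` bases
    (stagger regions shift it) and is located allowing up to
    ``max_adapter_mismatch`` substitutions; the earliest, best-matching
    start wins. Returns None when the adapter is not found or the read is
    too short to contain a full insert.
    """
    la = len(adapter5)
    best = None  # (mismatches, start)
    limit = min(window, max(0, len(read) - la))
    for start in range(limit + 1):
        mm = 0
        seg = read[start:start + la]
        if len(seg) < la:
            break
        for a, b in zip(seg, adapter5):
            if a != b:
                mm += 1
                if mm > max_adapter_mismatch:
                    break
        if mm <= max_adapter_mismatch and (best is None or mm < best[0]):
            best = (mm, start)
            if mm == 0:
                break
    if best is None:
        return None
    insert = read[best[1] + la: best[1] + la + insert_len]
    if len(insert) < insert_len:
        return None
    return insert


class LibraryIndex:
    """Pigeonhole (partition) index for Hamming matching within a budget.

    The insert is cut into ``max_mismatch + 1`` contiguous chunks; any
    library sequence within the budget must match at least one chunk
    exactly, so chunk-exact lookups enumerate every candidate.
    """

    def __init__(self, library: ShRNALibrary, max_mismatch: int = 3):
        self.max_mismatch = max_mismatch
        self.seq_len = library.seq_len
        self.ids = list(library.shrna_ids)
        self.seqs = list(library.table["sense_seq"])
        self._arr = np.frombuffer(
            "".join(self.seqs).encode(), dtype=np.uint8
        ).reshape(len(self.seqs), self.seq_len)
        k = max_mismatch + 1
        bounds = np.linspace(0, self.seq_len, k + 1).astype(int)
        self._chunks = list(zip(bounds[:-1], bounds[1:]))
        self._tables: list[dict[str, list[int]]] = []
        for lo, hi in self._chunks:
            table: dict[str, list[int]] = {}
            for i, s in enumerate(self.seqs):
                table.setdefault(s[lo:hi], []).append(i)
            self._tables.append(table)

    def match(self, insert: str) -> MatchResult:
        """Unique / ambiguous / unmatched status of one insert.

        Unique requires exactly one library sequence within max_mismatch;
        a second hit within the budget voids the read (conservative reading
        of single-hairpin concordance).
        """
        if len(insert) != self.seq_len or not insert:
            return MatchResult("unmatched", None, 0)
        candidates: set[int] = set()
        for (lo, hi), table in zip(self._chunks, self._tables):
            candidates.update(table.get(insert[lo:hi], ()))
        if not candidates:
            return MatchResult("unmatched", None, 0)
        ins = np.frombuffer(insert.encode(), dtype=np.uint8)
        cand = np.fromiter(candidates, dtype=np.int64)
        d = (self._arr[cand] != ins).sum(axis=1)
        within = d <= self.max_mismatch
        n_hits = int(within.sum())
        if n_hits == 0:
            return MatchResult("unmatched", None, 0)
        if n_hits > 1:
            return MatchResult("ambiguous", None, 0)
        i = int(cand[within][0])
        return MatchResult("unique", self.ids[i], int(d[within][0]))


def match_insert(insert: str, index: LibraryIndex,
                 max_mismatch: int | None = None) -> MatchResult:
    """Functional wrapper around :meth:`LibraryIndex.match`."""
    if max_mismatch is not None and max_mismatch != index.max_mismatch:
        raise ValidationError(
            "max_mismatch differs from the index; rebuild the index"
        )
    return index.match(insert)


def _open_read(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_pairs(r1_stream, r2_stream) -> Iterator[tuple[int, str, str]]:
    it1 = FastqGeneralIterator(r1_stream)
    it2 = FastqGeneralIterator(r2_stream)
    n = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        n += 1
        if rec1 is None or rec2 is None:
            raise ValidationError(
                f"truncated FASTQ pair: mate missing at record {n}"
            )
        yield n, rec1[1], rec2[1]


def _process(pairs: Iterable[tuple[int, str, str]], index: LibraryIndex,
             config: DeconvConfig, route):
    """Shared pair loop; ``route(r2) -> (sample, r2_remainder) | None``."""
    stats_by: dict[str, DeconvStats] = {}
    counts: dict[str, dict[str, int]] = {}

    def stats_for(sample: str) -> DeconvStats:
        if sample not in stats_by:
            stats_by[sample] = DeconvStats()
            counts[sample] = {}
        return stats_by[sample]

    for _, r1, r2 in pairs:
        routed = route(r2)
        if routed is None:
            st = stats_for("__unrouted__")
            st.total += 1
            st.barcode_mismatch += 1
            continue
        sample, r2_body = routed
        st = stats_for(sample)
        st.total += 1
        ins1 = trim_insert(r1, config.adapter5, config.adapter3,
                           config.insert_len, config.adapter_window,
                           config.adapter_max_mismatch)
        ins2 = trim_insert(r2_body, config.adapter5, config.adapter3,
                           config.insert_len, config.adapter_window,
                           config.adapter_max_mismatch)
        if ins1 is None or ins2 is None:
            st.untrimmed += 1
            continue
        m1 = index.match(ins1)
        m2 = index.match(revcomp(ins2))
        if m1.status == "unique" and m2.status == "unique":
            if m1.shrna_id == m2.shrna_id:
                st.counted += 1
                c = counts[sample]
                c[m1.shrna_id] = c.get(m1.shrna_id, 0) + 1
            else:
                st.discordant += 1
        elif "ambiguous" in (m1.status, m2.status):
            st.ambiguous += 1
        else:
            st.unmatched += 1
    for st in stats_by.values():
        st.check()
    return counts, stats_by


def count_pairs(r1_stream, r2_stream, library: ShRNALibrary,
                config: DeconvConfig | None = None,
                sample_id: str = "sample"
                ) -> tuple[pd.Series, DeconvStats]:
    """Count concordant unique pairs for a single (already demultiplexed)
    sample; returns one count column aligned to library order plus exact
    pair bookkeeping."""
    config = config or DeconvConfig()
    index = LibraryIndex(library, config.max_mismatch)
    pairs = _read_pairs(r1_stream, r2_stream)
    counts, stats_by = _process(pairs, index, config,
                                route=lambda r2: (sample_id, r2))
    col = pd.Series(counts.get(sample_id, {}), dtype=np.int64)
    col = col.reindex(library.shrna_ids, fill_value=0).astype(np.int64)
    col.name = sample_id
    col.index.name = "shrna_id"
    return col, stats_by.get(sample_id, DeconvStats())


def count_multiplexed(r1_path, r2_path, library: ShRNALibrary,
                      meta, config: DeconvConfig
                      ) -> tuple[ScreenCounts, pd.DataFrame]:
    """Demultiplex a barcoded lane (exact barcode at the start of read 2)
    and count every sample; returns a ScreenCounts plus per-sample stats."""
    if not config.barcodes:
        raise ValidationError("count_multiplexed requires a barcode table")
    bc_len = len(next(iter(config.barcodes.values())))
    by_bc = {bc: sid for sid, bc in config.barcodes.items()}
    if len(by_bc) != len(config.barcodes):
        raise ValidationError("barcodes are not unique across samples")

    def route(r2: str):
        sid = by_bc.get(r2[:bc_len])
        if sid is None:
            return None
        return sid, r2[bc_len:]

    index = LibraryIndex(library, config.max_mismatch)
    with _open_read(r1_path) as f1, _open_read(r2_path) as f2:
        counts, stats_by = _process(_read_pairs(f1, f2), index, config, route)

    matrix = pd.DataFrame(index=library.shrna_ids)
    matrix.index.name = "shrna_id"
    keep = [s for s in meta if s.sample_id in config.barcodes]
    for s in keep:
        col = pd.Series(counts.get(s.sample_id, {}), dtype=np.int64)
        matrix[s.sample_id] = col.reindex(library.shrna_ids,
                                          fill_value=0).astype(np.int64)
    stats = pd.concat(
        {sid: st.to_frame() for sid, st in sorted(stats_by.items())},
        names=["sample_id", None],
    ).reset_index(level=0)
    return ScreenCounts(matrix, keep, library), stats.reset_index(drop=True)
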