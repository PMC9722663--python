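"""Count normalization, low-count filtering, bin-enrichment scores, and
second-best gene ranking with a permutation null.

The per-hairpin enrichment score at one time point is

    score_low  = log2((low + ψ) / (intermediate + high + ψ))
    score_high = log2((high + ψ) / (intermediate + low + ψ))

on normalized counts, where a high ``score_low`` marks a candidate
reporter *enhancer* (its knockdown pushes cells into the low gate) and a
high ``score_high`` a candidate *suppressor*. Hairpins whose raw
low+intermediate+high counts at that time point fall below the count
filter (default 100 reads) are excluded before scoring.

Gene scores use the second-best hairpin so that a single (possibly
off-target) hairpin can never carry a gene; significance comes from
permuting the hairpin-to-gene assignment while preserving each gene's
hairpin count, with the null pooled across genes of equal size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .library_io import (
    CONTROL_GENE,
    ScreenCounts,
    ShRNALibrary,
    ValidationError,
)

SORTED_BINS = ("low", "intermediate", "high")


@dataclass
class NormalizedCounts:
    """Counts scaled per sample: count / total_reads * n_cells.

    Keeps a reference to the raw counts because the low-count filter is
    defined on raw sequencing depth, not on the normalized scale.
    """

    matrix: pd.DataFrame
    factors: pd.DataFrame
    raw: ScreenCounts


def normalize(counts: ScreenCounts) -> NormalizedCounts:
    """Normalize each sample to its sequencing depth and sorted cell number.

    norm = count / total_reads × n_cells, column-wise; zero counts stay
    zero and doubling counts together with total_reads is a no-op.
    """
    rows = []
    norm = counts.matrix.astype(float).copy()
    for s in counts.samples:
        if s.total_reads == 0:
            raise ValidationError(f"sample {s.sample_id}: total_reads is 0")
        factor = s.n_cells / s.total_reads
        norm[s.sample_id] = counts.matrix[s.sample_id] * factor
        rows.append((s.sample_id, s.total_reads, s.n_cells, factor))
    factors = pd.DataFrame(
        rows, columns=["sample_id", "total_reads", "n_cells", "factor"]
    )
    return NormalizedCounts(norm, factors, counts)


def enrichment_scores(norm: NormalizedCounts, timepoint: str,
                      pseudocount: float = 0.5,
                      count_filter: int = 100) -> pd.DataFrame:
    """Per-hairpin low- and high-bin enrichment scores at one time point.

    Returns a frame (shrna_id, timepoint, score_low, score_high, filtered);
    filtered rows (raw bin sum < count_filter) carry NaN scores.
    """
    counts = norm.raw
    cols = {pop: counts.sample(timepoint, pop) for pop in SORTED_BINS}
    raw_sum = sum(counts.matrix[c] for c in cols.values())
    filtered = raw_sum < count_filter

    low = norm.matrix[cols["low"]]
    mid = norm.matrix[cols["intermediate"]]
    high = norm.matrix[cols["high"]]
    psi = pseudocount
    with np.errstate(divide="ignore"):
        score_low = np.log2((low + psi) / (mid + high + psi))
        score_high = np.log2((high + psi) / (mid + low + psi))
    out = pd.DataFrame({
        "shrna_id": counts.matrix.index,
        "timepoint": timepoint,
        "score_low": score_low.to_numpy(),
        "score_high": score_high.to_numpy(),
        "filtered": filtered.to_numpy(),
    })
    out.loc[out["filtered"], ["score_low", "score_high"]] = np.nan
    return out


_DIRECTION_COL = {"enhancer": "score_low", "suppressor": "score_high"}


def _gene_scores(scores: pd.DataFrame, library: ShRNALibrary,
                 direction: str) -> pd.DataFrame:
    """Unfiltered per-hairpin scores joined to their (non-control) genes."""
    if direction not in _DIRECTION_COL:
        raise ValidationError(f"unknown direction {direction!r}")
    col = _DIRECTION_COL[direction]
    df = scores.loc[~scores["filtered"], ["shrna_id", col]].copy()
    df["gene"] = df["shrna_id"].map(library.gene_of())
    df = df[df["gene"] != CONTROL_GENE]
    return df.rename(columns={col: "score"})


def second_best(scores: pd.DataFrame, library: ShRNALibrary, direction: str,
                min_shrnas: int = 2) -> pd.DataFrame:
    """Gene-level ranking by each gene's second-best hairpin score.

    Genes with fewer than ``min_shrnas`` unfiltered hairpins are reported
    unscored (NaN score, no rank). Rank 1 is the top gene; ties break by
    gene symbol so ranking is deterministic.
    """
    df = _gene_scores(scores, library, direction)
    grouped = df.groupby("gene")["score"]
    n = grouped.size()
    nlargest2 = grouped.nlargest(2).groupby("gene").min()
    out = pd.DataFrame({"gene": library.genes}).set_index("gene")
    out["n_shrnas"] = n.reindex(out.index).fillna(0).astype(int)
    out["second_best"] = nlargest2.reindex(out.index)
    out.loc[out["n_shrnas"] < min_shrnas, "second_best"] = np.nan
    scored = out[out["second_best"].notna()].sort_values(
        ["second_best", "gene"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = pd.Series(
        np.arange(1, len(scored) + 1), index=scored.index
    ).reindex(out.index)
    out = out.reset_index()
    out["direction"] = direction
    return out[["gene", "direction", "n_shrnas", "second_best", "rank"]]


def permutation_significance(scores: pd.DataFrame, library: ShRNALibrary,
                             direction: str, n_perm: int = 1000,
                             seed: int = 0,
                             min_shrnas: int = 2) -> pd.DataFrame:
    """Second-best ranking plus permutation p-values and BH FDR.

    The null permutes the hairpin-to-gene assignment while preserving each
    gene's number of unfiltered hairpins; a gene's p-value compares its
    observed second-best score with the pooled null of all same-size genes:

        p = (1 + #{null >= observed}) / (1 + n_perm * n_genes_of_that_size)
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    ranking = second_best(scores, library, direction, min_shrnas)
    df = _gene_scores(scores, library, direction)
    pool = df["score"].to_numpy()
    sizes = df.groupby("gene").size()

    # genes ordered by size so each permutation slices contiguous groups
    order = sizes.sort_values(kind="mergesort").index
    sizes_sorted = sizes.loc[order].to_numpy()
    offsets = np.concatenate([[0], np.cumsum(sizes_sorted)])
    scorable = sizes_sorted >= min_shrnas

    size_classes: dict[int, tuple[int, int]] = {}
    for k in np.unique(sizes_sorted[scorable]):
        idx = np.nonzero(sizes_sorted == k)[0]
        size_classes[int(k)] = (int(idx[0]), int(idx[-1] + 1))

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, list[np.ndarray]] = {k: [] for k in size_classes}
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        for k, (g0, g1) in size_classes.items():
            seg = perm[offsets[g0]:offsets[g1]].reshape(g1 - g0, k)
            # second-largest element per row
            null_by_size[k].append(np.partition(seg, k - 2, axis=1)[:, k - 2])
    null_sorted = {
        k: np.sort(np.concatenate(v)) for k, v in null_by_size.items()
    }

    ranking = ranking.set_index("gene")
    pvals = pd.Series(np.nan, index=ranking.index)
    for gene, row in ranking.iterrows():
        if not np.isfinite(row["second_best"]):
            continue
        null = null_sorted[int(row["n_shrnas"])]
        n_ge = len(null) - np.searchsorted(null, row["second_best"],
                                           side="left")
        pvals[gene] = (1 + n_ge) / (1 + len(null))
    ranking["perm_p"] = pvals
    mask = ranking["perm_p"].notna()
    fdr = pd.Series(np.nan, index=ranking.index)
    if mask.any():
        fdr[mask] = false_discovery_control(ranking.loc[mask, "perm_p"],
                                            method="bh")
    ranking["fdr"] = fdr
    return ranking.reset_index()[
        ["gene", "direction", "n_shrnas", "second_best", "rank", "perm_p",
         "fdr"]
    ]


def rank_all_timepoints(norm: NormalizedCounts, library: ShRNALibrary,
                        direction: str, timepoints=("t0", "t1", "t2"),
                        pseudocount: float = 0.5, count_filter: int = 100,
                        n_perm: int = 1000, seed: int = 0,
                        min_shrnas: int = 2) -> dict[str, pd.DataFrame]:
    """Convenience: full ranking with significance at every time point."""
    out = {}
    for i, tp in enumerate(timepoints):
        sc = enrichment_scores(norm, tp, pseudocount, count_filter)
        out[tp] = permutation_significance(
            sc, library, direction, n_perm=n_perm, seed=seed + 101 * i,
            min_shrnas=min_shrnas,
        )
    return out
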