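"""Screen quality control via essential-gene dropout.

A screen that captures biology must deplete gold-standard constitutive
core essential (CCE) genes between the first and last unsorted time
points while leaving nonessential (NE) genes alone. Hairpins get a
log2 fold change t2/t0 on normalized unsorted counts; genes get their
best (most negative) and second-best depletion fold changes, and the
rank distributions of the CCE and NE sets are each compared against all
genes with a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .library_io import CONTROL_GENE, GeneListPair, ValidationError
from .score import NormalizedCounts


@dataclass
class DepletionTable:
    per_shrna: pd.DataFrame  # shrna_id, gene, lfc
    per_gene: pd.DataFrame   # gene, n_shrnas, best_lfc, second_best_lfc, rank


@dataclass
class QCReport:
    cce_stat: float
    cce_p: float
    ne_stat: float
    ne_p: float
    n_cce: int
    n_ne: int
    n_genes: int
    cdf: pd.DataFrame  # rank grid with empirical CDFs per gene set

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "set": "CCE", "n": self.n_cce, "ks_stat": self.cce_stat,
            "ks_p": self.cce_p,
        }, {
            "set": "NE", "n": self.n_ne, "ks_stat": self.ne_stat,
            "ks_p": self.ne_p,
        }])


def depletion_lfc(norm: NormalizedCounts,
                  pseudocount: float = 0.5) -> DepletionTable:
    """Per-hairpin and per-gene t2/t0 depletion on unsorted pools.

    lfc = log2((norm_t2 + ψ) / (norm_t0 + ψ)); a gene's best fold change
    is its most negative one, so second_best_lfc >= best_lfc always.
    """
    counts = norm.raw
    try:
        c0 = counts.sample("t0", "unsorted")
        c2 = counts.sample("t2", "unsorted")
    except ValidationError as err:
        raise ValidationError(f"depletion QC needs unsorted t0/t2: {err}")
    psi = pseudocount
    lfc = np.log2((norm.matrix[c2] + psi) / (norm.matrix[c0] + psi))
    gene_of = counts.library.gene_of()
    per_shrna = pd.DataFrame({
        "shrna_id": counts.matrix.index,
        "gene": counts.matrix.index.map(gene_of),
        "lfc": lfc.to_numpy(),
    })
    tg = per_shrna[per_shrna["gene"] != CONTROL_GENE]
    grouped = tg.groupby("gene")["lfc"]
    smallest2 = grouped.nsmallest(2).groupby("gene")
    per_gene = pd.DataFrame({
        "n_shrnas": grouped.size(),
        "best_lfc": smallest2.min(),
        "second_best_lfc": smallest2.max(),
    })
    # depletion rank: 1 = most depleted by the second-best hairpin
    order = per_gene.sort_values(
        ["second_best_lfc", "best_lfc"], kind="mergesort"
    ).index
    per_gene.loc[order, "rank"] = np.arange(1, len(per_gene) + 1)
    per_gene["rank"] = per_gene["rank"].astype(int)
    return DepletionTable(per_shrna, per_gene.reset_index())


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.sort(values)
    return np.searchsorted(values, grid, side="right") / len(values)


def essential_depletion_test(table: DepletionTable, lists: GeneListPair,
                             gene_scores_source: str = "rank",
                             min_genes: int = 20) -> QCReport:
    """KS comparison of CCE and NE gene depletion against all genes.

    ``gene_scores_source='rank'`` compares depletion ranks (matching the
    rank-CDF view of screen QC); ``'lfc'`` compares raw second-best fold
    changes instead.
    """
    if gene_scores_source not in ("rank", "lfc"):
        raise ValidationError(
            f"unknown gene_scores_source {gene_scores_source!r}"
        )
    col = "rank" if gene_scores_source == "rank" else "second_best_lfc"
    pg = table.per_gene.set_index("gene")
    cce = pg.index.intersection(sorted(lists.cce))
    ne = pg.index.intersection(sorted(lists.ne))
    if len(cce) == 0 or len(ne) == 0:
        raise ValidationError("gene lists do not overlap the screen")
    if len(cce) < min_genes or len(ne) < min_genes:
        raise ValidationError(
            f"need >= {min_genes} genes per list, got CCE={len(cce)}, "
            f"NE={len(ne)}"
        )
    all_vals = pg[col].to_numpy(float)
    cce_vals = pg.loc[cce, col].to_numpy(float)
    ne_vals = pg.loc[ne, col].to_numpy(float)
    r_cce = ks_2samp(cce_vals, all_vals, alternative="two-sided")
    r_ne = ks_2samp(ne_vals, all_vals, alternative="two-sided")

    grid = np.sort(np.unique(all_vals))
    cdf = pd.DataFrame({
        col: grid,
        "cdf_all": _ecdf_on_grid(all_vals, grid),
        "cdf_cce": _ecdf_on_grid(cce_vals, grid),
        "cdf_ne": _ecdf_on_grid(ne_vals, grid),
    })
    return QCReport(
        cce_stat=float(r_cce.statistic), cce_p=float(r_cce.pvalue),
        ne_stat=float(r_ne.statistic), ne_p=float(r_ne.pvalue),
        n_cce=len(cce), n_ne=len(ne), n_genes=len(pg), cdf=cdf,
    )


def plot_depletion_cdf(report: QCReport, path) -> None:
    """Rank-CDF plot of essential vs nonessential depletion (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    x = report.cdf.iloc[:, 0]
    ax.plot(x, report.cdf["cdf_all"], color="grey", label="all genes")
    ax.plot(x, report.cdf["cdf_cce"], color="crimson",
            label=f"CCE (p={report.cce_p:.2e})")
    ax.plot(x, report.cdf["cdf_ne"], color="royalblue",
            label=f"NE (p={report.ne_p:.2e})")
    ax.set_xlabel("depletion rank (1 = most depleted)")
    ax.set_ylabel("cumulative fraction")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
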