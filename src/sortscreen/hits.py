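"""Hit calling with the time-point consistency rule.

A gene is a called hit when it is significant at both later time points
but *not* at the baseline: significance at t0 — before knockdown
phenotypes have developed — flags sorting or library artifacts rather
than reporter biology, so (¬t0 ∧ t1 ∧ t2) is the only calling pattern.
Enhancers are read from the low-bin ranking, suppressors from the
high-bin ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library_io import TIMEPOINTS, ValidationError


def _significant(ranking: pd.DataFrame, fdr: float | None,
                 top_k: int | None) -> pd.Series:
    if top_k is not None:
        sig = ranking["rank"] <= top_k
    else:
        sig = ranking["fdr"] <= fdr
    return sig.fillna(False)


def call_hits(rankings: dict[str, pd.DataFrame], direction: str,
              fdr: float | None = 0.25, top_k: int | None = None,
              t0_fdr: float | None = None,
              t0_top_k: int | None = None) -> pd.DataFrame:
    """Apply the consistency rule to per-time-point gene rankings.

    ``rankings`` maps t0/t1/t2 to frames from the scoring stage (columns
    gene, rank, and fdr when FDR mode is used). Thresholding is either
    ``fdr <= fdr`` or ``rank <= top_k`` (top_k wins when both are given);
    the baseline threshold defaults to the t1/t2 one but is separately
    configurable. The output keeps full per-time-point evidence so hits
    can be re-thresholded without rescoring.
    """
    missing = [tp for tp in TIMEPOINTS if tp not in rankings]
    if missing:
        raise ValidationError(f"missing time points for hit calling: {missing}")
    if fdr is None and top_k is None:
        raise ValidationError("provide an fdr or top_k threshold")
    if t0_fdr is None and t0_top_k is None:
        t0_fdr, t0_top_k = fdr, top_k

    frames = {}
    for tp in TIMEPOINTS:
        r = rankings[tp].set_index("gene")
        frames[tp] = r
    genes = frames["t1"].index
    out = pd.DataFrame(index=genes)
    out["direction"] = direction
    sig = {}
    for tp in TIMEPOINTS:
        r = frames[tp].reindex(genes)
        out[f"rank_{tp}"] = r["rank"]
        out[f"fdr_{tp}"] = r.get("fdr", np.nan)
        if tp == "t0":
            sig[tp] = _significant(r, t0_fdr, t0_top_k)
        else:
            sig[tp] = _significant(r, fdr, top_k)
        out[f"sig_{tp}"] = sig[tp].to_numpy()
    out["called"] = (~sig["t0"] & sig["t1"] & sig["t2"]).to_numpy()
    order = out["rank_t2"].fillna(np.inf)
    out = out.loc[order.sort_values(kind="mergesort").index]
    return out.reset_index().rename(columns={"index": "gene"})
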