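"""Expression-stratified survival comparison.

Patients are split into low/high expression groups at a cutoff chosen by
scanning candidate thresholds and minimising the two-sided log-rank
p-value ("optimal cutoff"). The minimised p-value is selection-biased by
construction — the scan performs many implicit tests — and the report
flags it as such rather than correcting it, matching the convention of
the optimal-cutpoint literature this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .library_io import ValidationError, _read_tsv, _write_tsv


def read_cohort(path) -> pd.DataFrame:
    """Read a patient table (patient, expr, time, event) and collapse
    repeated samples per patient by averaging expression."""
    t = _read_tsv(path)
    need = {"patient", "expr", "time", "event"}
    if not need.issubset(t.columns):
        raise ValidationError(f"cohort table needs columns {sorted(need)}")
    t = t.astype({"expr": float, "time": float, "event": int})
    return aggregate_patients(t)


def aggregate_patients(table: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: expression averaged over that patient's
    samples; follow-up time and event must be consistent within patient."""
    if (table["time"] <= 0).any():
        raise ValidationError("follow-up times must be positive")
    g = table.groupby("patient", sort=True)
    if (g["time"].nunique() > 1).any() or (g["event"].nunique() > 1).any():
        raise ValidationError(
            "inconsistent follow-up time or event within a patient"
        )
    out = g.agg(expr=("expr", "mean"), time=("time", "first"),
                event=("event", "first")).reset_index()
    return out


def logrank(group_a: pd.DataFrame, group_b: pd.DataFrame
            ) -> tuple[float, float]:
    """Two-sided two-sample log-rank test; returns (chi2, p).

    Ties are handled by the usual simultaneous-event (hypergeometric)
    convention of the Mantel–Haenszel statistic.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValidationError("both groups must be non-empty")
    if group_a["event"].sum() + group_b["event"].sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    res = logrank_test(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CutoffResult:
    cutoff: float
    p_min: float
    chi2: float
    n_low: int
    n_high: int
    curve: pd.DataFrame  # cutoff, n_low, n_high, chi2, p
    selection_biased: bool = True  # p_min is a minimum over many tests


def optimal_cutoff(cohort: pd.DataFrame, scan: tuple[float, float] = (0.2, 0.8),
                   min_group: int = 8) -> CutoffResult:
    """Scan expression cutoffs and minimise the log-rank p-value.

    Candidates are the observed expression values inside the ``scan``
    quantile window whose low (expr <= cutoff) / high (expr > cutoff)
    split leaves at least ``min_group`` patients per arm. Deterministic:
    on p ties the smallest cutoff wins. A degenerate window like
    (0.5, 0.5) collapses to the split nearest the median.
    """
    if len(cohort) < 2 * min_group:
        raise ValidationError(
            f"need >= {2 * min_group} patients, got {len(cohort)}"
        )
    expr = cohort["expr"].to_numpy()
    lo, hi = np.quantile(expr, scan)
    values = np.unique(expr)
    candidates = values[(values >= lo) & (values <= hi)]
    if len(candidates) == 0:
        centre = (lo + hi) / 2
        candidates = values[[np.argmin(np.abs(values - centre))]]
    rows = []
    best = None
    for c in candidates:
        low = cohort[cohort["expr"] <= c]
        high = cohort[cohort["expr"] > c]
        if len(low) < min_group or len(high) < min_group:
            continue
        chi2, p = logrank(low, high)
        rows.append((c, len(low), len(high), chi2, p))
        if best is None or p < best[4]:
            best = rows[-1]
    if best is None:
        raise ValidationError(
            "no admissible cutoff in the scan window; relax min_group or scan"
        )
    curve = pd.DataFrame(
        rows, columns=["cutoff", "n_low", "n_high", "chi2", "p"]
    )
    return CutoffResult(cutoff=float(best[0]), p_min=float(best[4]),
                        chi2=float(best[3]), n_low=int(best[1]),
                        n_high=int(best[2]), curve=curve)


def write_report(result: CutoffResult, path, comment: str | None = None) -> None:
    head = pd.DataFrame([{
        "cutoff": result.cutoff, "p_min": result.p_min, "chi2": result.chi2,
        "n_low": result.n_low, "n_high": result.n_high,
        "selection_biased": result.selection_biased,
    }])
    note = "p_min is minimised over the cutoff scan (selection-biased)"
    full_comment = note if comment is None else f"{comment}\n{note}"
    _write_tsv(head, path, full_comment)
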