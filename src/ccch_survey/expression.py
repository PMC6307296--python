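"""Relative qPCR expression by the 2^-ΔΔCT method.

ΔCT normalizes a target gene's mean quantification cycle to a reference
gene within one (condition, time) stratum; ΔΔCT contrasts a treated stratum
with its time-matched untreated control; fold change is 2^-ΔΔCT. Replicates
are averaged on the Cq scale before ΔCT, and dispersion is reported as the
standard deviation of per-replicate fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

CONTROL_CONDITION = "control"


@dataclass(frozen=True)
class FoldChangeResult:
    gene_id: str
    condition: str
    time_h: float
    dct_treated: float
    dct_control: float
    ddct: float
    fold: float
    fold_sd: Optional[float] = None


def _mean_cq(stratum: pd.DataFrame, gene_id: str, what: str) -> float:
    rows = stratum[stratum["gene_id"] == gene_id]
    if rows.empty:
        raise ValueError(what)
    return float(rows["cq"].mean())


def ddct(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str = CONTROL_CONDITION,
) -> list[FoldChangeResult]:
    """Compute 2^-ΔΔCT fold changes for every (gene, condition, time).

    ``table`` holds columns gene_id, condition, time_h, replicate, cq,
    is_reference. The reference gene must be present in every stratum and a
    control stratum must exist at every treated time point; violations raise
    ``ValueError`` naming the stratum.
    """
    results: list[FoldChangeResult] = []
    treated = table[table["condition"] != control_condition]
    for (condition, time_h), stratum in treated.groupby(["condition", "time_h"], sort=True):
        control = table[
            (table["condition"] == control_condition) & (table["time_h"] == time_h)
        ]
        if control.empty:
            raise ValueError(f"no matched control stratum at time {time_h} h for {condition}")
        ref_treated = _mean_cq(
            stratum, reference_gene,
            f"reference gene {reference_gene!r} missing in ({condition}, {time_h} h)",
        )
        ref_control = _mean_cq(
            control, reference_gene,
            f"reference gene {reference_gene!r} missing in (control, {time_h} h)",
        )
        for gene_id in sorted(stratum.loc[~stratum["is_reference"], "gene_id"].unique()):
            if gene_id == reference_gene:
                continue
            dct_treated = _mean_cq(
                stratum, gene_id, f"gene {gene_id!r} missing in ({condition}, {time_h} h)"
            ) - ref_treated
            dct_control = _mean_cq(
                control, gene_id, f"gene {gene_id!r} missing in (control, {time_h} h)"
            ) - ref_control
            ddct_value = dct_treated - dct_control
            # per-replicate folds for dispersion (replicates paired by index)
            rep_folds = []
            t_rows = stratum[stratum["gene_id"] == gene_id].sort_values("replicate")
            c_rows = control[control["gene_id"] == gene_id].sort_values("replicate")
            tr_ref = stratum[stratum["gene_id"] == reference_gene].sort_values("replicate")
            co_ref = control[control["gene_id"] == reference_gene].sort_values("replicate")
            k = min(len(t_rows), len(c_rows), len(tr_ref), len(co_ref))
            for i in range(k):
                d = (
                    (t_rows["cq"].iloc[i] - tr_ref["cq"].iloc[i])
                    - (c_rows["cq"].iloc[i] - co_ref["cq"].iloc[i])
                )
                rep_folds.append(2.0 ** (-d))
            fold_sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else None
            results.append(
                FoldChangeResult(
                    gene_id=gene_id,
                    condition=str(condition),
                    time_h=float(time_h),
                    dct_treated=dct_treated,
                    dct_control=dct_control,
                    ddct=ddct_value,
                    fold=2.0 ** (-ddct_value),
                    fold_sd=fold_sd,
                )
            )
    return results


def results_frame(results: list[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.condition, r.time_h, r.dct_treated, r.dct_control,
             r.ddct, r.fold, r.fold_sd)
            for r in results
        ],
        columns=["gene_id", "condition", "time_h", "dct_treated", "dct_control",
                 "ddct", "fold", "fold_sd"],
    )


def classify_response(
    results: list[FoldChangeResult],
    induction_threshold: float = 2.0,
    suppression_threshold: float = 0.5,
) -> dict[tuple[str, str], str]:
    """Label each (gene, condition) induced / suppressed / unchanged.

    Induced when the maximal fold over the time course reaches the induction
    threshold; suppressed when the minimal fold falls to the suppression
    threshold; induction takes precedence when both occur.
    """
    if induction_threshold <= 0 or suppression_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if induction_threshold <= suppression_threshold:
        raise ValueError("induction threshold must exceed suppression threshold")
    series: dict[tuple[str, str], list[float]] = {}
    for r in results:
        series.setdefault((r.gene_id, r.condition), []).append(r.fold)
    labels: dict[tuple[str, str], str] = {}
    for key, folds in series.items():
        if max(folds) >= induction_threshold:
            labels[key] = "induced"
        elif min(folds) <= suppression_threshold:
            labels[key] = "suppressed"
        else:
            labels[key] = "unchanged"
    return labels


def peak_time(results: list[FoldChangeResult]) -> float:
    """Time of maximal fold for one gene x condition series (ties: earliest)."""
    if len(results) < 2:
        raise ValueError("peak detection needs at least two time points")
    keys = {(r.gene_id, r.condition) for r in results}
    if len(keys) != 1:
        raise ValueError("peak_time expects a single gene x condition series")
    ordered = sorted(results, key=lambda r: r.time_h)
    best = max(ordered, key=lambda r: r.fold)  # max() keeps the earliest tie
    return best.time_h
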