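"""Relative qPCR quantification by the 2^-ddCt method.

Cycle-threshold (Ct) tables carry one row per (gene, condition,
biological replicate, technical replicate). Technical replicates are
averaged on the Ct scale, then per biological replicate

    dCt  = Ct_target - Ct_reference
    ddCt = mean dCt(condition) - mean dCt(calibrator)
    fold = 2^-ddCt

assuming a doubling per cycle (no efficiency correction). The reference
gene is picked from a candidate housekeeping panel (gapdh, ef1a, actb) as
the one whose condition-mean Ct varies least across conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_CANDIDATES",
    "select_reference",
    "ddct",
    "fold_vs_reference_day",
]

REFERENCE_CANDIDATES = ("gapdh", "ef1a", "actb")

_REQUIRED = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def _check(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    if not np.isfinite(ct["ct"].to_numpy(float)).all():
        raise ValueError("non-finite Ct values")
    return ct


def _tech_averaged(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per (gene, condition, bio_rep)."""
    return (
        _check(ct)
        .groupby(["gene", "condition", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )


def select_reference(
    ct: pd.DataFrame, candidates: tuple[str, ...] = REFERENCE_CANDIDATES
) -> str:
    """Most stably expressed candidate: minimal SD of mean Ct across conditions.

    Candidates without complete condition coverage are excluded; ties break
    by candidate list order.
    """
    avg = _tech_averaged(ct)
    conditions = set(avg["condition"])
    best: tuple[float, int] | None = None
    best_gene = None
    for i, gene in enumerate(candidates):
        sub = avg[avg["gene"] == gene]
        if set(sub["condition"]) != conditions or sub.empty:
            continue
        cond_means = sub.groupby("condition")["ct"].mean()
        sd = float(cond_means.std(ddof=1)) if len(cond_means) > 1 else 0.0
        key = (sd, i)
        if best is None or key < best:
            best = key
            best_gene = gene
    if best_gene is None:
        raise ValueError(f"no candidate in {candidates} has complete Ct coverage")
    return best_gene


def ddct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_condition: str,
) -> pd.DataFrame:
    """Fold change per condition relative to the calibrator.

    Returns one row per condition with the fold change 2^-ddCt (exactly 1
    for the calibrator by construction), plus mean and SD of the
    per-biological-replicate folds and the replicate count.
    """
    avg = _tech_averaged(ct)
    tgt = avg[avg["gene"] == target_gene]
    ref = avg[avg["gene"] == reference_gene]
    if tgt.empty:
        raise ValueError(f"target gene {target_gene!r} absent from Ct table")
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    merged = tgt.merge(
        ref, on=["condition", "bio_rep"], suffixes=("_target", "_ref")
    )
    if merged.empty:
        raise ValueError("target and reference share no (condition, bio_rep) cells")
    merged["dct"] = merged["ct_target"] - merged["ct_ref"]
    if calibrator_condition not in set(merged["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} missing")
    cal_mean = merged.loc[merged["condition"] == calibrator_condition, "dct"].mean()

    rows = []
    for condition, grp in merged.groupby("condition", sort=False):
        ddct_val = grp["dct"].mean() - cal_mean
        rep_folds = np.power(2.0, -(grp["dct"].to_numpy(float) - cal_mean))
        rows.append(
            {
                "gene": target_gene,
                "condition": condition,
                "fold_change": float(2.0 ** -ddct_val),
                "fold_mean": float(rep_folds.mean()),
                "fold_sd": float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else 0.0,
                "n_bio_reps": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def fold_vs_reference_day(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    reference_day: str = "6dpf",
) -> pd.DataFrame:
    """Developmental day-series fold changes relative to a reference day.

    Condition labels are day labels (e.g. 6dpf..10dpf); this is ``ddct``
    with the calibrator set to the reference day.
    """
    days = set(_check(ct)["condition"])
    if reference_day not in days:
        raise ValueError(f"reference day {reference_day!r} not among conditions {sorted(days)}")
    return ddct(ct, target_gene, reference_gene, calibrator_condition=reference_day)
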