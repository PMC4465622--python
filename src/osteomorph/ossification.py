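"""Ordinal ossification scoring of cranial bone elements.

Each bone element of a stained larva is assigned one of four ordered
developmental categories relative to a typical control larva of the same
age: ``absent < early < advanced < over``. Categories are analyst-assigned;
this module never infers them from coordinates.

Per-larva summaries use the weighted global score — the sum over scored
elements of the category weight (default 0/1/2/4) — and cohort summaries
use per-element cumulated frequency tables. Bilateral elements may be
pooled (their two sides merged into one count stream) for frequency
reporting, as side differences are not of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import significance_stars
from scipy import stats

__all__ = [
    "CATEGORIES",
    "OssificationRecord",
    "ScoreWeights",
    "pool_bilateral",
    "frequency_table",
    "global_score",
    "global_scores",
    "compare_global_scores",
]

#: Ordered ossification categories, least to most developed.
CATEGORIES = ("absent", "early", "advanced", "over")
SIDES = ("up", "down", "unpaired", "pooled")


@dataclass(frozen=True)
class OssificationRecord:
    larva_id: str
    condition: str
    structure: str
    side: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass(frozen=True)
class ScoreWeights:
    """Integer weights per category; must be strictly increasing."""

    absent: int = 0
    early: int = 1
    advanced: int = 2
    over: int = 4

    def __post_init__(self) -> None:
        w = self.as_tuple()
        if not all(a < b for a, b in zip(w, w[1:])):
            raise ValueError(f"weights must strictly increase with category: {w}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.absent, self.early, self.advanced, self.over)

    def __getitem__(self, category: str) -> int:
        return dict(zip(CATEGORIES, self.as_tuple()))[category]


def pool_bilateral(records: list[OssificationRecord]) -> list[OssificationRecord]:
    """Merge the two sides of each paired structure into one pooled stream.

    Both sides' records are kept (n doubles for paired structures) but
    relabelled ``side='pooled'``; unpaired records pass through. A structure
    carrying both sided and unpaired records is a labelling error.
    """
    sides_seen: dict[str, set[str]] = {}
    for r in records:
        sides_seen.setdefault(r.structure, set()).add(r.side)
    for structure, seen in sides_seen.items():
        if "unpaired" in seen and seen & {"up", "down"}:
            raise ValueError(
                f"structure {structure!r} mixes unpaired and sided records"
            )
    out = []
    for r in records:
        if r.side in ("up", "down"):
            out.append(
                OssificationRecord(r.larva_id, r.condition, r.structure, "pooled", r.category)
            )
        else:
            out.append(r)
    return out


def frequency_table(
    records: list[OssificationRecord],
    conditions: list[str] | None = None,
) -> pd.DataFrame:
    """Counts and cumulated frequencies (%) per structure x condition x category.

    Percentages are rounded to 2 decimal places; within each structure /
    condition cell they sum to 100 up to rounding. ``n`` is the number of
    scored elements in the cell (doubled for pooled bilateral structures).
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "structure": [r.structure for r in records],
            "condition": [r.condition for r in records],
            "category": [r.category for r in records],
        }
    )
    if conditions is not None:
        df = df[df["condition"].isin(conditions)]
    rows = []
    cond_order = conditions or list(dict.fromkeys(df["condition"]))
    for structure in dict.fromkeys(df["structure"]):
        for condition in cond_order:
            cell = df[(df["structure"] == structure) & (df["condition"] == condition)]
            if cell.empty:
                continue
            n = len(cell)
            for category in CATEGORIES:
                count = int((cell["category"] == category).sum())
                rows.append(
                    {
                        "structure": structure,
                        "condition": condition,
                        "category": category,
                        "count": count,
                        "pct": round(100.0 * count / n, 2),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def global_score(
    records: list[OssificationRecord], weights: ScoreWeights = ScoreWeights()
) -> int:
    """Weighted global ossification score for one larva.

    Sum of the category weight over all scored elements, sides contributing
    separately. Bounded by ``over_weight * n_elements``; an element scored
    twice on the same side is an error.
    """
    larvae = {r.larva_id for r in records}
    if len(larvae) > 1:
        raise ValueError(f"records span multiple larvae: {sorted(larvae)}")
    seen: set[tuple[str, str]] = set()
    total = 0
    for r in records:
        key = (r.structure, r.side)
        if key in seen:
            raise ValueError(
                f"larva {r.larva_id!r}: {r.structure}/{r.side} scored twice"
            )
        seen.add(key)
        total += weights[r.category]
    return total


def global_scores(
    records: list[OssificationRecord], weights: ScoreWeights = ScoreWeights()
) -> pd.DataFrame:
    """Per-larva global scores: DataFrame(larva_id, condition, score)."""
    by_larva: dict[str, list[OssificationRecord]] = {}
    for r in records:
        by_larva.setdefault(r.larva_id, []).append(r)
    rows = [
        {
            "larva_id": lid,
            "condition": recs[0].condition,
            "score": global_score(recs, weights),
        }
        for lid, recs in by_larva.items()
    ]
    return pd.DataFrame(rows)


def compare_global_scores(scores: pd.DataFrame) -> dict:
    """Compare per-condition global scores.

    Two conditions: Welch t-test; three or more: one-way ANOVA. Returns the
    per-condition mean +/- SD (with the formatted ``m±s`` string), the test
    name, statistic, p-value and significance stars.
    """
    groups = list(dict.fromkeys(scores["condition"]))
    samples = {
        g: scores.loc[scores["condition"] == g, "score"].to_numpy(float) for g in groups
    }
    for g, s in samples.items():
        if len(s) < 2:
            raise ValueError(f"condition {g!r} has fewer than 2 larvae")
    summary = {
        g: {
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)),
            "n": int(len(s)),
            "formatted": f"{s.mean():.1f}±{s.std(ddof=1):.1f}",
        }
        for g, s in samples.items()
    }
    if len(groups) == 2:
        stat, p = stats.ttest_ind(samples[groups[0]], samples[groups[1]], equal_var=False)
        test = "welch_t"
    else:
        stat, p = stats.f_oneway(*samples.values())
        test = "anova"
    return {
        "conditions": summary,
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "significant": bool(p < 0.05),
        "stars": significance_stars(p),
    }
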