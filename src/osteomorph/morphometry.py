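"""Pixel-scale morphometry on annotated larvae.

Coordinates follow the image convention (origin top-left, y downward) but
every quantity computed here — Euclidean distances in pixels, interior
angles in radians, triangle areas in squared pixels — is invariant under
that choice. No Procrustes superimposition or mm calibration is applied:
values stay on the raw pixel scale of each image, and measures touching a
missing landmark are left missing rather than imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import LandmarkOntology

__all__ = [
    "AnnotatedLarva",
    "distance",
    "angle",
    "triangle_area",
    "extract_measures",
    "screen_measures_pca",
    "compare_measures",
    "compare_measures_anova",
    "significance_stars",
]

Point = tuple[float, float]


@dataclass
class AnnotatedLarva:
    """One specimen: condition label, stain, and named 2-D pixel coordinates."""

    larva_id: str
    condition: str
    stain: str  # "alcian_blue" (cartilage) or "alizarin_red" (bone)
    coords: dict[str, Point] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (x, y) in self.coords.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(
                    f"larva {self.larva_id!r}: non-finite coordinate for {name!r}"
                )


def distance(p: Point, q: Point) -> float:
    """Euclidean distance in pixels."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def angle(vertex: Point, p: Point, q: Point, names: tuple[str, str, str] | None = None) -> float:
    """Interior angle at ``vertex`` between the rays to ``p`` and ``q``, in [0, pi]."""
    u = (p[0] - vertex[0], p[1] - vertex[1])
    v = (q[0] - vertex[0], q[1] - vertex[1])
    nu = math.hypot(*u)
    nv = math.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        labels = names or ("vertex", "p", "q")
        coincident = labels[1] if nu == 0.0 else labels[2]
        raise ValueError(
            f"degenerate angle: landmark {coincident!r} coincides with vertex {labels[0]!r}"
        )
    cosang = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    return math.acos(min(1.0, max(-1.0, cosang)))


def triangle_area(a: Point, b: Point, c: Point) -> float:
    """Unsigned triangle area (shoelace / 2) in squared pixels."""
    return abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])) / 2.0


_STAIN_FOR_PREFIX = {"cartilage": "alcian_blue", "bone": "alizarin_red"}


def extract_measures(
    larvae: list[AnnotatedLarva], ontology: LandmarkOntology
) -> pd.DataFrame:
    """Assemble the per-larva measure table.

    Returns a DataFrame indexed by larva_id with a ``condition`` column
    followed by one column per measure, in ontology order. A cell is NaN
    iff at least one constituent landmark is missing for that larva.
    """
    expected_stain = _STAIN_FOR_PREFIX.get(ontology.name.split("_")[0])
    rows = []
    for larva in larvae:
        if expected_stain and larva.stain != expected_stain:
            warnings.warn(
                f"larva {larva.larva_id!r}: stain {larva.stain!r} does not match"
                f" ontology {ontology.name!r}; proceeding",
                stacklevel=2,
            )
        row: dict[str, object] = {"condition": larva.condition}
        for m in ontology.measures:
            pts = [larva.coords.get(n) for n in m.landmarks]
            if any(pt is None for pt in pts):
                row[m.name] = np.nan
            elif m.kind == "distance":
                row[m.name] = distance(*pts)
            elif m.kind == "angle":
                row[m.name] = angle(*pts, names=m.landmarks)
            else:
                row[m.name] = triangle_area(*pts)
        rows.append(pd.Series(row, name=larva.larva_id))
    table = pd.DataFrame(rows)
    table.index.name = "larva_id"
    return table


def _measure_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != "condition"]


def screen_measures_pca(
    table: pd.DataFrame,
    variance_floor: float = 1e-6,
    redundancy_r: float = 0.95,
) -> list[str]:
    """Flag invariable and redundant measures; return the retained names.

    Invariable: raw variance below ``variance_floor``. Redundant: within
    any pair with \\|Pearson r\\| >= ``redundancy_r`` (computed on complete
    rows, standardized), the member loading less on the first principal
    component is dropped. Deterministic given the table.
    """
    cols = _measure_columns(table)
    data = table[cols].dropna()
    if len(data) < 3:
        raise ValueError(f"need >=3 complete rows for PCA screening, got {len(data)}")

    variances = data.var(ddof=1)
    invariable = set(variances.index[variances < variance_floor])
    kept = [c for c in cols if c not in invariable]
    if not kept:
        return []

    x = data[kept].to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    # loadings on PC1 from the SVD of the standardized matrix
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    loading = {c: abs(vt[0, j]) for j, c in enumerate(kept)}
    corr = np.corrcoef(x, rowvar=False)

    dropped: set[str] = set()
    for i, ci in enumerate(kept):
        for j in range(i + 1, len(kept)):
            cj = kept[j]
            if ci in dropped or cj in dropped:
                continue
            if abs(corr[i, j]) >= redundancy_r:
                # drop the weaker PC1 contributor; tie favours the earlier column
                dropped.add(cj if loading[cj] <= loading[ci] else ci)
    return [c for c in kept if c not in dropped]


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001 (strict)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_measures(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-measure two-sample t-test (Welch by default) between two conditions.

    Missing values are dropped per measure; each row reports mean +/- SD per
    group, the t statistic, the two-sided p-value and significance stars.
    """
    for g in (group_a, group_b):
        if g not in set(table["condition"]):
            raise ValueError(f"condition {g!r} absent from table")
    out = []
    for col in _measure_columns(table):
        a = table.loc[table["condition"] == group_a, col].dropna().to_numpy(float)
        b = table.loc[table["condition"] == group_b, col].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out.append(
            {
                "measure": col,
                f"mean_{group_a}": a.mean() if len(a) else np.nan,
                f"sd_{group_a}": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"n_{group_a}": len(a),
                f"mean_{group_b}": b.mean() if len(b) else np.nan,
                f"sd_{group_b}": b.std(ddof=1) if len(b) > 1 else np.nan,
                f"n_{group_b}": len(b),
                "t": t,
                "p": p,
                "stars": significance_stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(out).set_index("measure")


def compare_measures_anova(table: pd.DataFrame, groups: list[str]) -> pd.DataFrame:
    """Per-measure one-way fixed-effects ANOVA across conditions.

    Intended for >=3 conditions (the multi-treatment designs); with 2 groups
    it reduces to the squared pooled-variance t-test.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA comparison expects >=2 conditions")
    present = set(table["condition"])
    for g in groups:
        if g not in present:
            raise ValueError(f"condition {g!r} absent from table")
    out = []
    for col in _measure_columns(table):
        samples = [
            table.loc[table["condition"] == g, col].dropna().to_numpy(float)
            for g in groups
        ]
        if any(len(s) < 2 for s in samples):
            f = p = np.nan
        else:
            f, p = stats.f_oneway(*samples)
        out.append(
            {
                "measure": col,
                "F": f,
                "p": p,
                "stars": significance_stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(out).set_index("measure")
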