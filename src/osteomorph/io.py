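"""Readers and writers for the package's tabular formats.

Landmark annotations arrive as long-format CSV (one row per landmark:
larva_id, condition, stain, landmark, x, y) or an equivalent JSON list of
specimens; ossification scores and Ct values as flat CSV. Lines starting
with ``#`` are treated as comments (generators record their seed there).
Comma decimal separators are accepted when configured, since source tables
may come from a comma-decimal locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .morphometry import AnnotatedLarva
from .ossification import OssificationRecord

__all__ = [
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "read_ossification_csv",
    "write_ossification_csv",
    "read_ct_csv",
    "write_ct_csv",
    "write_tsv",
    "read_tsv",
]

LANDMARK_COLUMNS = ["larva_id", "condition", "stain", "landmark", "x", "y"]
OSSIFICATION_COLUMNS = ["larva_id", "condition", "structure", "side", "category"]
CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


def _read_csv(path, columns: list[str], decimal: str = ".", sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, decimal=decimal, comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_landmarks_csv(path, decimal: str = ".", sep: str = ",") -> list[AnnotatedLarva]:
    df = _read_csv(path, LANDMARK_COLUMNS, decimal=decimal, sep=sep)
    larvae = []
    for (lid, condition, stain), grp in df.groupby(
        ["larva_id", "condition", "stain"], sort=False
    ):
        if grp["landmark"].duplicated().any():
            dup = sorted(grp.loc[grp["landmark"].duplicated(), "landmark"])
            raise ValueError(f"larva {lid!r}: duplicated landmark(s) {dup}")
        coords = {
            r.landmark: (float(r.x), float(r.y)) for r in grp.itertuples(index=False)
        }
        larvae.append(AnnotatedLarva(str(lid), str(condition), str(stain), coords))
    return larvae


def write_landmarks_csv(larvae: list[AnnotatedLarva], path, header_comment: str | None = None) -> None:
    rows = [
        {
            "larva_id": lv.larva_id,
            "condition": lv.condition,
            "stain": lv.stain,
            "landmark": name,
            "x": f"{x:.6f}",
            "y": f"{y:.6f}",
        }
        for lv in larvae
        for name, (x, y) in lv.coords.items()
    ]
    _write_csv(pd.DataFrame(rows, columns=LANDMARK_COLUMNS), path, header_comment)


def read_landmarks_json(path) -> list[AnnotatedLarva]:
    data = json.loads(Path(path).read_text())
    return [
        AnnotatedLarva(
            d["larva_id"],
            d["condition"],
            d["stain"],
            {k: (float(v[0]), float(v[1])) for k, v in d["coords"].items()},
        )
        for d in data
    ]


def write_landmarks_json(larvae: list[AnnotatedLarva], path) -> None:
    data = [
        {
            "larva_id": lv.larva_id,
            "condition": lv.condition,
            "stain": lv.stain,
            "coords": {k: list(v) for k, v in lv.coords.items()},
        }
        for lv in larvae
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def read_ossification_csv(path) -> list[OssificationRecord]:
    df = _read_csv(path, OSSIFICATION_COLUMNS)
    return [
        OssificationRecord(
            str(r.larva_id), str(r.condition), str(r.structure), str(r.side), str(r.category)
        )
        for r in df.itertuples(index=False)
    ]


def write_ossification_csv(records: list[OssificationRecord], path, header_comment: str | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "larva_id": r.larva_id,
                "condition": r.condition,
                "structure": r.structure,
                "side": r.side,
                "category": r.category,
            }
            for r in records
        ],
        columns=OSSIFICATION_COLUMNS,
    )
    _write_csv(df, path, header_comment)


def read_ct_csv(path, decimal: str = ".") -> pd.DataFrame:
    return _read_csv(path, CT_COLUMNS, decimal=decimal)


def write_ct_csv(ct: pd.DataFrame, path, header_comment: str | None = None) -> None:
    out = ct[CT_COLUMNS].copy()
    out["ct"] = out["ct"].map(lambda v: f"{v:.6f}")
    _write_csv(out, path, header_comment)


def _write_csv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    text = df.to_csv(index=False, lineterminator="\n")
    if header_comment:
        text = f"# {header_comment}\n{text}"
    p.write_text(text)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, sep="\t", index=index, lineterminator="\n")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
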