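"""End-to-end analysis runs: morphometry + scoring + association statistics.

A :class:`RunConfig` names the inputs (landmark, ossification and optional
Ct tables), the ontology, the reference condition and the statistical
options; :func:`run_pipeline` executes the stages and emits the canonical
TSV tables (and optional stacked-bar figures) into the output directory
together with a log recording versions, seed and a config hash. Outputs
are a deterministic function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as omio
from .morphometry import AnnotatedLarva, compare_measures, compare_measures_anova, extract_measures
from .ontology import builtin_ontologies, validate_annotation
from .ossification import (
    OssificationRecord,
    ScoreWeights,
    compare_global_scores,
    frequency_table,
    global_scores,
    pool_bilateral,
)
from .stats_ordinal import (
    ContingencyTable,
    chi_square,
    collapse_classes,
    fit_ordinal_logistic,
    grouped_contrast,
    significance_report,
)
from .qpcr import ddct, select_reference

__all__ = ["RunConfig", "RunResult", "run_pipeline", "summarize_runs"]

CATEGORY_COLORS = {"absent": "red", "early": "gold", "advanced": "green", "over": "purple"}


@dataclass
class RunConfig:
    ontology: str = "bone_29"
    reference_condition: str = "control"
    conditions: list[str] | None = None
    landmarks_path: str | None = None
    ossification_path: str | None = None
    ct_path: str | None = None
    # in-memory alternatives to the paths
    larvae: list[AnnotatedLarva] | None = None
    records: list[OssificationRecord] | None = None
    ct: pd.DataFrame | None = None
    grouping: dict | None = None  # {"pool": [...], "vs": "..."}
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    equal_var: bool = False
    alpha: float = 0.05
    bh_correction: bool = False  # optional extension, off by default
    qpcr_targets: list[str] | None = None
    qpcr_calibrator: str | None = None
    out_dir: str | None = None
    figures: bool = False
    seed: int = 0
    decimal: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "weights" in d:
            d["weights"] = ScoreWeights(**d["weights"])
        return cls(**d)

    def config_hash(self) -> str:
        public = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("larvae", "records", "ct", "weights")
        }
        public["weights"] = self.weights.as_tuple()
        text = yaml.safe_dump(public, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    morpho_table: pd.DataFrame | None
    morpho_comparison: pd.DataFrame | None
    frequency: pd.DataFrame
    scores: pd.DataFrame
    score_comparison: dict
    structure_stats: pd.DataFrame
    qpcr: pd.DataFrame | None
    log: list[str]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return wrap


def _conditions_of(config: RunConfig, records: list[OssificationRecord]) -> list[str]:
    if config.conditions:
        return list(config.conditions)
    seen = list(dict.fromkeys(r.condition for r in records))
    ref = config.reference_condition
    if ref not in seen:
        raise ValueError(f"reference condition {ref!r} absent from data")
    return [ref] + [c for c in seen if c != ref]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute morphometry, scoring and association statistics for one run."""
    log = [
        f"osteomorph {__version__} (python {sys.version.split()[0]},"
        f" numpy {np.__version__}, pandas {pd.__version__})",
        f"seed={config.seed} config_hash={config.config_hash()}",
    ]
    ontology = builtin_ontologies()[config.ontology]

    # ---- inputs ---------------------------------------------------------
    larvae = config.larvae
    if larvae is None and config.landmarks_path:
        larvae = _stage("read_landmarks")(
            omio.read_landmarks_csv, config.landmarks_path, decimal=config.decimal
        )
    records = config.records
    if records is None and config.ossification_path:
        records = _stage("read_ossification")(
            omio.read_ossification_csv, config.ossification_path
        )
    if records is None:
        raise ValueError("no ossification input (records or ossification_path)")
    ct = config.ct
    if ct is None and config.ct_path:
        ct = _stage("read_ct")(omio.read_ct_csv, config.ct_path, decimal=config.decimal)

    conditions = _conditions_of(config, records)
    ref = config.reference_condition

    # ---- morphometry ----------------------------------------------------
    morpho_table = morpho_cmp = None
    if larvae:
        for lv in larvae:
            report = validate_annotation(lv, ontology)
            if not report.accepted:
                raise RuntimeError(
                    f"pipeline stage 'validate' failed: larva {lv.larva_id!r}"
                    f" has unknown landmarks {report.unknown}"
                )
        morpho_table = _stage("extract_measures")(extract_measures, larvae, ontology)
        treat = [c for c in conditions if c != ref]
        if len(treat) == 1:
            morpho_cmp = _stage("compare_measures")(
                compare_measures, morpho_table, ref, treat[0], config.equal_var
            )
        else:
            morpho_cmp = _stage("compare_measures_anova")(
                compare_measures_anova, morpho_table, conditions
            )
        log.append(f"morphometry: {len(larvae)} larvae, {morpho_table.shape[1]-1} measures")

    # ---- ossification scoring -------------------------------------------
    pooled = _stage("pool_bilateral")(pool_bilateral, records)
    freq = _stage("frequency_table")(frequency_table, pooled, conditions)
    scores = _stage("global_scores")(global_scores, records, config.weights)
    score_cmp = _stage("compare_global_scores")(compare_global_scores, scores)
    log.append(
        "global scores: "
        + "; ".join(f"{c}: {s['formatted']} (n={s['n']})" for c, s in score_cmp["conditions"].items())
        + f"; {score_cmp['test']} p={score_cmp['p']:.3g}"
    )

    # ---- per-structure association tests --------------------------------
    structures = list(dict.fromkeys(r.structure for r in pooled))
    rows = []
    for structure in structures:
        table = ContingencyTable.from_records(pooled, structure, conditions)
        try:
            if config.grouping:
                res = grouped_contrast(
                    table, pool=config.grouping["pool"], vs=config.grouping["vs"]
                )
                chi, fit = res["chi_square"], res["ordinal_fit"]
            else:
                collapsed = collapse_classes(table)
                chi = chi_square(collapsed)
                fit = (
                    fit_ordinal_logistic(collapsed, reference_group=ref)
                    if len(conditions) == 2
                    else None
                )
        except ValueError as exc:
            log.append(f"structure {structure}: not testable ({exc})")
            continue
        row = {
            "structure": structure,
            "chi2": chi["chi2"],
            "df": chi["df"],
            "p_chi2": chi["p"],
        }
        if fit is not None:
            row.update(
                {
                    "beta": fit.beta,
                    "OR": fit.or_,
                    "ci_low": fit.ci95[0],
                    "ci_high": fit.ci95[1],
                    "p": fit.p,
                    "separation": fit.separation_flag,
                }
            )
        else:
            row.update({"beta": np.nan, "OR": np.nan, "ci_low": np.nan,
                        "ci_high": np.nan, "p": chi["p"], "separation": False})
        rows.append(row)
    structure_stats = pd.DataFrame(rows).set_index("structure")
    structure_stats = significance_report(structure_stats, alpha=config.alpha)
    if config.bh_correction and not structure_stats.empty:
        # optional extension, clearly not the default analysis
        from scipy.stats import false_discovery_control

        ok = structure_stats["p"].notna()
        adj = structure_stats.loc[ok, "p"].copy()
        structure_stats.loc[ok, "p_bh"] = false_discovery_control(adj.to_numpy())
    log.append(f"association tests: {structure_stats.attrs.get('n_tests', 0)} structures")

    # ---- qPCR ------------------------------------------------------------
    qpcr_out = None
    if ct is not None:
        reference_gene = _stage("select_reference")(select_reference, ct)
        calibrator = config.qpcr_calibrator or ref
        targets = config.qpcr_targets or [
            g for g in ct["gene"].unique() if g != reference_gene
        ]
        parts = [
            _stage("ddct")(ddct, ct, g, reference_gene, calibrator) for g in targets
        ]
        qpcr_out = pd.concat(parts, ignore_index=True)
        log.append(f"qpcr: reference={reference_gene}, calibrator={calibrator}")

    result = RunResult(
        config=config,
        morpho_table=morpho_table,
        morpho_comparison=morpho_cmp,
        frequency=freq,
        scores=scores,
        score_comparison=score_cmp,
        structure_stats=structure_stats,
        qpcr=qpcr_out,
        log=log,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.morpho_table is not None:
        omio.write_tsv(result.morpho_table, out / "measures.tsv")
        omio.write_tsv(result.morpho_comparison, out / "measure_comparison.tsv")
    omio.write_tsv(result.frequency, out / "frequency.tsv", index=False)
    omio.write_tsv(result.scores, out / "global_scores.tsv", index=False)
    omio.write_tsv(result.structure_stats, out / "structure_stats.tsv")
    cmp_rows = [
        {"condition": c, **s} for c, s in result.score_comparison["conditions"].items()
    ]
    cmp_df = pd.DataFrame(cmp_rows)
    cmp_df["test"] = result.score_comparison["test"]
    cmp_df["p"] = result.score_comparison["p"]
    omio.write_tsv(cmp_df, out / "score_comparison.tsv", index=False)
    if result.qpcr is not None:
        omio.write_tsv(result.qpcr, out / "qpcr_folds.tsv", index=False)
    (out / "run.log").write_text("\n".join(result.log) + "\n")
    if result.config.figures:
        _stacked_bars(result.frequency, out / "frequency.png")


def _stacked_bars(freq: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = freq[["structure", "condition"]].drop_duplicates()
    labels = [f"{s}\n{c}" for s, c in cells.itertuples(index=False)]
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(labels)), 4))
    bottom = np.zeros(len(cells))
    for category, color in CATEGORY_COLORS.items():
        heights = []
        for s, c in cells.itertuples(index=False):
            sel = freq[
                (freq["structure"] == s)
                & (freq["condition"] == c)
                & (freq["category"] == category)
            ]
            heights.append(float(sel["pct"].iloc[0]) if not sel.empty else 0.0)
        ax.bar(labels, heights, bottom=bottom, color=color, label=category)
        bottom += np.asarray(heights)
    ax.set_ylabel("cumulated frequency (%)")
    ax.legend(fontsize=8)
    plt.xticks(rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_runs(results: dict[str, RunResult], alpha: float = 0.05) -> pd.DataFrame:
    """Cross-experiment structure summary.

    One row per structure, one column per run, each cell ``increase`` /
    ``decrease`` / ``ns`` from the per-structure ordinal-fit p-value and the
    sign of beta (increase means higher ossification classes in the
    treated/pooled group).
    """
    if len(results) < 2:
        raise ValueError("need >=2 runs to summarize")
    structure_sets = [set(r.structure_stats.index) for r in results.values()]
    shared = set.intersection(*structure_sets)
    if not shared:
        raise ValueError("runs share no structures")
    rows = {}
    for name, res in results.items():
        col = {}
        for structure in shared:
            row = res.structure_stats.loc[structure]
            p, beta = row.get("p", np.nan), row.get("beta", np.nan)
            if not np.isfinite(p) or p >= alpha or not np.isfinite(beta):
                col[structure] = "ns"
            else:
                col[structure] = "increase" if beta > 0 else "decrease"
        rows[name] = col
    out = pd.DataFrame(rows).loc[sorted(shared)]
    out.index.name = "structure"
    return out
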