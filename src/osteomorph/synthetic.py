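"""Synthetic annotated-larva cohorts with known ground truth.

Every pipeline stage can be exercised without images: landmark tables are
drawn as a stylized template mean shape plus iid Gaussian landmark noise
plus per-condition displacement vectors; ossification categories come from
per-structure multinomial distributions (optionally parameterized as a
latent proportional-odds model); Ct tables encode configured true fold
changes plus replicate noise.

The stylized templates approximate the topology of a ventral head view at
the pixel scale of a typical image; they carry no metric claim about real
larvae. Preset scenarios fix the per-structure category probabilities so
that the *expected* weighted global score per condition equals the
documented study-scale means (see docs/methods.md for the constants):

========== ========= =========
scenario   control   treated
========== ========= =========
vitd3_like 26        33
pth_like   27        13.5
hyperg_like 23       27
rgp_like   23        27 (each 3g-exposed condition)
========== ========= =========

All generators are pure functions of (configuration, seed); random numbers
come from numpy's PCG64 ``default_rng``, and the seed is recorded in the
header of every emitted CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .morphometry import AnnotatedLarva
from .ossification import CATEGORIES, OssificationRecord
from . import io as omio

__all__ = [
    "ShapeTemplate",
    "OssificationModel",
    "SimulationConfig",
    "Scenario",
    "gen_landmarks",
    "gen_ossification",
    "gen_ct",
    "preset_scenarios",
    "generate_scenario",
    "bone_template_coords",
    "cartilage_template_coords",
]


@dataclass
class SimulationConfig:
    """Cohort sizes and the seed controlling every random draw."""

    n_per_condition: int = 27
    seed: int = 0
    out_dir: Path | None = None

    def n_for(self, condition: str) -> int:
        return int(self.n_per_condition)


@dataclass
class ShapeTemplate:
    """Mean landmark shape plus condition effects for one ontology."""

    ontology_name: str
    mean_coords: dict[str, tuple[float, float]]
    noise_sd: float = 2.0
    displacements: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    missing_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    rigid_transform: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for cond, probs in self.missing_probs.items():
            for name, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"missing prob for {cond}/{name} outside [0,1]")

    @property
    def conditions(self) -> list[str]:
        return list(self.displacements)


@dataclass
class OssificationModel:
    """Per structure x condition 4-class multinomial category probabilities."""

    probs: dict[str, dict[str, tuple[float, float, float, float]]]
    paired: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for structure, by_cond in self.probs.items():
            for cond, p in by_cond.items():
                arr = np.asarray(p, dtype=float)
                if arr.shape != (4,) or (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"probabilities for {structure}/{cond} must be 4 values summing to 1"
                    )

    @classmethod
    def from_latent(
        cls,
        cutpoints: tuple[float, float, float],
        shifts: dict[str, float],
        structures: list[str],
        paired: set[str] | None = None,
    ) -> "OssificationModel":
        """Latent proportional-odds parameterization.

        ``P(Y <= k | condition) = expit(cutpoint_k - shift)``; a positive
        shift moves mass toward higher (more ossified) classes.
        """
        alphas = np.asarray(cutpoints, dtype=float)
        if not np.all(np.diff(alphas) > 0):
            raise ValueError("cutpoints must be strictly increasing")
        probs = {}
        for structure in structures:
            probs[structure] = {}
            for cond, beta in shifts.items():
                cum = expit(alphas - beta)
                cell = np.diff(np.concatenate(([0.0], cum, [1.0])))
                probs[structure][cond] = tuple(cell)
        return cls(probs, paired=set(paired or structures))

    @property
    def conditions(self) -> list[str]:
        first = next(iter(self.probs.values()))
        return list(first)

    def expected_global_score(
        self, condition: str, weights: tuple[int, ...] = (0, 1, 2, 4)
    ) -> float:
        """Expected weighted global score of one larva (sides separate)."""
        w = np.asarray(weights, dtype=float)
        total = 0.0
        for structure, by_cond in self.probs.items():
            mult = 2.0 if structure in self.paired else 1.0
            total += mult * float(np.asarray(by_cond[condition]) @ w)
        return total


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def bone_template_coords() -> dict[str, tuple[float, float]]:
    """Stylized 29-landmark bone configuration (ventral view, anterior left)."""
    return {
        "anterior": (50.0, 300.0),
        "maxilla_up": (130.0, 260.0),
        "maxilla_down": (130.0, 340.0),
        "dentary_up": (150.0, 270.0),
        "dentary_down": (150.0, 330.0),
        "anguloarticular_up": (220.0, 250.0),
        "anguloarticular_down": (220.0, 350.0),
        "ceratohyal_int_up": (240.0, 280.0),
        "ceratohyal_int_down": (240.0, 320.0),
        "parasphenoid_a": (260.0, 300.0),
        "ceratohyal_ext_up": (280.0, 220.0),
        "ceratohyal_ext_down": (280.0, 380.0),
        "entopterygoid_up": (330.0, 230.0),
        "entopterygoid_down": (330.0, 370.0),
        "hyomandibular_up": (380.0, 210.0),
        "hyomandibular_down": (380.0, 390.0),
        "parasphenoid_b": (400.0, 270.0),
        "parasphenoid_c": (400.0, 330.0),
        "branchiostegal_ray1_up": (420.0, 240.0),
        "branchiostegal_ray1_down": (420.0, 360.0),
        "ceratobranchial5_up": (430.0, 280.0),
        "ceratobranchial5_down": (430.0, 320.0),
        "branchiostegal_ray2_up": (450.0, 250.0),
        "branchiostegal_ray2_down": (450.0, 350.0),
        "opercle_up": (470.0, 220.0),
        "opercle_down": (470.0, 380.0),
        "cleithrum_up": (520.0, 250.0),
        "cleithrum_down": (520.0, 350.0),
        "notochord": (560.0, 300.0),
    }


def cartilage_template_coords() -> dict[str, tuple[float, float]]:
    """Stylized 21-landmark cartilage configuration."""
    coords = {
        "anterior": (50.0, 300.0),
        "ethmoid_plate": (160.0, 300.0),
        "posterior": (560.0, 300.0),
        "meckel_up": (120.0, 270.0),
        "meckel_down": (120.0, 330.0),
        "articulation_up": (220.0, 250.0),
        "articulation_down": (220.0, 350.0),
        "ceratohyal_int_up": (240.0, 280.0),
        "ceratohyal_int_down": (240.0, 320.0),
        "ceratohyal_ext_up": (280.0, 220.0),
        "ceratohyal_ext_down": (280.0, 380.0),
        "hyosymplectic_up": (380.0, 210.0),
        "hyosymplectic_down": (380.0, 390.0),
    }
    x = 400.0
    for i in range(1, 5):
        coords[f"ceratobranchial{i}_up"] = (x, 275.0)
        coords[f"ceratobranchial{i}_down"] = (x, 325.0)
        x += 25.0
    return coords


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

_STAIN = {"bone": "alizarin_red", "cartilage": "alcian_blue"}


def gen_landmarks(
    template: ShapeTemplate, config: SimulationConfig
) -> list[AnnotatedLarva]:
    """Draw annotated larvae: mean + condition displacement + Gaussian noise.

    Landmarks are dropped per the template's per-condition missing
    probabilities. When ``rigid_transform`` is set, each larva additionally
    receives a random rotation (within +/- 10 degrees) and translation —
    every measure is invariant to these, so it is off by default to mirror
    roughly aligned ventral-view images.
    """
    rng = np.random.default_rng(config.seed)
    stain = _STAIN.get(template.ontology_name.split("_")[0], "alizarin_red")
    larvae = []
    for condition in template.conditions:
        disp = template.displacements.get(condition, {})
        unknown = set(disp) - set(template.mean_coords)
        if unknown:
            raise ValueError(f"displacement references unknown landmarks {sorted(unknown)}")
        missing = template.missing_probs.get(condition, {})
        for i in range(config.n_for(condition)):
            coords = {}
            for name, (mx, my) in template.mean_coords.items():
                dx, dy = disp.get(name, (0.0, 0.0))
                noise = rng.normal(0.0, template.noise_sd, size=2)
                coords[name] = (mx + dx + noise[0], my + dy + noise[1])
            if template.rigid_transform:
                theta = rng.uniform(-np.pi / 18, np.pi / 18)
                shift = rng.uniform(-30.0, 30.0, size=2)
                c, s = np.cos(theta), np.sin(theta)
                coords = {
                    k: (c * x - s * y + shift[0], s * x + c * y + shift[1])
                    for k, (x, y) in coords.items()
                }
            for name, p in missing.items():
                if name in coords and rng.random() < p:
                    del coords[name]
            larvae.append(
                AnnotatedLarva(f"{condition}_{i:03d}", condition, stain, coords)
            )
    return larvae


def gen_ossification(
    model: OssificationModel, config: SimulationConfig
) -> list[OssificationRecord]:
    """Draw per-larva per-structure categories from the model multinomials."""
    rng = np.random.default_rng(config.seed)
    records = []
    for condition in model.conditions:
        for i in range(config.n_for(condition)):
            lid = f"{condition}_{i:03d}"
            for structure, by_cond in model.probs.items():
                p = np.asarray(by_cond[condition], dtype=float)
                sides = ("up", "down") if structure in model.paired else ("unpaired",)
                for side in sides:
                    cat = CATEGORIES[rng.choice(4, p=p)]
                    records.append(
                        OssificationRecord(lid, condition, structure, side, cat)
                    )
    return records


def gen_ct(
    true_folds: dict[str, dict[str, float]],
    config: SimulationConfig,
    replicate_sd: float = 0.15,
    n_bio_reps: int = 4,
    n_tech_reps: int = 3,
    baseline_ct: float = 28.0,
    reference_gene: str = "gapdh",
    reference_ct: float = 16.0,
    tech_sd: float = 0.05,
) -> pd.DataFrame:
    """Generate a Ct table encoding configured true fold changes.

    For a target gene, ``Ct = baseline - log2(fold) + N(0, replicate_sd)``
    per biological replicate; technical replicates scatter around that with
    SD ``tech_sd``. The reference gene is flat across conditions. With all
    SDs at zero, ``ddct`` recovers the configured folds exactly.
    """
    for gene, by_cond in true_folds.items():
        for cond, f in by_cond.items():
            if f <= 0:
                raise ValueError(f"fold for {gene}/{cond} must be positive, got {f}")
    rng = np.random.default_rng(config.seed)
    conditions = list(next(iter(true_folds.values())))
    rows = []

    def emit(gene: str, condition: str, level_ct: float) -> None:
        for b in range(1, n_bio_reps + 1):
            bio_ct = level_ct + rng.normal(0.0, replicate_sd)
            for t in range(1, n_tech_reps + 1):
                rows.append(
                    {
                        "gene": gene,
                        "condition": condition,
                        "bio_rep": b,
                        "tech_rep": t,
                        "ct": bio_ct + rng.normal(0.0, tech_sd),
                    }
                )

    for gene, by_cond in true_folds.items():
        for condition in conditions:
            emit(gene, condition, baseline_ct - np.log2(by_cond[condition]))
    for condition in conditions:
        emit(reference_gene, condition, reference_ct)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

#: Bone element families scored in each cohort; all bilateral, so the
#: global score sums 16 elements.
SCORED_STRUCTURES = [
    "anguloarticular",
    "branchiostegal_ray1",
    "branchiostegal_ray2",
    "maxilla",
    "ceratohyal",
    "dentary",
    "entopterygoid",
    "hyomandibular",
]


def _solve_probs(mean: float, p_early: float, p_advanced: float) -> tuple[float, float, float, float]:
    """Multinomial with given early/advanced mass and expected weight ``mean``."""
    p_over = (mean - p_early - 2.0 * p_advanced) / 4.0
    p_absent = 1.0 - p_early - p_advanced - p_over
    probs = (p_absent, p_early, p_advanced, p_over)
    if any(p < -1e-12 for p in probs):
        raise ValueError(f"infeasible multinomial for mean {mean}")
    return tuple(max(p, 0.0) for p in probs)


@dataclass
class Scenario:
    """One named study condition set with its generating models."""

    name: str
    conditions: list[str]  # first entry is the control / reference
    template: ShapeTemplate
    ossification: OssificationModel
    ct_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    ct_calibrator: str | None = None
    n_default: int = 27
    grouping: dict | None = None  # e.g. {"pool": [...], "vs": "1g"}

    def config(self, n: int | None = None, seed: int = 0) -> SimulationConfig:
        return SimulationConfig(n_per_condition=n or self.n_default, seed=seed)


def _widen(landmarks: list[str], by: float) -> dict[str, tuple[float, float]]:
    disp = {}
    for stem in landmarks:
        disp[f"{stem}_up"] = (0.0, -by / 2.0)
        disp[f"{stem}_down"] = (0.0, by / 2.0)
    return disp


def preset_scenarios() -> dict[str, Scenario]:
    """The four named study emulations (see module docstring for targets)."""
    from .ontology import builtin_ontologies

    bone = bone_template_coords()
    bone15_names = set(builtin_ontologies()["bone_15"].landmark_names)
    bone15 = {k: v for k, v in bone.items() if k in bone15_names}
    scenarios: dict[str, Scenario] = {}

    # --- VitD3: enhanced ossification, broader jaw, longer head ---------
    vit_disp = _widen(["maxilla"], 20.0)
    vit_disp["anterior"] = (-15.0, 0.0)
    vit_probs = {
        s: {
            "control": _solve_probs(1.625, 0.25, 0.55),
            "VitD3": _solve_probs(2.0625, 0.10, 0.70),
        }
        for s in SCORED_STRUCTURES
    }
    scenarios["vitd3_like"] = Scenario(
        name="vitd3_like",
        conditions=["control", "VitD3"],
        template=ShapeTemplate(
            "bone_29",
            bone,
            displacements={"control": {}, "VitD3": vit_disp},
        ),
        ossification=OssificationModel(vit_probs, paired=set(SCORED_STRUCTURES)),
        ct_folds={
            "cyp24a1": {"control": 1.0, "VitD3": 10.969},
            "igfbp1": {"control": 1.0, "VitD3": 5.250},
            "socs1": {"control": 1.0, "VitD3": 0.447},
        },
        ct_calibrator="control",
    )

    # --- PTH: decreased ossification, missing elements ------------------
    pth_disp = {
        "parasphenoid_b": (-30.0, 8.0),
        "parasphenoid_c": (-30.0, -8.0),
        **_widen(["branchiostegal_ray1", "entopterygoid", "opercle"], 16.0),
    }
    pth_missing = {
        "anguloarticular_up": 0.5,
        "anguloarticular_down": 0.5,
        "branchiostegal_ray2_up": 0.3,
        "branchiostegal_ray2_down": 0.3,
        "maxilla_up": 0.2,
        "maxilla_down": 0.2,
    }
    pth_probs = {
        "branchiostegal_ray1": {
            "control": (0.0, 0.10, 0.90, 0.0),
            "PTH": (0.0, 0.10, 0.90, 0.0),
        },
        "entopterygoid": {
            "control": (0.0, 1.0 / 29.0, 28.0 / 29.0, 0.0),
            "PTH": (0.0, 0.60, 0.40, 0.0),
        },
        "anguloarticular": {
            "control": (0.21, 0.19, 0.60, 0.0),
            "PTH": (0.94, 0.04, 0.02, 0.0),
        },
    }
    # remaining families share one multinomial solved so the expected
    # global totals hit 27 (control) and 13.5 (PTH)
    rest_control = _solve_probs((13.5 - (1.9 + 2.0 * 28.0 / 29.0 + 1.0 / 29.0 + 1.39)) / 5.0, 0.25, 0.55)
    rest_pth = _solve_probs((6.75 - (1.9 + 1.4 + 0.08)) / 5.0, 0.25, 0.18)
    for s in ["branchiostegal_ray2", "maxilla", "ceratohyal", "dentary", "hyomandibular"]:
        pth_probs[s] = {"control": rest_control, "PTH": rest_pth}
    scenarios["pth_like"] = Scenario(
        name="pth_like",
        conditions=["control", "PTH"],
        template=ShapeTemplate(
            "bone_29",
            bone,
            displacements={"control": {}, "PTH": pth_disp},
            missing_probs={"PTH": pth_missing},
        ),
        ossification=OssificationModel(pth_probs, paired=set(SCORED_STRUCTURES)),
        ct_folds={
            "slc6a18": {"control": 1.0, "PTH": 0.883},
            "rxra": {"control": 1.0, "PTH": 1.247},
        },
        ct_calibrator="control",
    )

    # --- Hypergravity 3g: larger head, increased ossification -----------
    hyper_probs = {
        s: {
            "1g": _solve_probs(1.4375, 0.35, 0.45),
            "3g": _solve_probs(1.6875, 0.25, 0.55),
        }
        for s in SCORED_STRUCTURES
    }
    scenarios["hyperg_like"] = Scenario(
        name="hyperg_like",
        conditions=["1g", "3g"],
        template=ShapeTemplate(
            "bone_15",
            dict(bone15),
            displacements={
                "1g": {},
                "3g": _widen(
                    ["anguloarticular", "branchiostegal_ray1", "entopterygoid", "opercle"],
                    16.0,
                ),
            },
        ),
        ossification=OssificationModel(hyper_probs, paired=set(SCORED_STRUCTURES)),
        ct_calibrator="1g",
    )

    # --- Reduced Gravity Paradigm: 3g-reared conditions vs 1g -----------
    rgp_conditions = ["1g", "3g", "3g>1g", "3g>axe"]
    rgp_probs = {
        s: {
            "1g": _solve_probs(1.4375, 0.35, 0.45),
            "3g": _solve_probs(1.6875, 0.25, 0.55),
            "3g>1g": _solve_probs(1.6875, 0.25, 0.55),
            "3g>axe": _solve_probs(1.6875, 0.25, 0.55),
        }
        for s in SCORED_STRUCTURES
    }
    rgp_disp = _widen(["branchiostegal_ray1", "entopterygoid", "opercle"], 14.0)
    scenarios["rgp_like"] = Scenario(
        name="rgp_like",
        conditions=rgp_conditions,
        template=ShapeTemplate(
            "bone_15",
            dict(bone15),
            displacements={
                "1g": {},
                "3g": dict(rgp_disp),
                "3g>1g": dict(rgp_disp),
                "3g>axe": dict(rgp_disp),
            },
        ),
        ossification=OssificationModel(rgp_probs, paired=set(SCORED_STRUCTURES)),
        ct_calibrator="1g",
        grouping={"pool": ["3g", "3g>1g", "3g>axe"], "vs": "1g"},
    )
    return scenarios


def generate_scenario(
    name: str, n: int | None = None, seed: int = 0, out_dir: str | Path | None = None
) -> dict:
    """Generate one preset scenario's three CSVs (plus a manifest) or return
    the in-memory objects when ``out_dir`` is None."""
    scenarios = preset_scenarios()
    if name not in scenarios:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(scenarios)}")
    sc = scenarios[name]
    config = sc.config(n=n, seed=seed)
    larvae = gen_landmarks(sc.template, config)
    records = gen_ossification(sc.ossification, config)
    ct = gen_ct(sc.ct_folds, config) if sc.ct_folds else None
    result = {"scenario": sc, "larvae": larvae, "ossification": records, "ct": ct}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        comment = f"scenario={name} seed={seed} n={config.n_per_condition}"
        omio.write_landmarks_csv(larvae, out / "landmarks.csv", header_comment=comment)
        omio.write_ossification_csv(records, out / "ossification.csv", header_comment=comment)
        manifest = {
            "scenario": name,
            "seed": seed,
            "n_per_condition": config.n_per_condition,
            "conditions": sc.conditions,
            "files": ["landmarks.csv", "ossification.csv"],
        }
        if ct is not None:
            omio.write_ct_csv(ct, out / "ct.csv", header_comment=comment)
            manifest["files"].append("ct.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        result["out_dir"] = out
    return result
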