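"""Landmark vocabularies and named morphometric measures.

A :class:`LandmarkOntology` names the anatomical points annotated on a
stained zebrafish larva (Alcian blue for cartilage, Alizarin red for bone)
and the measures — Euclidean distances, interior angles and triangle areas
in image pixels — computed from them. Bilateral elements of the ventral
view appear twice, suffixed ``_up`` and ``_down`` for the two sides of the
head symmetry axis; midline elements are unpaired.

Three ontologies ship with the package:

``cartilage_21``
    21 cartilage landmarks and the 8 retained cartilage distances.
``bone_29``
    29 bone landmarks with 9 distances, the parasphenoid triangle area and
    its 3 interior angles (the parasphenoid is a triangular midline bone
    with an anterior summit *a* and posterior summits *b*, *c*).
``bone_15``
    the reduced 15-landmark bone set used for the hypergravity cohorts;
    it carries the same measures, all of which resolve within the subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "LandmarkDef",
    "MeasureDef",
    "LandmarkOntology",
    "ValidationReport",
    "builtin_ontologies",
    "validate_annotation",
]

LATERALITIES = ("unpaired", "up", "down")
MEASURE_KINDS = {"distance": 2, "angle": 3, "area": 3}
MEASURE_UNITS = {"distance": "pixels", "angle": "radians", "area": "pixels^2"}


@dataclass(frozen=True)
class LandmarkDef:
    """One named annotation point.

    ``abbreviation`` is the short code used on figures (aa, an, br1, ...);
    ``laterality`` says whether the landmark sits on the midline
    (``unpaired``) or on one side (``up``/``down``).
    """

    name: str
    abbreviation: str
    laterality: str = "unpaired"

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ValueError(f"landmark {self.name!r}: empty abbreviation")
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"landmark {self.name!r}: laterality must be one of {LATERALITIES}"
            )

    @property
    def partner(self) -> str | None:
        """Name of the contralateral landmark, or None for midline points."""
        if self.laterality == "up":
            return self.name[: -len("_up")] + "_down"
        if self.laterality == "down":
            return self.name[: -len("_down")] + "_up"
        return None


@dataclass(frozen=True)
class MeasureDef:
    """A named scalar computed from 2 or 3 landmarks.

    For angles the first landmark is the vertex; for areas the three
    landmarks are the triangle vertices.
    """

    name: str
    kind: str
    landmarks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in MEASURE_KINDS:
            raise ValueError(f"measure {self.name!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        arity = MEASURE_KINDS[self.kind]
        if len(self.landmarks) != arity:
            raise ValueError(
                f"measure {self.name!r}: kind {self.kind!r} needs {arity} landmarks,"
                f" got {len(self.landmarks)}"
            )

    @property
    def units(self) -> str:
        return MEASURE_UNITS[self.kind]


@dataclass(frozen=True)
class LandmarkOntology:
    name: str
    landmarks: tuple[LandmarkDef, ...]
    measures: tuple[MeasureDef, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        object.__setattr__(self, "measures", tuple(self.measures))
        names = [lm.name for lm in self.landmarks]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"ontology {self.name!r}: duplicate landmarks {dup}")
        by_name = {lm.name: lm for lm in self.landmarks}
        for lm in self.landmarks:
            if lm.laterality == "unpaired":
                continue
            partner = by_name.get(lm.partner)
            if partner is None:
                raise ValueError(
                    f"ontology {self.name!r}: {lm.name} lacks partner {lm.partner}"
                )
            if partner.laterality == lm.laterality:
                raise ValueError(
                    f"ontology {self.name!r}: {lm.name}/{partner.name} share a side"
                )
        for m in self.measures:
            missing = [n for n in m.landmarks if n not in by_name]
            if missing:
                raise ValueError(
                    f"ontology {self.name!r}: measure {m.name!r} references"
                    f" unknown landmarks {missing}"
                )

    @property
    def landmark_names(self) -> tuple[str, ...]:
        return tuple(lm.name for lm in self.landmarks)

    def __contains__(self, landmark_name: str) -> bool:
        return landmark_name in set(self.landmark_names)

    def __len__(self) -> int:
        return len(self.landmarks)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "landmarks": [
                {
                    "name": lm.name,
                    "abbreviation": lm.abbreviation,
                    "laterality": lm.laterality,
                }
                for lm in self.landmarks
            ],
            "measures": [
                {"name": m.name, "kind": m.kind, "landmarks": list(m.landmarks)}
                for m in self.measures
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkOntology":
        return cls(
            name=d["name"],
            landmarks=tuple(LandmarkDef(**lm) for lm in d["landmarks"]),
            measures=tuple(
                MeasureDef(m["name"], m["kind"], tuple(m["landmarks"]))
                for m in d.get("measures", ())
            ),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "LandmarkOntology":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LandmarkOntology":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Builtin ontologies
# ---------------------------------------------------------------------------


def _paired(stem: str, abbrev: str) -> list[LandmarkDef]:
    return [
        LandmarkDef(f"{stem}_up", abbrev, "up"),
        LandmarkDef(f"{stem}_down", abbrev, "down"),
    ]


def _cartilage_21() -> LandmarkOntology:
    landmarks: list[LandmarkDef] = [
        LandmarkDef("anterior", "an"),
        LandmarkDef("ethmoid_plate", "et"),
        LandmarkDef("posterior", "po"),
    ]
    for stem, ab in [
        ("articulation", "ar"),
        ("ceratohyal_ext", "ch"),
        ("ceratohyal_int", "ch"),
        ("hyosymplectic", "h"),
        ("meckel", "mk"),
        ("ceratobranchial1", "cb1"),
        ("ceratobranchial2", "cb2"),
        ("ceratobranchial3", "cb3"),
        ("ceratobranchial4", "cb4"),
    ]:
        landmarks.extend(_paired(stem, ab))
    measures = [
        MeasureDef("anterior_to_ethmoid_plate", "distance", ("anterior", "ethmoid_plate")),
        MeasureDef("anterior_to_posterior", "distance", ("anterior", "posterior")),
        MeasureDef(
            "articulation_down_to_articulation_up",
            "distance",
            ("articulation_down", "articulation_up"),
        ),
        MeasureDef(
            "ceratohyal_ext_down_to_ceratohyal_ext_up",
            "distance",
            ("ceratohyal_ext_down", "ceratohyal_ext_up"),
        ),
        MeasureDef(
            "ceratohyal_ext_down_to_ceratohyal_int_down",
            "distance",
            ("ceratohyal_ext_down", "ceratohyal_int_down"),
        ),
        MeasureDef(
            "ceratohyal_ext_up_to_ceratohyal_int_up",
            "distance",
            ("ceratohyal_ext_up", "ceratohyal_int_up"),
        ),
        MeasureDef("ethmoid_plate_to_posterior", "distance", ("ethmoid_plate", "posterior")),
        MeasureDef(
            "hyosymplectic_down_to_hyosymplectic_up",
            "distance",
            ("hyosymplectic_down", "hyosymplectic_up"),
        ),
    ]
    return LandmarkOntology("cartilage_21", tuple(landmarks), tuple(measures))


_BONE_15_LANDMARKS: list[LandmarkDef] = (
    _paired("anguloarticular", "aa")
    + [LandmarkDef("anterior", "an")]
    + _paired("branchiostegal_ray1", "br1")
    + _paired("entopterygoid", "en")
    + _paired("maxilla", "m")
    + [LandmarkDef("notochord", "n")]
    + _paired("opercle", "o")
    + [
        LandmarkDef("parasphenoid_a", "p_a"),
        LandmarkDef("parasphenoid_b", "p_b"),
        LandmarkDef("parasphenoid_c", "p_c"),
    ]
)

# Additional bone landmarks annotated only for the chemical-treatment
# cohorts. The ceratohyal carries exterior/interior points per side, as in
# the cartilage ontology.
_BONE_29_EXTRA: list[LandmarkDef] = (
    _paired("branchiostegal_ray2", "br2")
    + _paired("cleithrum", "c")
    + _paired("ceratobranchial5", "cb")
    + _paired("ceratohyal_ext", "ch")
    + _paired("ceratohyal_int", "ch")
    + _paired("dentary", "d")
    + _paired("hyomandibular", "hm")
)

_BONE_MEASURES: list[MeasureDef] = [
    MeasureDef(
        "anguloarticular_down_to_anguloarticular_up",
        "distance",
        ("anguloarticular_down", "anguloarticular_up"),
    ),
    MeasureDef("anterior_to_notochord", "distance", ("anterior", "notochord")),
    MeasureDef("anterior_to_parasphenoid_a", "distance", ("anterior", "parasphenoid_a")),
    MeasureDef(
        "branchiostegal_ray1_down_to_branchiostegal_ray1_up",
        "distance",
        ("branchiostegal_ray1_down", "branchiostegal_ray1_up"),
    ),
    MeasureDef(
        "entopterygoid_down_to_entopterygoid_up",
        "distance",
        ("entopterygoid_down", "entopterygoid_up"),
    ),
    MeasureDef("maxilla_down_to_maxilla_up", "distance", ("maxilla_down", "maxilla_up")),
    MeasureDef("opercle_down_to_opercle_up", "distance", ("opercle_down", "opercle_up")),
    MeasureDef(
        "parasphenoid_a_to_parasphenoid_b",
        "distance",
        ("parasphenoid_a", "parasphenoid_b"),
    ),
    MeasureDef(
        "parasphenoid_b_to_parasphenoid_c",
        "distance",
        ("parasphenoid_b", "parasphenoid_c"),
    ),
    MeasureDef(
        "area_parasphenoid",
        "area",
        ("parasphenoid_a", "parasphenoid_b", "parasphenoid_c"),
    ),
    # interior angle at each summit of the parasphenoid triangle
    MeasureDef(
        "angle_parasphenoid_a",
        "angle",
        ("parasphenoid_a", "parasphenoid_b", "parasphenoid_c"),
    ),
    MeasureDef(
        "angle_parasphenoid_b",
        "angle",
        ("parasphenoid_b", "parasphenoid_a", "parasphenoid_c"),
    ),
    MeasureDef(
        "angle_parasphenoid_c",
        "angle",
        ("parasphenoid_c", "parasphenoid_a", "parasphenoid_b"),
    ),
]


def _bone_29() -> LandmarkOntology:
    return LandmarkOntology(
        "bone_29",
        tuple(_BONE_15_LANDMARKS + _BONE_29_EXTRA),
        tuple(_BONE_MEASURES),
    )


def _bone_15() -> LandmarkOntology:
    return LandmarkOntology("bone_15", tuple(_BONE_15_LANDMARKS), tuple(_BONE_MEASURES))


def builtin_ontologies() -> dict[str, LandmarkOntology]:
    """Return the three shipped ontologies keyed by name."""
    onts = [_cartilage_21(), _bone_29(), _bone_15()]
    return {o.name: o for o in onts}


# ---------------------------------------------------------------------------
# Annotation validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    larva_id: str
    unknown: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.unknown


def validate_annotation(larva, ontology: LandmarkOntology) -> ValidationReport:
    """Check a larva's named coordinates against an ontology.

    A larva is accepted iff it carries no unknown landmark names; missing
    landmarks are reported but tolerated (measures touching them will be
    missing downstream). Duplicated names cannot occur in the dict-based
    container and raise at construction time.
    """
    names = set(larva.coords)
    known = set(ontology.landmark_names)
    return ValidationReport(
        larva_id=larva.larva_id,
        unknown=sorted(names - known),
        missing=sorted(known - names),
    )
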