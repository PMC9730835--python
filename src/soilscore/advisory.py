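"""Visual soil assessment integration and farming-practice advice.

The nine-item in-field visual soil assessment (VSA; earthworms,
compaction, gray spots, ponding, cracks, bio pores, rooting depth,
structure, crop cover; each rated poor/moderate/good) complements the
laboratory battery. When a VSA is available its compaction and
structure observations *replace* the model-derived subsoil-compaction
and aggregate-stability indicators.

Practice recommendation ranks a configured set of farming practices by
how much they would improve the poorly scored functions of a category:
``benefit(p) = sum_f e(p, f) * (1 - I_f)`` over the category's
functions, where ``e`` is a practice-by-function effectiveness matrix
(0-1, evidence-based, config-supplied) and ``1 - I_f`` the function's
remaining deficiency. The best practice per category is the top of the
ranking; ties break lexicographically on the practice id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigurationError, InputError
from .evaluation import IndicatorSource, IndicatorValue, IndicatorVector
from .types import Category, FieldContext, VSARating, VSARecord, VSA_ITEMS

__all__ = [
    "VSA_SCORE_MAP",
    "VSA_SUBSTITUTIONS",
    "vsa_item_score",
    "vsa_overall",
    "apply_vsa",
    "PracticeDefinition",
    "EffectivenessMatrix",
    "PracticeSet",
    "Recommendation",
    "recommend_category",
    "recommend_all",
    "load_practices",
    "default_practices",
]

#: Three-level VSA rating mapped onto the indicator scale (configurable).
VSA_SCORE_MAP: dict[VSARating, float] = {
    VSARating.POOR: 0.0,
    VSARating.MODERATE: 0.5,
    VSARating.GOOD: 1.0,
}

#: function_id -> VSA item whose observation replaces it.
VSA_SUBSTITUTIONS: dict[str, str] = {
    "i_p_compaction": "compaction",
    "i_p_aggstability": "structure",
}


def vsa_item_score(
    rating: VSARating, score_map: Mapping[VSARating, float] | None = None
) -> float:
    """Map a poor/moderate/good rating to the 0-1 indicator scale."""
    score_map = score_map or VSA_SCORE_MAP
    if not isinstance(rating, VSARating):
        raise InputError(f"unknown VSA rating {rating!r}")
    return score_map[rating]


def vsa_overall(vsa: VSARecord) -> float:
    """Arithmetic mean of the nine item scores."""
    vsa.validate()
    return sum(vsa_item_score(r) for r in vsa.items().values()) / len(VSA_ITEMS)


def apply_vsa(
    vec: IndicatorVector, vsa: VSARecord | None
) -> IndicatorVector:
    """Substitute VSA observations into an evaluated indicator vector.

    The compaction and structure items replace the subsoil-compaction
    and aggregate-stability indicators (source flagged ``vsa``); every
    other indicator is untouched. A missing VSA is a no-op.
    """
    if vsa is None:
        return vec
    vsa.validate()
    out = dict(vec)
    for function_id, item in VSA_SUBSTITUTIONS.items():
        if function_id in out:
            old = out[function_id]
            out[function_id] = IndicatorValue(
                function_id=function_id,
                category=old.category,
                value=vsa_item_score(getattr(vsa, item)),
                source=IndicatorSource.VSA,
            )
    return out


@dataclass
class PracticeDefinition:
    """One farming practice with its applicability filters."""

    practice_id: str
    label: str
    land_uses: frozenset[str]   # land-use values, or {"*"}
    soil_types: frozenset[str]  # soil-type values, or {"*"}

    def validate(self) -> None:
        if not self.practice_id:
            raise ConfigurationError("practice with empty id")
        if not self.land_uses or not self.soil_types:
            raise ConfigurationError(
                f"practice {self.practice_id}: empty applicability set"
            )

    def applicable(self, context: FieldContext) -> bool:
        lu_ok = "*" in self.land_uses or context.land_use.value in self.land_uses
        st_ok = "*" in self.soil_types or context.soil_type.value in self.soil_types
        return lu_ok and st_ok


class EffectivenessMatrix:
    """Sparse practice x soil-function effectiveness, values in [0, 1];
    unconfigured pairs default to 0."""

    def __init__(self, entries: Mapping[str, Mapping[str, float]] | None = None):
        self._e: dict[tuple[str, str], float] = {}
        for pid, row in (entries or {}).items():
            for fid, e in row.items():
                e = float(e)
                if not (0.0 <= e <= 1.0):
                    raise ConfigurationError(
                        f"effectiveness e({pid}, {fid})={e} outside [0, 1]"
                    )
                self._e[(pid, fid)] = e

    def get(self, practice_id: str, function_id: str) -> float:
        return self._e.get((practice_id, function_id), 0.0)

    def functions_for(self, practice_id: str) -> list[str]:
        return [fid for (pid, fid) in self._e if pid == practice_id]


@dataclass
class PracticeSet:
    """Validated practices plus their effectiveness matrix."""

    practices: list[PracticeDefinition]
    effectiveness: EffectivenessMatrix

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.practices:
            if p.practice_id in seen:
                raise ConfigurationError(f"duplicate practice id {p.practice_id!r}")
            seen.add(p.practice_id)
            p.validate()


@dataclass
class Recommendation:
    """Ranked practices for one category; ``best`` is the top of the
    ranking, ``None`` when no practice applies."""

    category: Category
    ranking: list[tuple[str, float]] = field(default_factory=list)
    best: str | None = None
    note: str = ""


def recommend_category(
    vec: IndicatorVector,
    category: Category,
    practices: Iterable[PracticeDefinition],
    matrix: EffectivenessMatrix,
    context: FieldContext,
) -> Recommendation:
    """Rank applicable practices by their benefit for one category."""
    applicable = [p for p in practices if p.applicable(context)]
    if not applicable:
        return Recommendation(category, [], None, "no applicable practice")
    deficits = {
        fid: 1.0 - iv.value
        for fid, iv in vec.items()
        if iv.category is category and iv.value is not None
    }
    scored = [
        (
            p.practice_id,
            sum(matrix.get(p.practice_id, fid) * d for fid, d in deficits.items()),
        )
        for p in applicable
    ]
    # descending benefit; ties broken lexicographically on practice id
    scored.sort(key=lambda t: (-t[1], t[0]))
    note = "" if scored[0][1] > 0 else "no deficiency"
    return Recommendation(category, scored, scored[0][0], note)


def recommend_all(
    vec: IndicatorVector,
    practice_set: PracticeSet,
    context: FieldContext,
    categories: Iterable[Category] | None = None,
) -> dict[Category, Recommendation]:
    cats = list(categories) if categories is not None else [
        Category.CHEMICAL, Category.PHYSICAL,
        Category.BIOLOGICAL, Category.ENVIRONMENTAL,
    ]
    return {
        cat: recommend_category(
            vec, cat, practice_set.practices, practice_set.effectiveness, context
        )
        for cat in cats
    }


def load_practices(source: str | Path | dict[str, Any]) -> PracticeSet:
    """Load practices + effectiveness matrix from YAML/JSON or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        origin = str(source)
    else:
        raw, origin = source, "<mapping>"
    if not isinstance(raw, dict) or "practices" not in raw:
        raise ConfigurationError(f"{origin}: expected a top-level 'practices' list")
    practices = []
    for i, entry in enumerate(raw["practices"]):
        where = f"{origin}: practices[{i}]"
        if not isinstance(entry, dict) or "practice_id" not in entry:
            raise ConfigurationError(f"{where}: entry must map and name a practice_id")
        practices.append(
            PracticeDefinition(
                practice_id=str(entry["practice_id"]),
                label=str(entry.get("label", "")),
                land_uses=frozenset(entry.get("land_uses", ["*"])),
                soil_types=frozenset(entry.get("soil_types", ["*"])),
            )
        )
    matrix = EffectivenessMatrix(raw.get("effectiveness", {}))
    return PracticeSet(practices, matrix)


def default_practices() -> PracticeSet:
    """The shipped illustrative practice set (M1-M11)."""
    ref = resources.files("soilscore.data").joinpath("practices.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_practices(yaml.safe_load(fh))
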