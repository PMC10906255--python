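"""Embedded reference metabolites and a small pathway map.

The reference set covers the eight exacerbation markers (creatine, lactic
acid, dimethylglycine, 3-hydroxybutyric acid, uric acid, threonine,
malondialdehyde, fucose) plus the four stable-disease markers (glucose,
lactic acid, uric acid, malondialdehyde — the latter three shared), with
monoisotopic masses computed from the atomic-mass table at import time
rather than hard-coded, so they stay consistent with the adduct
calculator.

The pathway map is a deliberately small, KEGG-style named table meant for
testing hypergeometric over-representation; user-supplied tables are
accepted by the enrichment routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adducts import formula_mass


@dataclass(frozen=True)
class MetaboliteRecord:
    name: str
    formula: str
    monoisotopic_mass: float
    pathways: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: mass must be positive")
        if abs(formula_mass(self.formula) - self.monoisotopic_mass) > 1e-4:
            raise ValueError(
                f"{self.name}: formula {self.formula} does not match stated mass "
                f"{self.monoisotopic_mass}"
            )


# (name, formula, short abbreviation)
_FORMULAS: list[tuple[str, str, str]] = [
    ("lactic acid", "C3H6O3", "Laa"),
    ("creatine", "C4H9N3O2", "Cre"),
    ("uric acid", "C5H4N4O3", "Ura"),
    ("dimethylglycine", "C4H9NO2", "Dim"),
    ("malondialdehyde", "C3H4O2", "Mal"),
    ("threonine", "C4H9NO3", "Thr"),
    ("3-hydroxybutyric acid", "C4H8O3", "Hya"),
    ("fucose", "C6H12O5", "Fuc"),
    ("glucose", "C6H12O6", "Glc"),
]

ABBREVIATIONS: dict[str, str] = {name: abbr for name, _, abbr in _FORMULAS}

# Small KEGG-style pathway membership map over a background of plasma
# metabolites; names follow KEGG conventions.
DEFAULT_PATHWAYS: dict[str, tuple[str, ...]] = {
    "Glycine, serine and threonine metabolism": (
        "threonine",
        "dimethylglycine",
        "creatine",
        "glycine",
        "serine",
        "betaine",
        "choline",
    ),
    "Glycolysis / Gluconeogenesis": (
        "glucose",
        "lactic acid",
        "pyruvic acid",
    ),
    "Purine metabolism": (
        "uric acid",
        "xanthine",
        "hypoxanthine",
        "inosine",
    ),
    "Synthesis and degradation of ketone bodies": (
        "3-hydroxybutyric acid",
        "acetoacetic acid",
    ),
    "Fructose and mannose metabolism": (
        "fucose",
        "mannose",
        "fructose",
    ),
    "Lipid peroxidation": (
        "malondialdehyde",
        "4-hydroxynonenal",
    ),
    "Arginine and proline metabolism": (
        "creatine",
        "proline",
        "ornithine",
        "arginine",
    ),
}


def _pathways_of(name: str) -> tuple[str, ...]:
    return tuple(p for p, members in DEFAULT_PATHWAYS.items() if name in members)


def reference_metabolites() -> list[MetaboliteRecord]:
    """The embedded reference set, masses computed from formulas."""
    return [
        MetaboliteRecord(
            name=name,
            formula=formula,
            monoisotopic_mass=formula_mass(formula),
            pathways=_pathways_of(name),
        )
        for name, formula, _ in _FORMULAS
    ]


#: metabolites the exacerbation panel reports as up- vs down-regulated
UP_MARKERS: tuple[str, ...] = ("lactic acid", "uric acid", "malondialdehyde", "3-hydroxybutyric acid")
DOWN_MARKERS: tuple[str, ...] = ("creatine", "dimethylglycine", "threonine", "fucose")
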