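"""Derived glycosylation traits from relative-abundance tables.

A derived trait is the summed relative abundance (%) of all glycoforms (or
UPLC peaks) sharing a structural feature: number of antennary galactoses
(agalactosylation / monogalactosylation / digalactosylation), presence of
sialic acid, presence of bisecting GlcNAc, and — for the total IgG glycome
only — presence of core fucose.  Core fucosylation is not derived for the
Fc glycopeptide tables, where non-fucosylated species are weakly measured.

Traits are linear in the abundances, so they inherit the closure property:
the galactosylation trio always sums to 100 within a sample (and subclass).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem import PanelEntry, default_panel

__all__ = [
    "TraitAnnotation",
    "TraitSchema",
    "FC_TRAITS",
    "TOTAL_TRAITS",
    "derive_fc_traits",
    "derive_total_traits",
    "load_uplc_schema",
    "default_uplc_schema",
]

FC_TRAITS = (
    "agalactosylation",
    "monogalactosylation",
    "digalactosylation",
    "sialylation",
    "bisecting_glcnac",
)

TOTAL_TRAITS = FC_TRAITS + ("core_fucosylation",)


@dataclass(frozen=True)
class TraitAnnotation:
    """Structural features of one glycoform / one UPLC peak's dominant structure."""

    label: str
    galactoses: int
    sialic_acids: int
    bisecting: bool
    core_fucose: bool
    weight: float = 1.0  # generator baseline; unused by trait derivation

    def __post_init__(self):
        if self.galactoses not in (0, 1, 2):
            raise ValueError(
                f"{self.label}: galactose count must be 0, 1 or 2, got {self.galactoses}")
        if self.sialic_acids < 0:
            raise ValueError(f"{self.label}: negative sialic acid count")


class TraitSchema:
    """Maps abundance columns to structural annotations, exactly one each."""

    def __init__(self, annotations: Sequence[TraitAnnotation]):
        labels = [a.label for a in annotations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in trait schema")
        self.annotations: List[TraitAnnotation] = list(annotations)
        self._by_label: Dict[str, TraitAnnotation] = {a.label: a for a in annotations}

    def __len__(self) -> int:
        return len(self.annotations)

    def __getitem__(self, label: str) -> TraitAnnotation:
        return self._by_label[label]

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    @property
    def labels(self) -> List[str]:
        return [a.label for a in self.annotations]

    @classmethod
    def from_panel(cls, panel: Sequence[PanelEntry] | None = None) -> "TraitSchema":
        """Annotations read off the glycan compositions of an Fc panel."""
        if panel is None:
            panel = default_panel()
        return cls([
            TraitAnnotation(
                label=e.label,
                galactoses=e.glycan.galactoses,
                sialic_acids=e.glycan.neuac,
                bisecting=e.glycan.bisecting,
                core_fucose=e.glycan.fucosylated,
            )
            for e in panel
        ])

    def indicator(self, trait: str, sialylation: str = "presence") -> np.ndarray:
        """Per-column weight vector whose dot product with abundances is the trait."""
        out = np.zeros(len(self.annotations))
        for i, a in enumerate(self.annotations):
            if trait == "agalactosylation":
                out[i] = float(a.galactoses == 0)
            elif trait == "monogalactosylation":
                out[i] = float(a.galactoses == 1)
            elif trait == "digalactosylation":
                out[i] = float(a.galactoses == 2)
            elif trait == "sialylation":
                if sialylation == "presence":
                    out[i] = float(a.sialic_acids >= 1)
                elif sialylation == "count":
                    out[i] = float(a.sialic_acids)
                else:
                    raise ValueError(
                        f"sialylation weighting must be 'presence' or 'count', got {sialylation!r}")
            elif trait == "bisecting_glcnac":
                out[i] = float(a.bisecting)
            elif trait == "core_fucosylation":
                out[i] = float(a.core_fucose)
            else:
                raise ValueError(f"unknown trait {trait!r}")
        return out


def _schema_from_yaml(doc: Mapping) -> TraitSchema:
    return TraitSchema([
        TraitAnnotation(
            label=str(p["label"]),
            galactoses=int(p["galactoses"]),
            sialic_acids=int(p["sialic_acids"]),
            bisecting=bool(p["bisecting"]),
            core_fucose=bool(p["core_fucose"]),
            weight=float(p.get("weight", 1.0)),
        )
        for p in doc["peaks"]
    ])


def load_uplc_schema(path) -> TraitSchema:
    with open(path) as fh:
        return _schema_from_yaml(yaml.safe_load(fh))


_DEFAULT_UPLC: TraitSchema | None = None


def default_uplc_schema() -> TraitSchema:
    """The shipped 24-peak total-IgG UPLC annotation (editable YAML)."""
    global _DEFAULT_UPLC
    if _DEFAULT_UPLC is None:
        ref = resources.files("igglycome.data").joinpath("uplc_schema.yaml")
        _DEFAULT_UPLC = _schema_from_yaml(yaml.safe_load(ref.read_text()))
    return _DEFAULT_UPLC


def _derive(tab: pd.DataFrame, schema: TraitSchema, traits: Sequence[str],
            sialylation: str) -> pd.DataFrame:
    missing = [c for c in tab.columns if c not in schema]
    if missing:
        raise ValueError(f"unannotated abundance column(s): {missing}")
    # align schema order to table columns
    sub = TraitSchema([schema[c] for c in tab.columns])
    mat = np.column_stack([sub.indicator(t, sialylation) for t in traits])
    values = tab.to_numpy(dtype=float) @ mat
    return pd.DataFrame(values, index=tab.index, columns=list(traits))


def derive_fc_traits(tab: pd.DataFrame, schema: TraitSchema | None = None,
                     sialylation: str = "presence") -> pd.DataFrame:
    """Derived traits from a subclass-specific Fc glycopeptide abundance table.

    ``tab`` is in % with either plain glycoform columns (one subclass) or a
    (subclass, glycoform) MultiIndex; the result mirrors that layout with
    trait columns.  Core fucosylation is deliberately not derived here.
    """
    if schema is None:
        schema = TraitSchema.from_panel()
    if isinstance(tab.columns, pd.MultiIndex):
        pieces = {}
        for subclass in tab.columns.get_level_values(0).unique():
            pieces[subclass] = _derive(tab[subclass], schema, FC_TRAITS, sialylation)
        return pd.concat(pieces, axis=1)
    return _derive(tab, schema, FC_TRAITS, sialylation)


def derive_total_traits(tab: pd.DataFrame, schema: TraitSchema | None = None,
                        sialylation: str = "presence") -> pd.DataFrame:
    """Derived traits (incl. core fucosylation) from a normalized 24-peak table."""
    if schema is None:
        schema = default_uplc_schema()
    return _derive(tab, schema, TOTAL_TRAITS, sialylation)
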