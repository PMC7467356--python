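"""Elemental compositions, monoisotopic masses, isotope envelopes and
multi-charge m/z values for IgG subclass-specific tryptic Fc glycopeptides.

The IgG Fc glycan is a complex biantennary N-glycan built on a core of four
GlcNAc and three mannose residues, optionally extended with galactose,
bisecting GlcNAc, core fucose and sialic acid (NeuAc).  Attached to the
conserved Asn-297 tryptic peptide of each heavy chain, it is measured here
as a glycopeptide.  This module is the chemistry substrate for everything
downstream: it turns a (peptide backbone, glycan composition) pair into an
elemental composition, a monoisotopic mass, an aggregated isotopologue
envelope and the m/z values of its 2+ and 3+ ions.

Isotopologue envelopes are aggregated by nucleon-number offset from the
monoisotopic species (isobaric fine structure is ignored, which is adequate
at the resolution of a quadrupole-TOF acquisition), computed by repeated
polynomial convolution of per-element isotope distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
import yaml

__all__ = [
    "ElementComposition",
    "GlycanComposition",
    "Glycopeptide",
    "IsotopeEnvelope",
    "elemental_composition",
    "monoisotopic_mass",
    "isotope_envelope",
    "glycopeptide_mz",
    "default_panel",
    "load_panel",
    "SUBCLASS_PEPTIDES",
    "PROTON_MASS",
    "NEUTRON_SPACING",
    "GLYCAN_RESIDUES",
]

# Monoisotopic (lightest-isotope) masses, Da.
ELEMENT_MASSES: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

# IUPAC isotopic abundances aggregated by nucleon-number offset from the
# lightest isotope.  Index i = offset of i nucleons.
ELEMENT_ISOTOPES: Dict[str, np.ndarray] = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

PROTON_MASS = 1.007276466622
# m/z spacing between adjacent isotopologues of a singly charged ion
# (13C-12C mass difference, the dominant contributor).
NEUTRON_SPACING = 1.0033548378

# Amino-acid residue compositions (residue = free amino acid minus water).
AMINO_ACID_RESIDUES: Dict[str, Dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER: Dict[str, int] = {"H": 2, "O": 1}

# Glycan residue (dehydrated monosaccharide) compositions.
GLYCAN_RESIDUES: Dict[str, Dict[str, int]] = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}

# Default tryptic Fc glycopeptide backbones.  The IgG3 Asn-297 peptide is
# allotype-dependent and co-elutes with IgG2 or IgG4, so it is not separable
# and carries no entry of its own.
SUBCLASS_PEPTIDES: Dict[str, str] = {
    "IgG1": "EEQYNSTYR",
    "IgG2": "EEQFNSTFR",
    "IgG4": "EEQFNSTYR",
}

SUBCLASSES: Tuple[str, ...] = ("IgG1", "IgG2", "IgG4")


@dataclass(frozen=True)
class ElementComposition:
    """Non-negative element counts (C, H, N, O, S).  Addition is element-wise."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASSES:
                raise ValueError(f"unknown element {el!r}")
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def __bool__(self) -> bool:
        return bool(self.counts)


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan.

    ``hex`` counts all hexoses (3 core mannoses + galactoses), ``hexnac``
    all N-acetylhexosamines (4 core GlcNAc + optional bisecting GlcNAc),
    ``dhex`` the core fucose, ``neuac`` the sialic acids.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self):
        for name in ("hex", "hexnac", "dhex", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative monosaccharide count: {name}")

    @property
    def galactoses(self) -> int:
        """Number of antennary galactoses (hexoses beyond the 3-mannose core)."""
        return max(self.hex - 3, 0)

    @property
    def bisecting(self) -> bool:
        """Bisecting GlcNAc present (a fifth HexNAc on the core)."""
        return self.hexnac >= 5

    @property
    def fucosylated(self) -> bool:
        return self.dhex >= 1

    @property
    def sialylated(self) -> bool:
        return self.neuac >= 1

    def residue_composition(self) -> ElementComposition:
        comp: Dict[str, int] = {}
        for name, count in (("hex", self.hex), ("hexnac", self.hexnac),
                            ("dhex", self.dhex), ("neuac", self.neuac)):
            for el, n in GLYCAN_RESIDUES[name].items():
                comp[el] = comp.get(el, 0) + n * count
        return ElementComposition(comp)


@dataclass(frozen=True)
class Glycopeptide:
    """A tryptic Fc glycopeptide: subclass backbone + one N-glycan."""

    subclass: str
    peptide: str
    glycan: GlycanComposition
    label: str = ""

    @classmethod
    def from_subclass(cls, subclass: str, glycan: GlycanComposition,
                      label: str = "") -> "Glycopeptide":
        if subclass not in SUBCLASS_PEPTIDES:
            raise ValueError(
                f"unknown subclass {subclass!r}; expected one of {sorted(SUBCLASS_PEPTIDES)}")
        return cls(subclass, SUBCLASS_PEPTIDES[subclass], glycan, label)


@dataclass
class IsotopeEnvelope:
    """Aggregated isotopologue distribution by nucleon-number offset.

    ``intensities[i]`` is the probability of the isotopologue class i
    nucleons above the monoisotopic species; the full (untruncated)
    distribution sums to 1, so the retained sum is the envelope fraction
    captured by the truncation.
    """

    monoisotopic_mass: float
    intensities: np.ndarray
    truncate: int

    @property
    def retained_fraction(self) -> float:
        return float(self.intensities.sum())


def elemental_composition(gp: Glycopeptide) -> ElementComposition:
    """Residue-summed peptide composition + water + glycan residues."""
    comp: Dict[str, int] = dict(WATER)
    for aa in gp.peptide:
        try:
            residue = AMINO_ACID_RESIDUES[aa]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid residue {aa!r} in peptide {gp.peptide!r}") from None
        for el, n in residue.items():
            comp[el] = comp.get(el, 0) + n
    return ElementComposition(comp) + gp.glycan.residue_composition()


def peptide_composition(sequence: str) -> ElementComposition:
    """Elemental composition of a free (non-glycosylated) peptide."""
    return elemental_composition(Glycopeptide("IgG1", sequence, GlycanComposition()))


def monoisotopic_mass(ec: ElementComposition) -> float:
    """Sum of count x lightest-isotope mass over the composition."""
    if not ec:
        raise ValueError("empty elemental composition has no mass")
    return sum(n * ELEMENT_MASSES[el] for el, n in ec.counts.items())


def _element_power(dist: np.ndarray, n: int) -> np.ndarray:
    """Distribution of n iid atoms: polynomial power by binary exponentiation."""
    result = np.array([1.0])
    base = dist.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def isotope_envelope(ec: ElementComposition, truncate: int = 4) -> IsotopeEnvelope:
    """Aggregated isotopologue envelope of a composition.

    Computed by repeated polynomial convolution of the per-element isotope
    distributions; the full distribution is normalized (it sums to 1 by
    construction) and the leading ``truncate`` offsets are retained.
    """
    if truncate < 1:
        raise ValueError(f"truncate must be >= 1, got {truncate}")
    if not ec:
        raise ValueError("empty elemental composition has no envelope")
    dist = np.array([1.0])
    for el, n in sorted(ec.counts.items()):
        dist = np.convolve(dist, _element_power(ELEMENT_ISOTOPES[el], n))
    return IsotopeEnvelope(
        monoisotopic_mass=monoisotopic_mass(ec),
        intensities=dist[:truncate].copy(),
        truncate=truncate,
    )


def mz_from_mass(mono_mass: float, charge: int, isotope_offset: int = 0) -> float:
    """m/z of the isotopologue ``isotope_offset`` nucleons above monoisotopic."""
    if charge not in (2, 3):
        raise ValueError(f"unsupported charge state {charge}; expected 2 or 3")
    if not 0 <= isotope_offset <= 3:
        raise ValueError(f"isotope offset must be in 0..3, got {isotope_offset}")
    return (mono_mass + isotope_offset * NEUTRON_SPACING
            + charge * PROTON_MASS) / charge


def glycopeptide_mz(gp: Glycopeptide, charge: int, isotope_offset: int = 0) -> float:
    """m/z of a glycopeptide ion at charge 2+ or 3+, isotopologue offset 0..3."""
    return mz_from_mass(monoisotopic_mass(elemental_composition(gp)),
                        charge, isotope_offset)


# ---------------------------------------------------------------------------
# Default glycoform panel


@dataclass(frozen=True)
class PanelEntry:
    label: str
    glycan: GlycanComposition


def _parse_panel(entries: Iterable[Mapping]) -> List[PanelEntry]:
    panel = []
    seen = set()
    for row in entries:
        label = str(row["label"])
        if label in seen:
            raise ValueError(f"duplicate glycoform label {label!r} in panel")
        seen.add(label)
        panel.append(PanelEntry(label, GlycanComposition(
            hex=int(row["hex"]), hexnac=int(row["hexnac"]),
            dhex=int(row["dhex"]), neuac=int(row["neuac"]))))
    return panel


def load_panel(path) -> List[PanelEntry]:
    """Load a glycoform panel from a YAML schema file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_panel(doc["glycoforms"])


_DEFAULT_PANEL: List[PanelEntry] | None = None


def default_panel() -> List[PanelEntry]:
    """The shipped 20-glycoform Fc panel (editable YAML schema)."""
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        ref = resources.files("igglycome.data").joinpath("fc_panel.yaml")
        doc = yaml.safe_load(ref.read_text())
        _DEFAULT_PANEL = _parse_panel(doc["glycoforms"])
    return _DEFAULT_PANEL


def panel_glycopeptides(subclass: str,
                        panel: List[PanelEntry] | None = None) -> List[Glycopeptide]:
    """Glycopeptide objects for every panel glycoform of one subclass."""
    if panel is None:
        panel = default_panel()
    return [Glycopeptide.from_subclass(subclass, e.glycan, e.label) for e in panel]
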