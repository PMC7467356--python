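"""Raw signals to relative abundances.

LC-MS path: centroid peak lists per sample x IgG subclass are internally
calibrated against a defined list of high-signal glycopeptides, signals of
all panel glycoforms are extracted in narrow m/z windows at both charge
states, the first four isotopologues of the 2+ and 3+ ions are summed per
species, and species are normalized to the total area of their subclass
(20 glycopeptides per subclass with the default panel).

UPLC path: raw 24-peak chromatographic area tables are total-area
normalized to relative abundances in %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import (Glycopeptide, PanelEntry, default_panel, glycopeptide_mz,
                   isotope_envelope, elemental_composition, NEUTRON_SPACING)
from .traits import TraitSchema, default_uplc_schema

__all__ = [
    "SpectrumPeakList",
    "CalibrationModel",
    "CalibrationError",
    "calibrate_spectrum",
    "extract_glycopeptide_signals",
    "sum_isotopologues",
    "normalize_subclass",
    "normalize_uplc",
    "quantify_fc_spectra",
    "collision_report",
    "DEFAULT_CALIBRANT_LABELS",
    "CHARGES",
    "N_ISOTOPOLOGUES",
]

CHARGES: Tuple[int, ...] = (2, 3)
N_ISOTOPOLOGUES = 4  # first four isotopic peaks summed per charge state
MZ_RANGE = (600.0, 1800.0)

# Calibrant list: the most abundant species of the conventional Fc
# repertoire (the fucosylated neutral species dominate human plasma IgG).
DEFAULT_CALIBRANT_LABELS: Tuple[str, ...] = (
    "G0F", "G1F", "G2F", "G0FN", "G1FN", "G2FS1")


@dataclass
class SpectrumPeakList:
    """Centroid (m/z, intensity) pairs for one sample x subclass window."""

    sample_id: str
    subclass: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if not (np.isfinite(self.mz).all() and np.isfinite(self.intensity).all()):
            raise ValueError("non-finite values in peak list")
        if (self.intensity < 0).any():
            raise ValueError("negative intensities in peak list")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


class CalibrationError(RuntimeError):
    """Raised when a spectrum cannot be internally calibrated."""


@dataclass
class CalibrationModel:
    """Affine internal mass calibration: m/z_corr = a * m/z_obs + b."""

    a: float
    b: float
    matches: pd.DataFrame
    residual_ppm: np.ndarray
    sample_id: str = ""
    subclass: str = ""

    @property
    def median_abs_residual_ppm(self) -> float:
        return float(np.median(np.abs(self.residual_ppm)))

    @property
    def n_calibrants(self) -> int:
        return int(self.matches["accepted"].sum())

    def apply(self, spec: SpectrumPeakList) -> SpectrumPeakList:
        return SpectrumPeakList(spec.sample_id, spec.subclass,
                                self.a * spec.mz + self.b, spec.intensity.copy())


def _nearest_peak(spec: SpectrumPeakList, center: float, tol: float) -> int:
    """Index of the closest centroid within +-tol of center, or -1."""
    lo = np.searchsorted(spec.mz, center - tol, side="left")
    hi = np.searchsorted(spec.mz, center + tol, side="right")
    if hi <= lo:
        return -1
    window = spec.mz[lo:hi]
    return lo + int(np.argmin(np.abs(window - center)))


def _theoretical_envelope(gp: Glycopeptide, truncate: int = N_ISOTOPOLOGUES) -> np.ndarray:
    env = isotope_envelope(elemental_composition(gp), truncate=truncate)
    return env.intensities


def _local_noise_floor(spec: SpectrumPeakList, anchor: float,
                       exclude: Sequence[float] | np.ndarray,
                       half_width: float = 2.0,
                       exclude_tol: float = 0.08) -> float:
    """Median intensity in +-half_width around anchor, excluding known
    analyte isotopologue positions (the candidate's own and those of all
    other panel species, which would otherwise inflate the floor).

    Falls back to the global median when the window is otherwise empty;
    a spectrum with no non-analyte peaks at all has a noise floor of 0.
    """
    lo = np.searchsorted(spec.mz, anchor - half_width, side="left")
    hi = np.searchsorted(spec.mz, anchor + half_width, side="right")
    keep = _non_analyte_mask(spec.mz[lo:hi], np.asarray(exclude), exclude_tol)
    if keep.any():
        return float(np.median(spec.intensity[lo:hi][keep]))
    # window holds nothing but analyte signal: fall back to the global
    # median of non-analyte peaks (0 when the spectrum is noise-free)
    keep_global = _non_analyte_mask(spec.mz, np.asarray(exclude), exclude_tol)
    if keep_global.any():
        return float(np.median(spec.intensity[keep_global]))
    return 0.0


def _non_analyte_mask(mz: np.ndarray, exclude: np.ndarray,
                      exclude_tol: float) -> np.ndarray:
    if len(mz) == 0:
        return np.zeros(0, dtype=bool)
    if len(exclude) == 0:
        return np.ones(len(mz), dtype=bool)
    dist = np.abs(mz[:, None] - exclude[None, :]).min(axis=1)
    return dist > exclude_tol


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def calibrate_spectrum(spec: SpectrumPeakList,
                       calibrants: Sequence[Glycopeptide] | None = None,
                       match_tol: float = 0.08,
                       snr_min: float = 9.0,
                       envelope_cos_min: float = 0.95,
                       k_min: int = 5) -> CalibrationModel:
    """Internal affine calibration against a defined calibrant list.

    Each calibrant species is looked up at both charge states; a candidate
    is accepted when its signal-to-noise ratio against the local median
    intensity and the cosine similarity between the observed and
    theoretical first-four isotopologue intensities pass their thresholds.
    The (observed, theoretical) monoisotopic m/z pairs of accepted
    candidates enter an ordinary least-squares affine fit.
    """
    panel = default_panel()
    if calibrants is None:
        by_label = {e.label: e for e in panel}
        calibrants = [Glycopeptide.from_subclass(spec.subclass, by_label[l].glycan, l)
                      for l in DEFAULT_CALIBRANT_LABELS]
    try:
        analyte_positions = _window_centers(panel, spec.subclass)["mz"].to_numpy()
    except ValueError:
        analyte_positions = np.empty(0)
    rows = []
    for gp in calibrants:
        env = _theoretical_envelope(gp)
        for charge in CHARGES:
            theo0 = glycopeptide_mz(gp, charge, 0)
            idx = _nearest_peak(spec, theo0, match_tol)
            if idx < 0:
                rows.append(dict(species=gp.label or gp.peptide, charge=charge,
                                 observed=np.nan, theoretical=theo0,
                                 snr=np.nan, envelope_cos=np.nan, accepted=False))
                continue
            obs0 = float(spec.mz[idx])
            # observed envelope anchored on the observed monoisotopic peak,
            # so a common drift does not break the pattern check
            positions = [obs0 + k * NEUTRON_SPACING / charge
                         for k in range(N_ISOTOPOLOGUES)]
            observed = np.zeros(N_ISOTOPOLOGUES)
            for k, pos in enumerate(positions):
                j = _nearest_peak(spec, pos, match_tol)
                if j >= 0:
                    observed[k] = spec.intensity[j]
            # exclude every known analyte position, shifted by the
            # candidate's apparent drift, from the noise estimate
            noise = _local_noise_floor(
                spec, obs0, analyte_positions + (obs0 - theo0))
            snr = np.inf if noise == 0 else float(spec.intensity[idx]) / noise
            cos = _cosine(observed, env)
            accepted = bool(snr >= snr_min and cos >= envelope_cos_min)
            rows.append(dict(species=gp.label or gp.peptide, charge=charge,
                             observed=obs0, theoretical=theo0,
                             snr=snr, envelope_cos=cos, accepted=accepted))
    matches = pd.DataFrame(rows)
    used = matches[matches["accepted"]]
    if len(used) < k_min:
        raise CalibrationError(
            f"calibration failed for sample {spec.sample_id!r} ({spec.subclass}): "
            f"only {len(used)} of {len(matches)} calibrant candidates accepted "
            f"(k_min={k_min})")
    a, b = np.polyfit(used["observed"].to_numpy(), used["theoretical"].to_numpy(), 1)
    corrected = a * used["observed"].to_numpy() + b
    residual_ppm = (corrected - used["theoretical"].to_numpy()) \
        / used["theoretical"].to_numpy() * 1e6
    return CalibrationModel(a=float(a), b=float(b), matches=matches,
                            residual_ppm=residual_ppm,
                            sample_id=spec.sample_id, subclass=spec.subclass)


def _window_centers(panel: Sequence[PanelEntry], subclass: str) -> pd.DataFrame:
    rows = []
    for entry in panel:
        gp = Glycopeptide.from_subclass(subclass, entry.glycan, entry.label)
        mono = chem.monoisotopic_mass(elemental_composition(gp))
        for charge in CHARGES:
            for offset in range(N_ISOTOPOLOGUES):
                rows.append(dict(glycoform=entry.label, charge=charge,
                                 offset=offset,
                                 mz=chem.mz_from_mass(mono, charge, offset)))
    return pd.DataFrame(rows)


def collision_report(panel: Sequence[PanelEntry] | None = None,
                     subclass: str = "IgG1",
                     tol_ppm: float = 10.0) -> pd.DataFrame:
    """Pairs of theoretical extraction windows that overlap at tol_ppm."""
    if panel is None:
        panel = default_panel()
    centers = _window_centers(panel, subclass)
    mz = centers["mz"].to_numpy()
    tol = mz * tol_ppm * 1e-6
    rows = []
    for i in range(len(mz)):
        for j in range(i + 1, len(mz)):
            if (centers.loc[i, "glycoform"] == centers.loc[j, "glycoform"]
                    and centers.loc[i, "charge"] == centers.loc[j, "charge"]):
                continue
            if abs(mz[i] - mz[j]) >= tol[i] + tol[j]:
                continue
            rows.append(dict(
                species_a=centers.loc[i, "glycoform"], charge_a=centers.loc[i, "charge"],
                offset_a=centers.loc[i, "offset"], mz_a=mz[i],
                species_b=centers.loc[j, "glycoform"], charge_b=centers.loc[j, "charge"],
                offset_b=centers.loc[j, "offset"], mz_b=mz[j],
                gap=abs(mz[i] - mz[j])))
    return pd.DataFrame(rows, columns=["species_a", "charge_a", "offset_a", "mz_a",
                                       "species_b", "charge_b", "offset_b", "mz_b",
                                       "gap"])


def extract_glycopeptide_signals(spec: SpectrumPeakList,
                                 panel: Sequence[PanelEntry] | None = None,
                                 tol_ppm: float = 10.0,
                                 warn_collisions: bool = True) -> pd.DataFrame:
    """Summed centroid intensity in a half-open window [c-tol, c+tol)
    around every theoretical (glycoform, charge, isotopologue) m/z.

    Returns a glycoform-indexed frame with (charge, offset) MultiIndex
    columns; absent signal contributes 0.
    """
    if panel is None:
        panel = default_panel()
    centers = _window_centers(panel, spec.subclass)
    if warn_collisions:
        rep = collision_report(panel, spec.subclass, tol_ppm)
        if len(rep):
            pairs = ", ".join(
                f"{r.species_a}(z{r.charge_a}+{r.offset_a})/"
                f"{r.species_b}(z{r.charge_b}+{r.offset_b})"
                for r in rep.itertuples())
            warnings.warn(f"overlapping extraction windows at {tol_ppm} ppm: {pairs}")
    glycoforms = [e.label for e in panel]
    out = pd.DataFrame(
        0.0, index=pd.Index(glycoforms, name="glycoform"),
        columns=pd.MultiIndex.from_product(
            [CHARGES, range(N_ISOTOPOLOGUES)], names=["charge", "offset"]))
    for row in centers.itertuples():
        tol = row.mz * tol_ppm * 1e-6
        lo = np.searchsorted(spec.mz, row.mz - tol, side="left")
        hi = np.searchsorted(spec.mz, row.mz + tol, side="left")  # half-open
        out.loc[row.glycoform, (row.charge, row.offset)] = \
            float(spec.intensity[lo:hi].sum())
    return out


def sum_isotopologues(extracted: pd.DataFrame) -> pd.Series:
    """Per-species raw abundance: sum over 2 charges x 4 isotopologues."""
    return extracted.sum(axis=1)


def normalize_subclass(raw: pd.DataFrame) -> pd.DataFrame:
    """Total-area normalization within each sample x subclass, in %.

    ``raw`` has samples in rows and either plain glycoform columns (one
    subclass) or a (subclass, glycoform) MultiIndex.  A sample whose
    subclass total is zero is marked missing (NaN), never divided 0/0.
    """
    if isinstance(raw.columns, pd.MultiIndex):
        pieces = {
            subclass: normalize_subclass(raw[subclass])
            for subclass in raw.columns.get_level_values(0).unique()
        }
        return pd.concat(pieces, axis=1)
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative raw abundances")
    totals = raw.sum(axis=1)
    out = raw.div(totals.where(totals > 0), axis=0) * 100.0
    return out


def normalize_uplc(raw: pd.DataFrame, schema: TraitSchema | None = None) -> pd.DataFrame:
    """Total-area normalization of a raw UPLC peak-area table, in %.

    The column set must match the schema (24 peaks by default); supply a
    custom schema to work with a different peak list.
    """
    if schema is None:
        schema = default_uplc_schema()
    expected = schema.labels
    if list(raw.columns) != expected:
        if set(raw.columns) == set(expected):
            raw = raw[expected]
        else:
            raise ValueError(
                f"expected the {len(expected)} schema peak columns "
                f"{expected[:3]}...; got {list(raw.columns)[:3]}... "
                f"({len(raw.columns)} columns). Supply a custom schema for "
                f"non-default peak tables.")
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative peak areas")
    totals = raw.sum(axis=1)
    return raw.div(totals.where(totals > 0), axis=0) * 100.0


def quantify_fc_spectra(spectra: Iterable[SpectrumPeakList],
                        panel: Sequence[PanelEntry] | None = None,
                        tol_ppm: float = 10.0,
                        calibrate: bool = True,
                        calibrants: Mapping[str, Sequence[Glycopeptide]] | None = None,
                        on_failure: str = "flag",
                        **calibration_kwargs) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Full LC-MS quantification: calibrate, extract, sum, normalize.

    Returns the abundance table (samples x (subclass, glycoform) in %) and
    a per-spectrum QC report.  ``on_failure`` controls what happens when a
    spectrum cannot be calibrated: "flag" records the failure and leaves
    the sample x subclass missing, "raise" propagates the error.
    """
    if panel is None:
        panel = default_panel()
    if on_failure not in ("flag", "raise"):
        raise ValueError("on_failure must be 'flag' or 'raise'")
    raw_rows: Dict[Tuple[str, str], pd.Series] = {}
    qc = []
    warned = set()
    for spec in spectra:
        record = dict(sample=spec.sample_id, subclass=spec.subclass,
                      n_peaks=len(spec), calibrated=False,
                      n_calibrants=np.nan, gain=np.nan, offset=np.nan,
                      median_abs_residual_ppm=np.nan, status="ok")
        work = spec
        if calibrate:
            try:
                cal = calibrate_spectrum(
                    spec,
                    calibrants=None if calibrants is None
                    else calibrants[spec.subclass],
                    **calibration_kwargs)
            except CalibrationError as err:
                if on_failure == "raise":
                    raise
                record["status"] = f"calibration_failed: {err}"
                qc.append(record)
                continue
            work = cal.apply(spec)
            record.update(calibrated=True, n_calibrants=cal.n_calibrants,
                          gain=cal.a, offset=cal.b,
                          median_abs_residual_ppm=cal.median_abs_residual_ppm)
        warn = spec.subclass not in warned
        warned.add(spec.subclass)
        extracted = extract_glycopeptide_signals(work, panel, tol_ppm,
                                                 warn_collisions=warn)
        raw_rows[(spec.sample_id, spec.subclass)] = sum_isotopologues(extracted)
        qc.append(record)
    qc_df = pd.DataFrame(qc)
    if not raw_rows:
        return pd.DataFrame(), qc_df
    samples = sorted({s for s, _ in raw_rows})
    subclasses = sorted({c for _, c in raw_rows})
    glycoforms = [e.label for e in panel]
    columns = pd.MultiIndex.from_product([subclasses, glycoforms],
                                         names=["subclass", "glycoform"])
    raw = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample"),
                       columns=columns)
    for (sample, subclass), series in raw_rows.items():
        for glycoform, value in series.items():
            raw.loc[sample, (subclass, glycoform)] = value
    return normalize_subclass(raw), qc_df
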