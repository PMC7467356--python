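"""File formats: the package peak-list dialect, mzML reading, and table IO.

Peak-list dialect (CSV): one centroid per row with columns
``sample,subclass,mz,intensity``; one file may hold many sample x
subclass windows.  The JSON variant is a list of objects with keys
``sample``, ``subclass``, ``mz`` (list) and ``intensity`` (list).
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .quantify import SpectrumPeakList

__all__ = [
    "PeakListFormatError",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_peaklist_json",
    "write_peaklist_json",
    "read_mzml",
]

PEAKLIST_COLUMNS = ("sample", "subclass", "mz", "intensity")


class PeakListFormatError(ValueError):
    """A malformed peak-list file; the message names the file and line."""


def read_peaklist_csv(path) -> List[SpectrumPeakList]:
    path = Path(path)
    buckets: Dict[Tuple[str, str], List[Tuple[float, float]]] = defaultdict(list)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(PEAKLIST_COLUMNS):
            raise PeakListFormatError(
                f"{path}:1: expected header {','.join(PEAKLIST_COLUMNS)}, "
                f"got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise PeakListFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            sample, subclass, mz_s, int_s = row
            try:
                mz = float(mz_s)
                intensity = float(int_s)
            except ValueError as err:
                raise PeakListFormatError(f"{path}:{lineno}: {err}") from None
            buckets[(sample, subclass)].append((mz, intensity))
    return [
        SpectrumPeakList(sample, subclass,
                         np.array([m for m, _ in peaks]),
                         np.array([i for _, i in peaks]))
        for (sample, subclass), peaks in buckets.items()
    ]


def write_peaklist_csv(spectra: Iterable[SpectrumPeakList], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAKLIST_COLUMNS)
        for spec in spectra:
            for mz, intensity in zip(spec.mz, spec.intensity):
                writer.writerow([spec.sample_id, spec.subclass,
                                 f"{mz:.6f}", f"{intensity:.6f}"])


def read_peaklist_json(path) -> List[SpectrumPeakList]:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for i, entry in enumerate(doc):
        try:
            out.append(SpectrumPeakList(
                entry["sample"], entry["subclass"],
                np.asarray(entry["mz"], dtype=float),
                np.asarray(entry["intensity"], dtype=float)))
        except (KeyError, TypeError, ValueError) as err:
            raise PeakListFormatError(f"{path}: entry {i}: {err}") from None
    return out


def write_peaklist_json(spectra: Iterable[SpectrumPeakList], path) -> None:
    doc = [
        {"sample": s.sample_id, "subclass": s.subclass,
         "mz": s.mz.tolist(), "intensity": s.intensity.tolist()}
        for s in spectra
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_mzml(path, sample_id: str, subclass: str) -> SpectrumPeakList:
    """Read one centroid mzML file into a single merged peak list."""
    from pyteomics import mzml as _mzml

    mz_parts, int_parts = [], []
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            mz_parts.append(np.asarray(scan["m/z array"], dtype=float))
            int_parts.append(np.asarray(scan["intensity array"], dtype=float))
    if not mz_parts:
        raise PeakListFormatError(f"{path}: no spectra found")
    return SpectrumPeakList(sample_id, subclass,
                            np.concatenate(mz_parts), np.concatenate(int_parts))
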