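"""Configuration and orchestration of the full analysis pipeline.

A single YAML config drives the run: either synthetic inputs are
generated (cohort, spectra, UPLC areas, indicators) or existing files are
read, then the stages run in order — LC-MS quantification, UPLC
normalization, derived traits, log transform + batch correction, mixed-
model variance decomposition, and country-level indicator correlation —
writing one CSV per product plus QC reports and a run log.  Given the
same config and seed the output CSVs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io, preprocess, quantify, simulate, traits as traits_mod, varcomp
from .indicators import aggregate_by_country, correlate_with_indicators

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("igglycome")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # synthetic-input parameters (used when no input paths are given)
    n_countries: int = 4
    n_per_country: int = 24
    drift_ppm: float = 0.0
    n_noise_peaks: int = 100
    mz_jitter_ppm: float = 0.5
    target_r: float = 0.9
    n_indicators: int = 10
    # optional real inputs
    peaklists: Optional[str] = None       # peak-list CSV (package dialect)
    metadata: Optional[str] = None        # sample,age,sex,country,batch CSV
    uplc_areas: Optional[str] = None      # samples x 24 raw areas CSV
    indicators: Optional[str] = None      # country x indicator CSV
    # stage options
    tol_ppm: float = 10.0
    sialylation: str = "presence"
    protect: List[str] = field(default_factory=lambda: ["country", "age", "sex"])

    def __post_init__(self):
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be > 0")
        for name in ("peaklists", "metadata", "uplc_areas", "indicators"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config {name}: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as err:
                logger.error("stage %s: FAILED: %s", name, err)
                raise PipelineError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run every stage and return the paths of the written products."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: Dict[str, Path] = {}
    try:
        # ---- inputs -----------------------------------------------------
        @_stage("inputs")
        def load_inputs():
            if config.peaklists is not None:
                spectra = io.read_peaklist_csv(config.peaklists)
                meta = pd.read_csv(config.metadata, index_col="sample")
                uplc = (pd.read_csv(config.uplc_areas, index_col=0)
                        if config.uplc_areas else None)
                ind = (pd.read_csv(config.indicators, index_col=0)
                       if config.indicators else None)
                return spectra, meta, uplc, ind
            design = simulate.CohortDesign(
                countries=[simulate.CountrySpec(name, config.n_per_country)
                           for name in simulate.DEFAULT_COUNTRIES[:config.n_countries]],
                seed=config.seed)
            cohort = simulate.simulate_cohort(design)
            spectra = list(simulate.render_spectra(
                cohort, drift_ppm=config.drift_ppm,
                n_noise_peaks=config.n_noise_peaks,
                mz_jitter_ppm=config.mz_jitter_ppm).values())
            uplc = simulate.simulate_uplc_table(cohort)
            ind, _ = simulate.simulate_indicators(
                cohort, target_r=config.target_r,
                n_indicators=config.n_indicators)
            return spectra, cohort.metadata, uplc, ind

        spectra, meta, uplc_areas, indicator_table = load_inputs()
        meta.to_csv(out / "metadata.csv")
        paths["metadata"] = out / "metadata.csv"

        # ---- LC-MS quantification ---------------------------------------
        @_stage("quantify-fc")
        def stage_quantify():
            table, qc = quantify.quantify_fc_spectra(
                spectra, tol_ppm=config.tol_ppm)
            return table, qc

        fc_abundance, qc = stage_quantify()
        fc_abundance.to_csv(out / "fc_abundance.csv")
        qc.to_csv(out / "calibration_qc.csv", index=False)
        paths["fc_abundance"] = out / "fc_abundance.csv"
        paths["calibration_qc"] = out / "calibration_qc.csv"

        # ---- derived traits ---------------------------------------------
        @_stage("traits")
        def stage_traits():
            fc_traits = traits_mod.derive_fc_traits(
                fc_abundance, sialylation=config.sialylation)
            total = None
            if uplc_areas is not None:
                normalized = quantify.normalize_uplc(uplc_areas)
                normalized.to_csv(out / "uplc_normalized.csv")
                paths["uplc_normalized"] = out / "uplc_normalized.csv"
                total = traits_mod.derive_total_traits(
                    normalized, sialylation=config.sialylation)
            return fc_traits, total

        fc_traits, total_traits = stage_traits()
        fc_traits.to_csv(out / "fc_traits.csv")
        paths["fc_traits"] = out / "fc_traits.csv"
        if total_traits is not None:
            total_traits.to_csv(out / "total_traits.csv")
            paths["total_traits"] = out / "total_traits.csv"

        # ---- preprocessing ----------------------------------------------
        @_stage("preprocess")
        def stage_preprocess():
            logged = preprocess.log_transform(fc_traits)
            protect = [c for c in config.protect if c in meta.columns]
            corrected = preprocess.combat_adjust(
                logged, meta.loc[logged.index, "batch"],
                covariates=meta.loc[logged.index, protect] if protect else None)
            return corrected

        corrected = stage_preprocess()
        corrected.to_csv(out / "fc_traits_corrected.csv")
        paths["fc_traits_corrected"] = out / "fc_traits_corrected.csv"

        # ---- variance decomposition -------------------------------------
        @_stage("varcomp")
        def stage_varcomp():
            return varcomp.decompose_variance(corrected, meta)

        decomposition = stage_varcomp()
        decomposition.to_csv(out / "variance_decomposition.csv", index=False)
        paths["variance_decomposition"] = out / "variance_decomposition.csv"

        # ---- indicator correlation --------------------------------------
        if indicator_table is not None:
            @_stage("correlate")
            def stage_correlate():
                country_traits = aggregate_by_country(
                    np.exp(corrected), meta)
                return correlate_with_indicators(country_traits, indicator_table)

            correlations = stage_correlate()
            correlations.to_csv(out / "correlations.csv", index=False)
            paths["correlations"] = out / "correlations.csv"
        return paths
    finally:
        logger.removeHandler(handler)
        handler.close()
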