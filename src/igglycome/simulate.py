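"""Synthetic cohorts, spectra, UPLC tables and country indicators.

The generator emulates the statistical structure the downstream analysis
assumes: per-individual glycoform compositions driven by a latent
galactosylation score with age and sex fixed effects, country random
effects, plate batch effects and residual noise; centroid spectra with
2+/3+ isotope envelopes and an injectable systematic mass error; 24-peak
UPLC area tables; and country-level development indicators correlated
with the countries' latent galactosylation.

The latent score g is mapped to the (agal, mono, digal) simplex by a
softmax over (-g, 0, g) scaled by a shape constant - a monotone,
invertible allocation - and each class share is distributed over the
glycoforms of that class with fixed baseline proportions, tilted by
smaller latent scores for sialylation and bisecting GlcNAc (the tilt is
renormalized within each galactosylation class, so the galactosylation
trio is exactly the softmax allocation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import PanelEntry, default_panel
from .quantify import SpectrumPeakList, CHARGES, N_ISOTOPOLOGUES, MZ_RANGE
from . import chem
from .traits import TraitSchema, default_uplc_schema

__all__ = [
    "CountrySpec",
    "CohortDesign",
    "SimulatedCohort",
    "default_design",
    "simulate_cohort",
    "render_spectra",
    "simulate_uplc_table",
    "true_uplc_composition",
    "simulate_indicators",
    "simulate_variance_benchmark",
    "DEFAULT_COUNTRIES",
    "FC_BASE_WEIGHTS",
]

DEFAULT_COUNTRIES: Tuple[str, ...] = (
    "China", "Croatia", "Germany", "India", "Italy", "Kazakhstan", "Kosovo",
    "Papua New Guinea", "Russia", "Sweden", "Thailand", "Turkey", "Uganda",
    "United Kingdom",
)

# Baseline Fc glycoform proportions (normalized within each
# galactosylation class at run time); roughly the composition of adult
# human plasma IgG1 Fc, where fucosylated neutral species dominate.
FC_BASE_WEIGHTS: Dict[str, float] = {
    "G0": 3.0, "G1": 2.0, "G2": 1.0,
    "G0N": 0.5, "G1N": 0.5, "G2N": 0.3,
    "G0F": 22.0, "G1F": 30.0, "G2F": 12.0,
    "G0FN": 4.0, "G1FN": 3.5, "G2FN": 1.0,
    "G1S1": 0.5, "G2S1": 1.0, "G2S2": 0.3,
    "G1FS1": 6.0, "G2FS1": 8.0, "G2FS2": 1.5,
    "G1FNS1": 1.5, "G2FNS1": 1.6,
}

SUBCLASS_G_OFFSETS: Dict[str, float] = {"IgG1": 0.10, "IgG2": -0.10, "IgG4": 0.0}


@dataclass(frozen=True)
class CountrySpec:
    name: str
    n: int
    age_range: Tuple[int, int] = (18, 70)
    female_fraction: float = 0.5


@dataclass
class CohortDesign:
    """Study design and effect sizes of the synthetic cohort.

    Effect sizes act on the latent galactosylation score g (dimensionless;
    a unit change of g moves the digalactosylation share by roughly
    ``shape``/3 x 100 percentage points near the simplex center).
    """

    countries: List[CountrySpec]
    plate_size: int = 96
    seed: int = 0
    # latent galactosylation model
    beta0: float = 0.0
    age_slope: float = -0.013      # per year of age; galactosylation falls with age
    sex_offset: float = 0.02       # female minus male
    country_sd: float = 0.25
    batch_sd: float = 0.05
    residual_sd: float = 0.30
    subclass_sd: float = 0.05      # extra subclass-specific noise on g
    shape: float = 1.0             # softmax scale of the latent-to-simplex map
    age_center: float = 44.0
    # smaller analogous latents
    sial_country_sd: float = 0.10
    sial_residual_sd: float = 0.15
    sial_age_slope: float = -0.004
    bisect_country_sd: float = 0.08
    bisect_residual_sd: float = 0.12
    bisect_age_slope: float = 0.004
    fucose_country_sd: float = 0.15
    fucose_residual_sd: float = 0.10

    def __post_init__(self):
        for name in ("country_sd", "batch_sd", "residual_sd", "subclass_sd",
                     "sial_country_sd", "sial_residual_sd",
                     "bisect_country_sd", "bisect_residual_sd",
                     "fucose_country_sd", "fucose_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.countries:
            raise ValueError("design needs at least one country")
        for c in self.countries:
            if c.n <= 0:
                raise ValueError(f"non-positive sample count for {c.name!r}")
            if not 0 <= c.female_fraction <= 1:
                raise ValueError(f"invalid sex ratio for {c.name!r}")

    @property
    def n_samples(self) -> int:
        return sum(c.n for c in self.countries)

    @property
    def latent_icc(self) -> float:
        """Analytic intraclass correlation of the latent score
        (country share of the non-fixed variance)."""
        denom = self.country_sd**2 + self.batch_sd**2 + self.residual_sd**2
        return self.country_sd**2 / denom if denom > 0 else 0.0


def default_design(seed: int = 0) -> CohortDesign:
    """14 countries x 184 samples (n=2,576), ages 18-70, plates of 96."""
    return CohortDesign(
        countries=[CountrySpec(name, 184) for name in DEFAULT_COUNTRIES],
        seed=seed)


@dataclass
class SimulatedCohort:
    """Metadata, true compositions and the full truth record of one draw."""

    design: CohortDesign
    metadata: pd.DataFrame            # sample, age, sex, country, batch
    compositions: Dict[str, pd.DataFrame]  # subclass -> samples x glycoforms (%)
    latents: pd.DataFrame             # per-sample latent scores and components
    truth: Dict                       # drawn effects, analytic quantities

    @property
    def samples(self) -> pd.Index:
        return self.metadata.index


def _softmax_shares(g: np.ndarray, shape: float) -> np.ndarray:
    """(n, 3) array of (agal, mono, digal) shares: softmax(shape * (-g, 0, g))."""
    logits = np.column_stack([-shape * g, np.zeros_like(g), shape * g])
    logits -= logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    return ex / ex.sum(axis=1, keepdims=True)


def _class_composition(shares: np.ndarray, sial: np.ndarray, bis: np.ndarray,
                       labels: Sequence[str], gal: np.ndarray,
                       sial_flag: np.ndarray, bis_flag: np.ndarray,
                       base: np.ndarray,
                       fuc: np.ndarray | None = None,
                       fuc_flag: np.ndarray | None = None) -> np.ndarray:
    """Distribute class shares over glycoforms with tilted base weights.

    Tilts are renormalized within each galactosylation class, so the
    class (trio) shares are preserved exactly.
    """
    n = len(shares)
    logw = np.log(base)[None, :] \
        + np.outer(sial, sial_flag) + np.outer(bis, bis_flag)
    if fuc is not None and fuc_flag is not None:
        logw = logw + np.outer(fuc, fuc_flag)
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    comp = np.zeros((n, len(labels)))
    for k in (0, 1, 2):
        cls = gal == k
        wk = w[:, cls]
        comp[:, cls] = shares[:, [k]] * wk / wk.sum(axis=1, keepdims=True)
    return comp * 100.0


def simulate_cohort(design: CohortDesign,
                    panel: Sequence[PanelEntry] | None = None) -> SimulatedCohort:
    """Draw one cohort: metadata, latent scores and true compositions.

    Deterministic given ``design`` (which carries the seed): the same
    design yields byte-identical tables.
    """
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(design.seed)
    rows = []
    for spec in design.countries:
        lo, hi = spec.age_range
        ages = rng.integers(lo, hi + 1, size=spec.n)
        sexes = np.where(rng.random(spec.n) < spec.female_fraction, "F", "M")
        for a, s in zip(ages, sexes):
            rows.append((spec.name, int(a), s))
    meta = pd.DataFrame(rows, columns=["country", "age", "sex"])
    meta.index = pd.Index([f"S{i+1:05d}" for i in range(len(meta))], name="sample")

    # plate assignment: order by (country, sex, age) and deal round-robin,
    # so every plate gets a balanced mix of countries, sexes and ages
    n_plates = max(1, math.ceil(len(meta) / design.plate_size))
    order = meta.sort_values(["country", "sex", "age"]).index
    plates = pd.Series(index=order,
                       data=[f"P{(i % n_plates) + 1:02d}" for i in range(len(order))])
    meta["batch"] = plates.reindex(meta.index)

    countries = [c.name for c in design.countries]
    u = dict(zip(countries, rng.normal(0.0, design.country_sd, len(countries))))
    u_sial = dict(zip(countries, rng.normal(0.0, design.sial_country_sd, len(countries))))
    u_bis = dict(zip(countries, rng.normal(0.0, design.bisect_country_sd, len(countries))))
    u_fuc = dict(zip(countries, rng.normal(0.0, design.fucose_country_sd, len(countries))))
    plate_names = sorted(meta["batch"].unique())
    b = dict(zip(plate_names, rng.normal(0.0, design.batch_sd, len(plate_names))))

    n = len(meta)
    age_c = meta["age"].to_numpy(float) - design.age_center
    female = (meta["sex"] == "F").to_numpy(float)
    eps = rng.normal(0.0, design.residual_sd, n)
    g_common = (design.beta0 + design.age_slope * age_c
                + design.sex_offset * female
                + meta["country"].map(u).to_numpy()
                + meta["batch"].map(b).to_numpy()
                + eps)
    sial = (design.sial_age_slope * age_c
            + meta["country"].map(u_sial).to_numpy()
            + rng.normal(0.0, design.sial_residual_sd, n))
    bis = (design.bisect_age_slope * age_c
           + meta["country"].map(u_bis).to_numpy()
           + rng.normal(0.0, design.bisect_residual_sd, n))
    fuc = (meta["country"].map(u_fuc).to_numpy()
           + rng.normal(0.0, design.fucose_residual_sd, n))

    labels = [e.label for e in panel]
    base = np.array([FC_BASE_WEIGHTS.get(l, 1.0) for l in labels])
    gal = np.array([e.glycan.galactoses for e in panel])
    sial_flag = np.array([float(e.glycan.sialylated) for e in panel])
    bis_flag = np.array([float(e.glycan.bisecting) for e in panel])

    latents = pd.DataFrame({
        "g": g_common, "sial": sial, "bisect": bis, "fucose": fuc,
        "age_term": design.age_slope * age_c,
        "sex_term": design.sex_offset * female,
        "country_effect": meta["country"].map(u).to_numpy(),
        "batch_effect": meta["batch"].map(b).to_numpy(),
        "residual": eps,
    }, index=meta.index)

    compositions = {}
    for subclass, offset in SUBCLASS_G_OFFSETS.items():
        g_sub = g_common + offset
        if design.subclass_sd > 0:
            g_sub = g_sub + rng.normal(0.0, design.subclass_sd, n)
        latents[f"g_{subclass}"] = g_sub
        shares = _softmax_shares(g_sub, design.shape)
        comp = _class_composition(shares, sial, bis, labels, gal,
                                  sial_flag, bis_flag, base)
        compositions[subclass] = pd.DataFrame(comp, index=meta.index,
                                              columns=labels)

    truth = {
        "country_effects": u,
        "country_effects_sial": u_sial,
        "country_effects_bisect": u_bis,
        "country_effects_fucose": u_fuc,
        "batch_effects": b,
        "latent_icc": design.latent_icc,
        "design": {
            k: v for k, v in asdict(design).items() if k != "countries"},
    }
    return SimulatedCohort(design=design, metadata=meta,
                           compositions=compositions, latents=latents,
                           truth=truth)


# ---------------------------------------------------------------------------
# Spectra


def render_spectra(cohort: SimulatedCohort,
                   drift_ppm: float = 0.0,
                   n_noise_peaks: int = 150,
                   noise_intensity: float = 2e-4,
                   mz_jitter_ppm: float = 0.0,
                   seed: int | None = None,
                   subclasses: Sequence[str] | None = None,
                   samples: Sequence[str] | None = None,
                   charge_split: Tuple[float, float] = (0.7, 0.3),
                   full_envelope: bool = False,
                   panel: Sequence[PanelEntry] | None = None,
                   ) -> Dict[Tuple[str, str], SpectrumPeakList]:
    """Render centroid peak lists for each sample x subclass.

    Each glycoform with non-zero abundance produces peaks at the first
    four isotopologues of its 2+ and 3+ ions; all m/z values are scaled by
    (1 + drift_ppm x 1e-6) to inject a systematic calibration error, and
    optionally jittered per peak.  By default isotopologue intensities are
    the envelope fractions renormalized over the retained four peaks (so
    the emitted peaks carry the species' full signal); ``full_envelope``
    instead emits the first eight isotopologues with absolute envelope
    fractions, exposing the species-dependent truncation loss.  Uniform
    random noise peaks are added and output is restricted to the
    600-1800 m/z acquisition range.
    """
    if abs(drift_ppm) > 100:
        raise ValueError("drift must be within +-100 ppm")
    if panel is None:
        panel = default_panel()
    if subclasses is None:
        subclasses = list(cohort.compositions)
    rng = np.random.default_rng(cohort.design.seed + 1 if seed is None else seed)
    n_emit = 8 if full_envelope else N_ISOTOPOLOGUES
    split = {2: charge_split[0], 3: charge_split[1]}

    # theoretical m/z grids and envelope fractions per subclass
    theo: Dict[str, Dict[str, Tuple[np.ndarray, np.ndarray]]] = {}
    for subclass in subclasses:
        per = {}
        for entry in panel:
            gp = chem.Glycopeptide.from_subclass(subclass, entry.glycan, entry.label)
            mono = chem.monoisotopic_mass(chem.elemental_composition(gp))
            env = chem.isotope_envelope(chem.elemental_composition(gp),
                                        truncate=n_emit).intensities
            if not full_envelope:
                env = env / env.sum()
            mzs = np.array([[ (mono + k * chem.NEUTRON_SPACING
                               + z * chem.PROTON_MASS) / z
                              for k in range(n_emit)] for z in CHARGES])
            per[entry.label] = (mzs, env)
        theo[subclass] = per

    sample_ids = list(cohort.samples if samples is None else samples)
    out: Dict[Tuple[str, str], SpectrumPeakList] = {}
    for sample in sample_ids:
        for subclass in subclasses:
            comp = cohort.compositions[subclass].loc[sample]
            scale = 1e6 * rng.lognormal(0.0, 0.2)
            mz_list, int_list = [], []
            for entry in panel:
                abundance = comp[entry.label]
                if abundance <= 0:
                    continue
                mzs, env = theo[subclass][entry.label]
                for zi, z in enumerate(CHARGES):
                    inten = scale * (abundance / 100.0) * env * split[z]
                    mz_list.append(mzs[zi])
                    int_list.append(inten)
            mz = np.concatenate(mz_list) if mz_list else np.empty(0)
            inten = np.concatenate(int_list) if int_list else np.empty(0)
            mz = mz * (1.0 + drift_ppm * 1e-6)
            if mz_jitter_ppm > 0:
                mz = mz * (1.0 + rng.normal(0.0, mz_jitter_ppm, len(mz)) * 1e-6)
            if n_noise_peaks > 0:
                noise_mz = rng.uniform(*MZ_RANGE, n_noise_peaks)
                noise_int = rng.exponential(noise_intensity * scale, n_noise_peaks)
                mz = np.concatenate([mz, noise_mz])
                inten = np.concatenate([inten, noise_int])
            keep = (mz >= MZ_RANGE[0]) & (mz <= MZ_RANGE[1])
            out[(sample, subclass)] = SpectrumPeakList(
                sample, subclass, mz[keep], inten[keep])
    return out


# ---------------------------------------------------------------------------
# UPLC


def true_uplc_composition(cohort: SimulatedCohort,
                          schema: TraitSchema | None = None) -> pd.DataFrame:
    """Noise-free total-glycome composition (%) implied by the cohort latents."""
    if schema is None:
        schema = default_uplc_schema()
    g = cohort.latents["g"].to_numpy()
    sial = cohort.latents["sial"].to_numpy()
    bis = cohort.latents["bisect"].to_numpy()
    fuc = cohort.latents["fucose"].to_numpy()
    shares = _softmax_shares(g, cohort.design.shape)
    labels = schema.labels
    gal = np.array([schema[l].galactoses for l in labels])
    sial_flag = np.array([float(schema[l].sialic_acids >= 1) for l in labels])
    bis_flag = np.array([float(schema[l].bisecting) for l in labels])
    fuc_flag = np.array([float(schema[l].core_fucose) for l in labels])
    base = np.array([schema[l].weight for l in labels])
    comp = _class_composition(shares, sial, bis, labels, gal, sial_flag,
                              bis_flag, base, fuc, fuc_flag)
    return pd.DataFrame(comp, index=cohort.samples, columns=labels)


def simulate_uplc_table(cohort: SimulatedCohort,
                        seed: int | None = None,
                        noise_cv: float = 0.02,
                        schema: TraitSchema | None = None) -> pd.DataFrame:
    """Raw 24-peak UPLC area table whose normalized values carry the
    cohort's trait structure; total area per sample is arbitrary."""
    if schema is None:
        schema = default_uplc_schema()
    comp = true_uplc_composition(cohort, schema)
    rng = np.random.default_rng(cohort.design.seed + 2 if seed is None else seed)
    total = 1e5 * rng.lognormal(0.0, 0.3, len(comp))
    areas = comp.to_numpy() / 100.0 * total[:, None]
    if noise_cv > 0:
        areas = areas * rng.lognormal(0.0, noise_cv, areas.shape)
    return pd.DataFrame(areas, index=comp.index, columns=comp.columns)


# ---------------------------------------------------------------------------
# Country indicators


def simulate_indicators(cohort: SimulatedCohort,
                        target_r: float = 0.9,
                        n_indicators: int = 45,
                        seed: int | None = None,
                        ) -> Tuple[pd.DataFrame, Dict]:
    """Country x indicator table with a controlled country-level correlation.

    Each indicator is an affine function of the countries' realized mean
    latent galactosylation score plus independent Gaussian noise scaled so
    the expected Pearson correlation with the true country means equals
    ``target_r`` (sign included).
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("|target_r| must be <= 1")
    means = cohort.latents["g"].groupby(cohort.metadata["country"]).mean()
    if len(means) < 3:
        raise ValueError(
            f"need at least 3 countries for a defined correlation, got {len(means)}")
    rng = np.random.default_rng(cohort.design.seed + 3 if seed is None else seed)
    x = means.to_numpy()
    sd_x = x.std(ddof=1)
    columns = {}
    if target_r == 0.0:
        for j in range(n_indicators):
            columns[f"IND{j+1:02d}"] = 50.0 + rng.normal(0.0, 1.0, len(x))
    else:
        gamma = math.copysign(1.0, target_r)
        sigma_delta = sd_x * math.sqrt(1.0 / target_r**2 - 1.0)
        for j in range(n_indicators):
            delta = rng.normal(0.0, sigma_delta, len(x)) if sigma_delta > 0 else 0.0
            columns[f"IND{j+1:02d}"] = 50.0 + 10.0 * (gamma * x + delta)
    table = pd.DataFrame(columns, index=means.index)
    truth = {"country_means": means, "target_r": target_r}
    return table, truth


# ---------------------------------------------------------------------------
# Mixed-model benchmark


def simulate_variance_benchmark(seed: int,
                                n_countries: int = 14,
                                n_per_country: int = 184,
                                country_share: float = 0.38,
                                age_share: float = 0.026,
                                sex_share: float = 0.001,
                                total_var: float = 1.0,
                                age_range: Tuple[int, int] = (18, 70),
                                ) -> Tuple[pd.DataFrame, Dict]:
    """One draw from the linear mixed-model data law of the variance
    decomposition: y = b0 + b_age age + b_sex sex + u_country + eps, with
    the design variance shares prescribed.

    The truth record reports the *realized* shares of this draw (between-
    country variance of the drawn random intercepts, realized variance of
    the fixed predictor, realized residual variance): with few countries
    the realized between-country spread fluctuates substantially around
    its design value, and the model can only be asked to recover what was
    drawn.
    """
    if not 0 <= country_share + age_share + sex_share < 1:
        raise ValueError("variance shares must be in [0, 1) and sum below 1")
    rng = np.random.default_rng(seed)
    n = n_countries * n_per_country
    country = np.repeat([f"C{j+1:02d}" for j in range(n_countries)], n_per_country)
    ages = rng.integers(age_range[0], age_range[1] + 1, n).astype(float)
    female = (rng.random(n) < 0.5).astype(float)

    sd_age_design = math.sqrt(((age_range[1] - age_range[0] + 1) ** 2 - 1) / 12.0)
    beta_age = math.sqrt(age_share * total_var) / sd_age_design
    beta_sex = 2.0 * math.sqrt(sex_share * total_var)  # Bernoulli(1/2) var = 1/4
    sigma_u = math.sqrt(country_share * total_var)
    sigma_e = math.sqrt(
        total_var * (1.0 - country_share - age_share - sex_share))

    u = rng.normal(0.0, sigma_u, n_countries)
    eps = rng.normal(0.0, sigma_e, n)
    fixed = beta_age * (ages - ages.mean()) + beta_sex * female
    y = 10.0 + fixed + np.repeat(u, n_per_country) + eps

    df = pd.DataFrame({
        "y": y, "age": ages,
        "sex": np.where(female > 0, "F", "M"),
        "country": country,
    })
    var_u_real = float(np.var(u, ddof=1))
    var_fixed_real = float(np.var(fixed))
    var_age_real = float(np.var(beta_age * ages))
    var_sex_real = float(np.var(beta_sex * female))
    var_e_real = float(np.var(eps))
    denom = var_fixed_real + var_u_real + var_e_real
    truth = {
        "beta_age": beta_age, "beta_sex": beta_sex,
        "sigma2_country": sigma_u**2, "sigma2_resid": sigma_e**2,
        "realized": {
            "sigma2_country": var_u_real,
            "sigma2_resid": var_e_real,
            "var_fixed": var_fixed_real,
            "country_share_pct": 100.0 * var_u_real / denom,
            "age_share_pct": 100.0 * var_age_real / denom,
            "sex_share_pct": 100.0 * var_sex_real / denom,
        },
        "design_shares_pct": {
            "country": 100.0 * country_share,
            "age": 100.0 * age_share,
            "sex": 100.0 * sex_share,
        },
    }
    return df, truth
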