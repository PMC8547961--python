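"""Synthetic liquid-phase FTIR serum cohorts with known ground truth.

The study data behind blood-based infrared fingerprinting are clinical and
non-public, so every downstream stage is exercised on simulated cohorts that
emulate the salient physics and statistics of the real measurement:

* serum-like absorption bands (amide I/II, CH bending, carbohydrate, lipid
  ester, CH stretch) with log-normal between-person amplitude variation;
* a *negative* water-displacement baseline: a sample containing less water
  than the pure-water reference appears as the solute spectrum minus a
  multiple beta of the water reference, with beta proportional to the total
  solute load;
* smooth correlated biological deviations plus small white measurement
  noise (measurement error is small compared to biological variability);
* optional covariate confounding (age/BMI scale two bands) and a disease
  signature whose amplitude grows with tumour T class.

Ground truth (every beta, delta and label) is returned so that recovery can
be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import CohortSet, Spectrum, WavenumberGrid

__all__ = [
    "BandModel",
    "DiseaseSignature",
    "SimConfig",
    "GroundTruth",
    "default_serum_bands",
    "default_disease_signature",
    "water_reference_spectrum",
    "sample_person_spectrum",
    "generate_cohort",
    "generate_multigroup_cohort",
    "inject_artifacts",
]


@dataclass(frozen=True)
class BandModel:
    """A Gaussian absorption band: center/width in cm^-1, amplitude in AU."""

    center: float
    width: float
    amplitude: float
    concentration_cv: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0 or self.concentration_cv < 0:
            raise ValueError("amplitude and concentration_cv must be >= 0")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavenumbers, float) - self.center) / self.width
        return np.exp(-0.5 * z * z)


def default_serum_bands() -> list[BandModel]:
    """Eight bands loosely mimicking a serum absorption spectrum.

    Amide I dominates; amplitudes are plausible for an ~8 um path length.
    """
    return [
        BandModel(1652.0, 25.0, 0.30, 0.08, "amide I"),
        BandModel(1545.0, 22.0, 0.18, 0.08, "amide II"),
        BandModel(1450.0, 15.0, 0.06, 0.10, "CH2 bend"),
        BandModel(1400.0, 15.0, 0.05, 0.10, "CH3/COO-"),
        BandModel(1080.0, 40.0, 0.05, 0.15, "carbohydrate"),
        BandModel(1160.0, 20.0, 0.03, 0.15, "carbohydrate C-O"),
        BandModel(1740.0, 12.0, 0.02, 0.25, "lipid ester C=O"),
        BandModel(2930.0, 35.0, 0.08, 0.12, "CH stretch asym"),
        BandModel(2870.0, 20.0, 0.04, 0.12, "CH stretch sym"),
    ]


@dataclass(frozen=True)
class DiseaseSignature:
    """Unit-norm differential shape scaled per tumour T class."""

    signature: np.ndarray
    amplitude_per_stage: dict = field(
        default_factory=lambda: {"T1": 0.005, "T2": 0.013,
                                 "T3": 0.024, "T4": 0.040})

    def __post_init__(self) -> None:
        sig = np.asarray(self.signature, dtype=float)
        nrm = float(np.linalg.norm(sig))
        if nrm <= 0:
            raise ValueError("signature must be nonzero")
        object.__setattr__(self, "signature", sig / nrm)
        amps = self.amplitude_per_stage
        if any(a < 0 for a in amps.values()):
            raise ValueError("stage amplitudes must be >= 0")

    def scaled(self, factor: float) -> "DiseaseSignature":
        return DiseaseSignature(
            self.signature,
            {k: v * factor for k, v in self.amplitude_per_stage.items()})


def default_disease_signature(grid: WavenumberGrid) -> DiseaseSignature:
    """A smooth signature: amide-shoulder gain, carbohydrate loss, lipid gain.

    Centers are deliberately offset from the bulk serum bands: a disease
    leaves shoulders and shape changes, not a uniform rescaling of the
    healthy bands (which between-person variability already produces).
    """
    wn = np.asarray(grid, dtype=float)

    def g(c, w):
        return np.exp(-0.5 * ((wn - c) / w) ** 2)

    shape = g(1590.0, 20.0) - 0.7 * g(1120.0, 25.0) + 0.5 * g(1700.0, 15.0) \
        + 0.3 * g(2960.0, 25.0)
    return DiseaseSignature(shape)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings (defaults are the study conditions)."""

    n_cases: int = 200
    n_refs: int = 200
    seed: int = 0
    noise_sd: float = 0.002            # white measurement noise, AU
    bio_smooth_sd: float = 0.004       # smooth biological deviation, AU
    bio_smooth_corr: float = 25.0      # correlation length, cm^-1
    water_deficit_mean: float = 0.10   # mean beta at nominal solute load
    water_deficit_sd: float = 0.03
    covariate_confounding: float = 0.3
    outlier_fraction: float = 0.0
    age_shift: float = 5.0             # case-minus-reference mean age, years
    bmi_shift: float = 1.0             # kg/m^2
    male_fraction_case: float = 0.6
    male_fraction_ref: float = 0.5
    stage_probs: tuple = (0.30, 0.30, 0.25, 0.15)  # T1..T4

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_refs < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sd < 0 or self.bio_smooth_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Per-sample simulation truth, keyed by sample id."""

    beta: dict
    delta: dict
    label: dict
    t_class: dict
    artifact_ids: list = field(default_factory=list)


# --------------------------------------------------------------------- water
def water_reference_spectrum(grid: WavenumberGrid) -> Spectrum:
    """Deterministic stand-in for a measured pure-water absorption spectrum.

    Broad H-O-H bending band near 1640 cm^-1, a rising O-H stretch wing
    toward 3050 cm^-1, and a gentle linear ramp so the OLS slope over the
    2000-2300 cm^-1 flat window is nonzero (which makes the water-correction
    coefficient identifiable).
    """
    wn = np.asarray(grid, dtype=float)
    bend = 0.75 * np.exp(-0.5 * ((wn - 1640.0) / 100.0) ** 2)
    stretch = 1.2 / (1.0 + np.exp(-(wn - 3020.0) / 90.0))
    ramp = 1.5e-4 * (wn - 950.0)
    return Spectrum(wn, bend + stretch + ramp)


def _smooth_noise(rng: np.random.Generator, wn: np.ndarray,
                  sd: float, corr: float) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise with pointwise SD ``sd``."""
    if sd == 0:
        return np.zeros_like(wn)
    step = float(np.median(np.diff(wn)))
    sigma_pts = max(corr / step, 1e-6)
    half = int(np.ceil(4 * sigma_pts))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_pts) ** 2)
    kern /= np.sqrt(np.sum(kern ** 2))  # unit output variance
    white = rng.standard_normal(wn.size + 2 * half)
    return sd * np.convolve(white, kern, mode="valid")


def sample_person_spectrum(grid, bands: list[BandModel], water: Spectrum,
                           rng: np.random.Generator, *,
                           noise_sd: float = 0.002,
                           bio_smooth_sd: float = 0.0,
                           bio_smooth_corr: float = 25.0,
                           water_deficit_mean: float = 0.10,
                           water_deficit_sd: float = 0.03,
                           extra: np.ndarray | None = None,
                           band_scale: np.ndarray | None = None):
    """Draw one person's measured spectrum; returns ``(Spectrum, beta)``.

    The clean solute spectrum is the band sum with log-normal per-person
    amplitudes (mean equal to the nominal band amplitude, CV equal to the
    band's ``concentration_cv``); the water deficit beta is log-normal with
    mean proportional to the person's total solute load; ``extra`` (e.g. a
    disease signature) is added before noise.
    """
    if not bands:
        raise ValueError("at least one band is required")
    wn = np.asarray(grid, dtype=float)
    nominal = sum(b.amplitude for b in bands)
    amps = np.empty(len(bands))
    for i, b in enumerate(bands):
        if b.concentration_cv > 0:
            s = np.sqrt(np.log1p(b.concentration_cv ** 2))
            amps[i] = b.amplitude * np.exp(rng.normal(-0.5 * s * s, s))
        else:
            amps[i] = b.amplitude
    if band_scale is not None:
        amps = amps * np.asarray(band_scale, dtype=float)
    solute = np.zeros_like(wn)
    envelope = np.zeros_like(wn)
    for a, b in zip(amps, bands):
        solute += a * b.profile(wn)
        envelope += b.amplitude * b.profile(wn)
    envelope /= envelope.max()
    solute_load = float(amps.sum())

    if water_deficit_mean > 0:
        cv = water_deficit_sd / water_deficit_mean
        s = np.sqrt(np.log1p(cv ** 2))
        mult = np.exp(rng.normal(-0.5 * s * s, s)) if cv > 0 else 1.0
        beta = water_deficit_mean * (solute_load / nominal) * mult
    else:
        beta = 0.0

    absorb = solute - beta * water.absorbance
    if extra is not None:
        absorb = absorb + np.asarray(extra, dtype=float)
    # biological variability lives where biomolecules absorb: shaping by the
    # solute envelope keeps the 2000-2300 cm^-1 window solute-free, as for
    # real dried serum
    absorb = absorb + envelope * _smooth_noise(rng, wn, bio_smooth_sd,
                                               bio_smooth_corr)
    if noise_sd > 0:
        absorb = absorb + rng.normal(0.0, noise_sd, wn.size)
    return Spectrum(wn, absorb), beta


# -------------------------------------------------------------------- cohorts
_SITES = ("clinic_A", "clinic_B", "clinic_C")
_SITE_P = (0.5, 0.3, 0.2)


def _draw_covariates(rng, n, *, age_mean, male_fraction, bmi_mean):
    age = np.clip(rng.normal(age_mean, 10.0, n), 30.0, 85.0)
    sex = (rng.random(n) < male_fraction).astype(int)
    bmi = np.clip(rng.normal(bmi_mean, 3.5, n), 17.0, 42.0)
    site = rng.choice(_SITES, size=n, p=_SITE_P)
    return age, sex, bmi, site


def _confound_scale(bands, age, bmi, strength):
    """Per-band amplitude factors: age scales amide II, BMI the lipid band."""
    scale = np.ones(len(bands))
    for i, b in enumerate(bands):
        if b.name == "amide II":
            scale[i] = 1.0 + strength * (age - 55.0) / 30.0
        elif b.name == "lipid ester C=O":
            scale[i] = 1.0 + strength * (bmi - 25.0) / 10.0
    return np.clip(scale, 0.05, None)


def generate_cohort(config: SimConfig,
                    signature: DiseaseSignature | None = None,
                    grid: WavenumberGrid | None = None,
                    bands: list[BandModel] | None = None,
                    case_label: str = "case",
                    ref_label: str = "reference"):
    """Simulate a case/reference cohort; returns ``(CohortSet, GroundTruth)``.

    Cases receive ``delta_T * signature`` added before noise, where T is the
    sample's simulated tumour class; references carry no signal. Covariates
    are drawn with a configurable case-vs-reference shift so that matching
    has something to balance. Fully reproducible from ``config.seed``.
    """
    grid = grid or WavenumberGrid.default()
    bands = bands or default_serum_bands()
    if signature is None:
        signature = default_disease_signature(grid)
    rng = np.random.default_rng(config.seed)
    wn = np.asarray(grid, dtype=float)
    water = water_reference_spectrum(grid)
    stages = ("T1", "T2", "T3", "T4")

    n = config.n_cases + config.n_refs
    ids = [f"S{i:05d}" for i in range(n)]
    is_case = np.array([True] * config.n_cases + [False] * config.n_refs)

    age_c, sex_c, bmi_c, site_c = _draw_covariates(
        rng, config.n_cases, age_mean=55.0 + config.age_shift,
        male_fraction=config.male_fraction_case,
        bmi_mean=25.0 + config.bmi_shift)
    age_r, sex_r, bmi_r, site_r = _draw_covariates(
        rng, config.n_refs, age_mean=55.0,
        male_fraction=config.male_fraction_ref, bmi_mean=25.0)
    age = np.concatenate([age_c, age_r])
    sex = np.concatenate([sex_c, sex_r])
    bmi = np.concatenate([bmi_c, bmi_r])
    site = np.concatenate([site_c, site_r])

    t_class = np.array(
        list(rng.choice(stages, size=config.n_cases, p=config.stage_probs))
        + [""] * config.n_refs, dtype=object)
    grade = np.array(
        list(rng.integers(1, 4, size=config.n_cases).astype(str))
        + [""] * config.n_refs, dtype=object)

    X = np.empty((n, wn.size))
    beta_map, delta_map, label_map, t_map = {}, {}, {}, {}
    for i in range(n):
        scale = _confound_scale(bands, age[i], bmi[i],
                                config.covariate_confounding)
        if is_case[i]:
            delta = signature.amplitude_per_stage.get(str(t_class[i]), 0.0)
            extra = delta * signature.signature
        else:
            delta, extra = 0.0, None
        spec, beta = sample_person_spectrum(
            grid, bands, water, rng,
            noise_sd=config.noise_sd,
            bio_smooth_sd=config.bio_smooth_sd,
            bio_smooth_corr=config.bio_smooth_corr,
            water_deficit_mean=config.water_deficit_mean,
            water_deficit_sd=config.water_deficit_sd,
            extra=extra, band_scale=scale)
        X[i] = spec.absorbance
        beta_map[ids[i]] = beta
        delta_map[ids[i]] = delta
        label_map[ids[i]] = case_label if is_case[i] else ref_label
        t_map[ids[i]] = str(t_class[i])

    spectra = pd.DataFrame(X, index=pd.Index(ids, name="sample_id"),
                           columns=wn)
    meta = pd.DataFrame({
        "group": np.where(is_case, case_label, ref_label),
        "age": age, "sex": sex, "bmi": bmi, "site": site,
        "t_class": t_class, "grade": grade,
    }, index=spectra.index)
    cohort = CohortSet(spectra, meta, water=water,
                       provenance={"sim_config": config.__dict__.copy()})
    truth = GroundTruth(beta_map, delta_map, label_map, t_map)

    if config.outlier_fraction > 0:
        cohort, artifact_ids = inject_artifacts(
            cohort, config.outlier_fraction, rng)
        truth.artifact_ids = artifact_ids
    return cohort, truth


def generate_multigroup_cohort(config: SimConfig,
                               signatures: dict,
                               grid: WavenumberGrid | None = None,
                               bands: list[BandModel] | None = None):
    """Simulate several diagnosis groups with identical covariate laws.

    ``signatures`` maps group label -> DiseaseSignature or None (no signal).
    Each group has ``config.n_cases`` samples; sub-seeds derive from
    ``config.seed``.
    """
    grid = grid or WavenumberGrid.default()
    parts, truths = [], []
    for j, (label, sig) in enumerate(sorted(signatures.items())):
        sub = replace(config, n_refs=0, seed=(config.seed * 1009 + j) % (2**31),
                      age_shift=0.0, bmi_shift=0.0,
                      male_fraction_case=config.male_fraction_ref)
        if sig is None:
            sig = default_disease_signature(grid).scaled(0.0)
        part, truth = generate_cohort(sub, signature=sig, grid=grid,
                                      bands=bands, case_label=label)
        part.spectra.index = [f"{label}_{i}" for i in part.spectra.index]
        part.meta.index = part.spectra.index
        parts.append(part)
        truths.append(truth)
    spectra = pd.concat([p.spectra for p in parts])
    meta = pd.concat([p.meta for p in parts])
    spectra.index.name = "sample_id"
    meta.index.name = "sample_id"
    merged = CohortSet(spectra, meta, water=parts[0].water,
                       provenance={"sim_config": config.__dict__.copy(),
                                   "groups": sorted(signatures)})
    truth = GroundTruth(
        beta={k: v for t in truths for k, v in t.beta.items()},
        delta={k: v for t in truths for k, v in t.delta.items()},
        label={k: v for t in truths for k, v in t.label.items()},
        t_class={k: v for t in truths for k, v in t.t_class.items()})
    return merged, truth


# ------------------------------------------------------------------ artifacts
def inject_artifacts(cohort: CohortSet, fraction: float,
                     rng: np.random.Generator):
    """Replace a fraction of spectra with measurement-style anomalies.

    Each chosen spectrum is either globally scaled to 20% absorbance
    (emulating abnormally low absorbance) or given a spurious narrow
    contamination band. Returns ``(new_cohort, artifact_ids)``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    out = cohort.copy()
    n = len(out.sample_ids)
    m = int(round(fraction * n))
    if m == 0:
        return out, []
    idx = rng.choice(n, size=m, replace=False)
    wn = out.wavenumbers
    ids = []
    for i in np.sort(idx):
        sid = out.sample_ids[i]
        row = out.spectra.iloc[i].to_numpy()
        if rng.random() < 0.5:
            row = 0.2 * row
        else:
            center = rng.uniform(1050.0, 1700.0)
            row = row + 0.15 * np.exp(-0.5 * ((wn - center) / 6.0) ** 2)
        out.spectra.iloc[i] = row
        ids.append(sid)
    return out, ids
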