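"""Synthetic plasma LDI-MS cohorts with known differential metabolites.

The generator plants a small set of differential metabolites (each observed
as one cation adduct) among a large background of null features in the
100–400 Da window, then renders each sample either as a full profile-mode
spectrum (Gaussian peaks on an exponentially decaying baseline with
instrument noise) or directly as a feature matrix (the intensity model
without spectral rendering, for statistical studies).

Signal model per feature and sample, on the natural-log intensity scale:

    log I = base_log_intensity + effect(group) * sigma_log + N(0, sigma_log)

where ``sigma_log = sqrt(ln(1 + cv^2))`` is the log-normal scale matching
the configured intensity coefficient of variation, and ``effect(group)`` is
the planted standardized shift (Cohen's d on log intensities).  Fold change
on the natural scale therefore converges to ``exp(effect * sigma_log)``.

All randomness flows from one master seed through ``numpy.random
.SeedSequence.spawn``: child 0 builds templates, child ``1+i`` drives
sample ``i`` (one grandchild per replicate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adducts import DEFAULT_RULES, adduct_mz
from .containers import MZ_WINDOW, FeatureMatrix, Spectrum
from .refdata import DOWN_MARKERS, UP_MARKERS, reference_metabolites


@dataclass(frozen=True)
class MetaboliteTemplate:
    """A metabolite as the simulator sees it: mass, adducts, planted effects."""

    name: str
    formula: str
    monoisotopic_mass: float
    adducts: tuple[str, ...]
    base_log_intensity: float
    group_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: monoisotopic mass must be positive")
        for a in self.adducts:
            if a not in DEFAULT_RULES:
                raise ValueError(f"{self.name}: unknown adduct {a!r}")

    def adduct_mzs(self) -> list[float]:
        return [adduct_mz(self.monoisotopic_mass, a) for a in self.adducts]


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument-noise model for spectral rendering.

    Defaults emulate a clean nanoparticle-assisted LDI acquisition:
    replicate intensity CV near 10%, small m/z jitter relative to peak
    width, and a baseline that is small against analyte peaks.
    """

    baseline_amplitude: float = 30.0
    baseline_decay: float = 0.01  # per Da
    mz_jitter_sd: float = 0.01  # Da
    intensity_cv: float = 0.10
    additive_noise_sd: float = 3.0
    dropout_prob: float = 0.0
    peak_width_sigma: float = 0.05  # Da

    def __post_init__(self) -> None:
        for name in ("baseline_amplitude", "baseline_decay", "mz_jitter_sd",
                     "intensity_cv", "additive_noise_sd", "dropout_prob",
                     "peak_width_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not 0 <= self.intensity_cv < 1:
            raise ValueError("intensity_cv must be in [0, 1)")

    @property
    def sigma_log(self) -> float:
        """Log-normal scale parameter matching ``intensity_cv``."""
        return math.sqrt(math.log1p(self.intensity_cv**2))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: group sizes, demographics, replication, master seed."""

    groups: tuple[tuple[str, int], ...] = (("HC", 24), ("AECOPD", 24))
    age_distribution: dict[str, tuple[float, float]] | None = None  # group -> (mean, sd) years
    sex_ratio: dict[str, float] | None = None  # group -> fraction male
    replicates_per_sample: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        for label, n in self.groups:
            if n < 1:
                raise ValueError(f"group {label!r} must have n >= 1")

    def age_of(self, group: str) -> tuple[float, float]:
        # balanced demographics by default: same age/sex law in every group
        if self.age_distribution and group in self.age_distribution:
            return self.age_distribution[group]
        return (65.0, 8.0)

    def sex_of(self, group: str) -> float:
        if self.sex_ratio and group in self.sex_ratio:
            return self.sex_ratio[group]
        return 0.6


@dataclass(frozen=True)
class GroundTruth:
    """The simulator's manifest of planted differential features."""

    differential_features: tuple[tuple[str, float, str, float], ...]  # (name, mz, direction, effect)
    null_features: tuple[float, ...]

    def __post_init__(self) -> None:
        diff_mz = {mz for _, mz, _, _ in self.differential_features}
        if diff_mz & set(self.null_features):
            raise ValueError("differential and null m/z sets must be disjoint")
        for _, mz, direction, _ in self.differential_features:
            if not MZ_WINDOW[0] <= mz <= MZ_WINDOW[1]:
                raise ValueError(f"differential m/z {mz} outside window {MZ_WINDOW}")
            if direction not in ("up", "down"):
                raise ValueError(f"direction must be up|down, got {direction!r}")

    @property
    def differential_mz(self) -> np.ndarray:
        return np.array([mz for _, mz, _, _ in self.differential_features])


_ADDUCT_PREFERENCE = ("[M+H]+", "[M+Na]+", "[M+K]+")


def _marker_order() -> list[tuple[str, str]]:
    """Reference markers interleaved up/down so small panels stay balanced."""
    out: list[tuple[str, str]] = []
    for up, down in zip(UP_MARKERS, DOWN_MARKERS):
        out.append((up, "up"))
        out.append((down, "down"))
    return out


def build_template_library(
    n_background: int,
    n_differential: int,
    effect_size: float,
    seed: int,
    *,
    case_group: str = "AECOPD",
    control_group: str = "HC",
    peak_width_sigma: float = 0.05,
    window: tuple[float, float] = MZ_WINDOW,
    background_log_mean: float = math.log(2000.0),
    background_log_sd: float = 1.0,
    differential_log_mean: float = math.log(5000.0),
    differential_log_sd: float = 0.3,
) -> tuple[list[MetaboliteTemplate], GroundTruth]:
    """Build a template library with ``n_differential`` planted markers.

    Differential metabolites come from the embedded reference set
    (alternating up/down regulation, so ``n_differential=8`` plants four of
    each direction); beyond eight, synthetic metabolites with alternating
    directions are appended.  Background metabolites are synthetic nulls
    placed uniformly in the window with a minimum spacing of
    ``4 * peak_width_sigma`` between any two adduct peaks.

    Raises ``ValueError`` when the requested peaks cannot be packed into
    the window at that spacing.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    min_spacing = 4.0 * peak_width_sigma
    lo, hi = window
    n_total = n_background + n_differential
    capacity = int((hi - lo) / min_spacing)
    if n_total > 0.85 * capacity:
        raise ValueError(
            f"infeasible packing: {n_total} peaks need spacing {min_spacing:g} Da "
            f"in a {hi - lo:g} Da window (capacity ~{capacity})"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    templates: list[MetaboliteTemplate] = []
    taken: list[float] = []
    differential: list[tuple[str, float, str, float]] = []

    refs = {m.name: m for m in reference_metabolites()}
    order = _marker_order()
    for i in range(n_differential):
        if i < len(order):
            name, direction = order[i]
            rec = refs[name]
            mass, formula = rec.monoisotopic_mass, rec.formula
            adduct = next(
                a for a in _ADDUCT_PREFERENCE
                if lo + min_spacing <= adduct_mz(mass, a) <= hi - min_spacing
            )
        else:
            direction = "up" if i % 2 == 0 else "down"
            name, formula = f"diff_{i:03d}", "unknown"
            adduct = "[M+H]+"
            mass = _place_mass(rng, adduct, taken, lo, hi, min_spacing)
        mz = adduct_mz(mass, adduct)
        if any(abs(mz - t) < min_spacing for t in taken):
            raise ValueError(f"planted marker {name} collides with an existing peak at {mz:.3f}")
        taken.append(mz)
        signed = effect_size if direction == "up" else -effect_size
        templates.append(MetaboliteTemplate(
            name=name,
            formula=formula,
            monoisotopic_mass=mass,
            adducts=(adduct,),
            base_log_intensity=float(differential_log_mean + differential_log_sd * rng.standard_normal()),
            group_effects={control_group: 0.0, case_group: signed},
        ))
        differential.append((name, mz, direction, effect_size))

    null_mz: list[float] = []
    for i in range(n_background):
        adduct = str(rng.choice(_ADDUCT_PREFERENCE))
        mass = _place_mass(rng, adduct, taken, lo, hi, min_spacing)
        mz = adduct_mz(mass, adduct)
        taken.append(mz)
        null_mz.append(mz)
        templates.append(MetaboliteTemplate(
            name=f"bg_{i:04d}",
            formula="unknown",
            monoisotopic_mass=mass,
            adducts=(adduct,),
            base_log_intensity=float(background_log_mean + background_log_sd * rng.standard_normal()),
            group_effects={control_group: 0.0, case_group: 0.0},
        ))

    truth = GroundTruth(tuple(differential), tuple(null_mz))
    return templates, truth


def _place_mass(rng: np.random.Generator, adduct: str, taken: list[float],
                lo: float, hi: float, min_spacing: float, max_tries: int = 5000) -> float:
    shift = DEFAULT_RULES[adduct].mass_shift
    for _ in range(max_tries):
        mz = float(rng.uniform(lo + min_spacing, hi - min_spacing))
        if all(abs(mz - t) >= min_spacing for t in taken):
            return mz - shift
    raise ValueError("infeasible packing: could not place a peak after rejection sampling")


def _draw_log_intensities(templates: list[MetaboliteTemplate], group: str,
                          noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    sig = noise.sigma_log
    base = np.array([t.base_log_intensity for t in templates])
    shift = np.array([t.group_effects.get(group, 0.0) for t in templates]) * sig
    return base + shift + sig * rng.standard_normal(len(templates))


def simulate_spectrum(
    templates: list[MetaboliteTemplate],
    group: str,
    noise: NoiseSpec,
    seed: int | np.random.SeedSequence,
    *,
    window: tuple[float, float] = MZ_WINDOW,
    grid_step: float | None = None,
    sample_id: str = "",
) -> Spectrum:
    """Render one profile-mode spectrum for a sample of the given group.

    The m/z grid spans the window at ``grid_step`` spacing (default
    ``peak_width_sigma / 4``, and never coarser than a third of the peak
    width).  Peaks are Gaussian with constant width; peak apex amplitudes
    follow the log-normal intensity model; each peak is independently
    dropped with ``dropout_prob``.
    """
    if not templates:
        raise ValueError("template list must not be empty")
    rng = np.random.default_rng(seed)
    lo, hi = window
    step = grid_step if grid_step is not None else noise.peak_width_sigma / 4.0
    if noise.peak_width_sigma > 0 and step > noise.peak_width_sigma / 3.0 + 1e-12:
        raise ValueError("grid_step must be <= peak_width_sigma / 3")
    mz = np.arange(lo, hi + step / 2, step)

    intensity = noise.baseline_amplitude * np.exp(-noise.baseline_decay * (mz - lo))
    log_int = _draw_log_intensities(templates, group, noise, rng)
    sigma = max(noise.peak_width_sigma, 1e-9)
    for tmpl, li in zip(templates, log_int):
        for center in tmpl.adduct_mzs():
            if noise.dropout_prob > 0 and rng.uniform() < noise.dropout_prob:
                continue
            c = center + (noise.mz_jitter_sd * rng.standard_normal() if noise.mz_jitter_sd else 0.0)
            amp = math.exp(li)
            i0 = np.searchsorted(mz, c - 6 * sigma)
            i1 = np.searchsorted(mz, c + 6 * sigma)
            intensity[i0:i1] += amp * np.exp(-0.5 * ((mz[i0:i1] - c) / sigma) ** 2)
    if noise.additive_noise_sd > 0:
        intensity = intensity + noise.additive_noise_sd * rng.standard_normal(mz.size)
    intensity = np.clip(intensity, 0.0, None)
    return Spectrum(mz, intensity, sample_id=sample_id, metadata={"group": group})


def simulate_cohort(
    spec: CohortSpec,
    templates: list[MetaboliteTemplate],
    noise: NoiseSpec,
    ground_truth: GroundTruth | None = None,
) -> tuple[list[Spectrum], pd.DataFrame, GroundTruth]:
    """Render a full cohort: one spectrum per sample per replicate.

    Metadata rows carry sample_id, group, age, sex and replicate; the
    master seed is recorded in ``metadata.attrs['seed']``.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(1 + sum(n for _, n in spec.groups))
    spectra: list[Spectrum] = []
    rows: list[dict] = []
    idx = 0
    for group, n in spec.groups:
        mean_age, sd_age = spec.age_of(group)
        p_male = spec.sex_of(group)
        for _ in range(n):
            idx += 1
            child = children[idx]
            demo_rng = np.random.default_rng(child)
            age = float(demo_rng.normal(mean_age, sd_age))
            sex = "M" if demo_rng.uniform() < p_male else "F"
            sample_id = f"{group}_{idx:04d}"
            rep_seeds = child.spawn(spec.replicates_per_sample)
            for rep, rseed in enumerate(rep_seeds, start=1):
                sid = sample_id if spec.replicates_per_sample == 1 else f"{sample_id}_r{rep}"
                spectra.append(simulate_spectrum(templates, group, noise, rseed, sample_id=sid))
                rows.append({"sample_id": sid, "group": group, "age": round(age, 2),
                             "sex": sex, "replicate": rep})
    meta = pd.DataFrame(rows)
    meta.attrs["seed"] = spec.seed
    truth = ground_truth if ground_truth is not None else _truth_from_templates(templates)
    return spectra, meta, truth


def simulate_feature_matrix(
    spec: CohortSpec,
    templates: list[MetaboliteTemplate],
    noise: NoiseSpec,
    ground_truth: GroundTruth | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame, GroundTruth]:
    """Draw a cohort directly as a feature matrix (no spectral rendering).

    Columns are all adduct m/z of the template library in ascending order;
    entries follow the same log-normal intensity model (and dropout) as
    :func:`simulate_spectrum`, so planted standardized effects are exact.
    Replicates are ignored here (one row per sample).
    """
    features: list[tuple[float, int]] = []  # (mz, template index)
    for j, t in enumerate(templates):
        for mz in t.adduct_mzs():
            features.append((mz, j))
    features.sort()
    feature_mz = np.array([mz for mz, _ in features])
    t_index = np.array([j for _, j in features])

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(1 + sum(n for _, n in spec.groups))
    rows, labels, ids = [], [], []
    meta_rows = []
    idx = 0
    for group, n in spec.groups:
        mean_age, sd_age = spec.age_of(group)
        p_male = spec.sex_of(group)
        for _ in range(n):
            idx += 1
            rng = np.random.default_rng(children[idx])
            age = float(rng.normal(mean_age, sd_age))
            sex = "M" if rng.uniform() < p_male else "F"
            log_int = _draw_log_intensities(templates, group, noise, rng)
            vals = np.exp(log_int)[t_index]
            if noise.dropout_prob > 0:
                vals = vals * (rng.uniform(size=vals.size) >= noise.dropout_prob)
            sid = f"{group}_{idx:04d}"
            rows.append(vals)
            labels.append(group)
            ids.append(sid)
            meta_rows.append({"sample_id": sid, "group": group, "age": round(age, 2),
                              "sex": sex, "replicate": 1})
    meta = pd.DataFrame(meta_rows)
    meta.attrs["seed"] = spec.seed
    matrix = FeatureMatrix(feature_mz, np.vstack(rows), ids, labels)
    truth = ground_truth if ground_truth is not None else _truth_from_templates(templates)
    return matrix, meta, truth


def _truth_from_templates(templates: list[MetaboliteTemplate]) -> GroundTruth:
    diff, null = [], []
    for t in templates:
        effects = [e for e in t.group_effects.values() if e != 0.0]
        for mz in t.adduct_mzs():
            if effects:
                direction = "up" if effects[0] > 0 else "down"
                diff.append((t.name, mz, direction, abs(effects[0])))
            else:
                null.append(mz)
    return GroundTruth(tuple(diff), tuple(null))
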