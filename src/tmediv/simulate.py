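"""Synthetic TMA cohorts with known ground truth.

The generator emulates the study design the analysis pipeline targets:
1.2 mm-diameter circular TMA cores extracted in triplicate per patient;
cells as a homogeneous Poisson point pattern over the core disc, each cell
carrying a categorical phenotype drawn from patient-level proportions over
the 32 marker-combination codes plus the DAPI-only and CD21-only classes;
follicle-like clustering (labels such as CD4+PD-1+ follicular helper cells
enriched inside follicle discs via acceptance re-weighting); bimodal
log-normal marker intensities so that threshold scoring can recover the
generated labels; and survival times from a Weibull proportional-hazards
model whose log-hazard is linear in the patient's (standardised) diversity
feature, with independent exponential censoring calibrated to a target
censoring fraction.

Per-patient proportions are Dirichlet perturbations of the configured base
proportions, giving real between-patient heterogeneity in the true
entropies. Every patient owns an independent seed sub-stream, so adding a
patient never changes existing patients' cell tables. Follicle discs are
emitted as the CD21 meshwork annotations, making the meshwork area fraction
analytically known.

What it deliberately does **not** model: optics, spectral bleed-through, or
segmentation error beyond the overlap of the intensity components.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Point

from .annotations import CoreAnnotations
from .errors import ValidationError
from .panel import DEFAULT_PHENOTYPING_MARKERS, MarkerPanel, default_panel
from .phenotypes import (
    CD21_ONLY,
    DAPI_ONLY,
    all_combination_codes,
    combination_code,
    positive_markers,
)

_CIRCLE_SEGMENTS = 128


def _circle(cx: float, cy: float, r: float, segments: int = _CIRCLE_SEGMENTS):
    return Point(cx, cy).buffer(r, quad_segs=segments // 4)


def _default_proportions() -> dict[str, float]:
    """A follicular-lymphoma-like phenotype mixture.

    Tumour B cells (DAPI-only) dominate; T-helper, cytotoxic, macrophage,
    Treg and follicular-helper subsets make up the immune infiltrate, with
    a small follicular-dendritic (CD21-only) class.
    """
    m = DEFAULT_PHENOTYPING_MARKERS

    def code(*pos: str) -> str:
        return combination_code([x in pos for x in m], m)

    return {
        DAPI_ONLY: 0.55,
        CD21_ONLY: 0.02,
        code("CD4"): 0.13,
        code("CD8"): 0.07,
        code("CD68"): 0.05,
        code("CD4", "FOXP3"): 0.04,
        code("CD4", "PD-1"): 0.06,
        code("CD8", "PD-1"): 0.02,
        code("CD4", "FOXP3", "PD-1"): 0.01,
        code("CD4", "CD68"): 0.01,
        code("CD8", "CD68"): 0.005,
        code("FOXP3"): 0.01,
        code("PD-1"): 0.01,
        code("CD68", "PD-1"): 0.005,
        code("CD4", "CD8"): 0.01,
    }


def _default_enrichment() -> dict[str, float]:
    """Follicle enrichment: CD4+PD-1+ codes (T follicular helpers) 4x."""
    m = DEFAULT_PHENOTYPING_MARKERS
    out = {}
    for code in all_combination_codes(m):
        pos = positive_markers(code, m)
        if "CD4" in pos and "PD-1" in pos:
            out[code] = 4.0
    return out


@dataclass(frozen=True)
class IntensityModel:
    """Two-component log-normal intensity model shared by all markers.

    Intensities are log-normal: log-intensity ~ N(mean, sd) with the
    positive component 8 log-sd above the negative one by default, i.e. a
    midpoint threshold sits 4 sd from each component mean (positive cells
    ~25x brighter — typical of well-separated immunofluorescence stains).
    """

    log_neg_mean: float = 0.0
    log_pos_mean: float = 3.2
    log_sd: float = 0.4

    def midpoint_threshold(self) -> float:
        """Threshold at the geometric midpoint of the two components."""
        return float(np.exp(0.5 * (self.log_neg_mean + self.log_pos_mean)))


@dataclass(frozen=True)
class FollicleConfig:
    count: int = 3
    radius_um: float = 150.0
    enrichment: Mapping[str, float] = field(default_factory=_default_enrichment)


@dataclass(frozen=True)
class SurvivalConfig:
    """Weibull PH outcome model on standardised patient features.

    ``beta_per_feature`` maps feature name -> log hazard ratio per standard
    deviation of the true patient feature. ``censoring_rate`` is the target
    expected fraction censored; an independent exponential censoring time is
    calibrated to it. Times are reported at monthly resolution (ties occur).
    """

    baseline_shape: float = 1.2
    baseline_scale_months: float = 240.0
    pfs_scale_months: float = 80.0
    beta_per_feature: Mapping[str, float] = field(
        default_factory=lambda: {"phenotype_entropy": -1.5}
    )
    censoring_rate: float = 0.7
    pfs_censoring_rate: float = 0.4
    flipi_log_hr: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 127
    cores_per_patient: int = 3
    core_diameter_um: float = 1200.0
    cell_density_per_mm2: float = 1800.0
    phenotype_proportions: Mapping[str, float] = field(
        default_factory=_default_proportions
    )
    follicle: FollicleConfig = field(default_factory=FollicleConfig)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    #: Dirichlet dispersion of per-patient proportions around the base
    #: mixture (concentration = 1 / patient_effect_sd**2)
    patient_effect_sd: float = 0.08
    treatment_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "rituximab": 0.52, "radiotherapy": 0.28, "surveillance": 0.20
        }
    )
    flipi_missing_frac: float = 0.2

    def validate(self) -> None:
        props = np.array(list(self.phenotype_proportions.values()), float)
        if abs(props.sum() - 1.0) > 1e-8:
            raise ValidationError(
                f"phenotype proportions must sum to 1 (got {props.sum():.6f})"
            )
        if (props < 0).any():
            raise ValidationError("phenotype proportions must be non-negative")
        valid = set(all_combination_codes(DEFAULT_PHENOTYPING_MARKERS)) | {
            DAPI_ONLY, CD21_ONLY,
        }
        unknown = set(self.phenotype_proportions) - valid
        if unknown:
            raise ValidationError(f"unknown phenotype labels: {sorted(unknown)}")
        if self.cell_density_per_mm2 <= 0 or self.core_diameter_um <= 0:
            raise ValidationError("density and core diameter must be positive")
        if not 0 <= self.survival.censoring_rate <= 1:
            raise ValidationError("censoring_rate must be in [0, 1]")

    def panel(self) -> MarkerPanel:
        """Default panel with midpoint thresholds matching the intensity model."""
        return default_panel(self.intensity.midpoint_threshold())


@dataclass
class GroundTruth:
    """Generator-side truth for validating the pipeline."""

    patient_proportions: dict[str, dict[str, float]]
    patient_entropy: dict[str, float]
    betas: dict[str, float]
    cd21_fraction: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    cells: pd.DataFrame
    annotations: dict[str, CoreAnnotations]
    clinical: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def true_entropy(proportions: Mapping[str, float]) -> float:
    """Plug-in entropy of a mixture after the standard exclusions."""
    p = np.array(
        [v for k, v in proportions.items() if k not in (DAPI_ONLY, CD21_ONLY)],
        float,
    )
    if p.sum() <= 0:
        return 0.0
    p = p / p.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _patient_proportions(
    base: Mapping[str, float], sd: float, rng: np.random.Generator
) -> dict[str, float]:
    labels = list(base)
    p = np.array([base[k] for k in labels], float)
    nz = p > 0
    if sd <= 0 or nz.sum() < 2:
        return dict(zip(labels, p))
    conc = 1.0 / (sd * sd)
    drawn = rng.dirichlet(p[nz] * conc)
    out = np.zeros_like(p)
    out[nz] = drawn
    return dict(zip(labels, out))


def draw_patient_entropies(
    n_patients: int,
    rng: np.random.Generator,
    base: Mapping[str, float] | None = None,
    patient_effect_sd: float = 0.08,
) -> np.ndarray:
    """True phenotype entropies for a cohort, without cell-level simulation.

    Draws each patient's Dirichlet-perturbed mixture and returns its plug-in
    entropy; this is the patient-level feature path used when only the
    feature–outcome linkage matters (e.g. survival-model calibration runs).
    """
    if base is None:
        base = _default_proportions()
    return np.array(
        [
            true_entropy(_patient_proportions(base, patient_effect_sd, rng))
            for _ in range(n_patients)
        ]
    )


def generate_core(
    config: SimulationConfig,
    patient_id: str,
    core_id: str,
    seed_seq: np.random.SeedSequence,
    proportions: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, CoreAnnotations]:
    """One synthetic TMA core: cell table rows plus annotations.

    Cell count ~ Poisson(density x disc area); positions uniform in the
    disc, re-weighted inside follicle discs for enriched labels (rejection
    sampling, so marginal label proportions are untouched); intensities from
    the two-component log-normal model on the marker's designated
    compartment, negative component on the other compartment.
    """
    config.validate()
    rng = np.random.default_rng(seed_seq)
    props = dict(proportions) if proportions is not None else dict(
        config.phenotype_proportions
    )
    labels_all = list(props)
    pvec = np.array([props[k] for k in labels_all], float)
    pvec = pvec / pvec.sum()

    radius = config.core_diameter_um / 2.0
    center = (radius, radius)
    area_mm2 = np.pi * radius**2 / 1e6
    n_cells = int(rng.poisson(config.cell_density_per_mm2 * area_mm2))

    labels = rng.choice(np.array(labels_all, object), size=n_cells, p=pvec)

    # follicle discs (also emitted as CD21 meshwork annotations)
    fol = config.follicle
    f_r = min(fol.radius_um, radius)
    centers = []
    max_c = max(radius - f_r, 0.0)
    for _ in range(fol.count):
        rr = max_c * np.sqrt(rng.random())
        th = 2 * np.pi * rng.random()
        centers.append((center[0] + rr * np.cos(th), center[1] + rr * np.sin(th)))

    mult = np.array([float(fol.enrichment.get(l, 1.0)) for l in labels])

    x = np.empty(n_cells)
    y = np.empty(n_cells)
    pending = np.arange(n_cells)
    margin = 1.0  # keep points inside the polygonal tissue boundary
    while pending.size:
        m = pending.size
        rr = (radius - margin) * np.sqrt(rng.random(m))
        th = 2 * np.pi * rng.random(m)
        px = center[0] + rr * np.cos(th)
        py = center[1] + rr * np.sin(th)
        in_follicle = np.zeros(m, bool)
        for cx, cy in centers:
            in_follicle |= (px - cx) ** 2 + (py - cy) ** 2 <= f_r**2
        w = np.where(in_follicle, mult[pending], 1.0)
        accept = rng.random(m) * mult[pending].clip(min=1.0) <= w
        idx = pending[accept]
        x[idx] = px[accept]
        y[idx] = py[accept]
        pending = pending[~accept]

    im = config.intensity
    panel = config.panel()
    data: dict[str, object] = {
        "cell_id": [f"{core_id}_c{i}" for i in range(n_cells)],
        "core_id": core_id,
        "patient_id": patient_id,
        "x_um": x,
        "y_um": y,
    }
    pos_sets = [positive_markers(l, DEFAULT_PHENOTYPING_MARKERS) for l in labels]
    cd21_pos = np.array([l == CD21_ONLY for l in labels])
    for marker in panel.markers:
        if marker == "DAPI":
            is_pos = np.ones(n_cells, bool)
        elif marker == "CD21":
            is_pos = cd21_pos
        else:
            is_pos = np.array([marker in s for s in pos_sets])
        mean = np.where(is_pos, im.log_pos_mean, im.log_neg_mean)
        designated = panel.compartment_of[marker]
        other = "membrane" if designated == "nucleus" else "nucleus"
        data[f"{marker}:{designated}"] = np.exp(rng.normal(mean, im.log_sd))
        data[f"{marker}:{other}"] = np.exp(
            rng.normal(im.log_neg_mean, im.log_sd, n_cells)
        )
    data["true_phenotype"] = labels
    cells = pd.DataFrame(data)

    ann = CoreAnnotations(
        core_id=core_id,
        tissue=_circle(center[0], center[1], radius),
        exclusions=[],
        cd21_meshwork=[_circle(cx, cy, f_r, 64) for cx, cy in centers],
    )
    return cells, ann


def calibrate_censoring_rate(event_times: np.ndarray, rate: float) -> float:
    """Exponential censoring rate lambda with mean censoring fraction ``rate``.

    Solves mean(1 - exp(-lambda*T)) = rate on the realised event times.
    """
    t = np.asarray(event_times, float)
    if rate <= 0:
        return 0.0
    if rate >= 1:
        return np.inf

    def f(log_lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(log_lam) * t)) - rate)

    return float(np.exp(brentq(f, -30.0, 30.0)))


def draw_survival_times(
    lp: np.ndarray,
    cfg: SurvivalConfig,
    rng: np.random.Generator,
    scale_months: float | None = None,
    censoring_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed (time, event) pairs from the Weibull PH model.

    ``lp`` is the linear predictor (log hazard ratio vs baseline). Times are
    rounded to whole months (minimum 1), creating realistic ties.
    """
    lp = np.asarray(lp, float)
    scale = cfg.baseline_scale_months if scale_months is None else scale_months
    rate = cfg.censoring_rate if censoring_rate is None else censoring_rate
    t = scale * (rng.exponential(size=lp.size) / np.exp(lp)) ** (1.0 / cfg.baseline_shape)
    if rate >= 1.0:
        c = t * rng.random(lp.size)  # everything censored strictly before the event
        events = np.zeros(lp.size, bool)
        observed = c
    elif rate <= 0.0:
        events = np.ones(lp.size, bool)
        observed = t
    else:
        lam = calibrate_censoring_rate(t, rate)
        c = rng.exponential(1.0 / lam, lp.size)
        events = t <= c
        observed = np.minimum(t, c)
    months = np.maximum(np.round(observed), 1.0)
    return months, events


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full synthetic study: cell tables, annotations, clinical outcomes, truth."""
    config.validate()
    patient_root = np.random.SeedSequence([int(config.seed), 0])
    clinical_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    patient_seeds = patient_root.spawn(config.n_patients)

    cell_frames = []
    annotations: dict[str, CoreAnnotations] = {}
    truth_props: dict[str, dict[str, float]] = {}
    truth_entropy: dict[str, float] = {}
    truth_cd21: dict[str, float] = {}
    patient_ids = [f"P{i:03d}" for i in range(config.n_patients)]
    for pid, pseed in zip(patient_ids, patient_seeds):
        streams = pseed.spawn(config.cores_per_patient + 1)
        rng_p = np.random.default_rng(streams[0])
        props = _patient_proportions(
            config.phenotype_proportions, config.patient_effect_sd, rng_p
        )
        truth_props[pid] = props
        truth_entropy[pid] = true_entropy(props)
        for c in range(config.cores_per_patient):
            core_id = f"{pid}_core{c}"
            cells, ann = generate_core(config, pid, core_id, streams[c + 1], props)
            cell_frames.append(cells)
            annotations[core_id] = ann
            truth_cd21[core_id] = (
                sum(p.area for p in ann.cd21_meshwork) / ann.tissue.area
            )
    cells = pd.concat(cell_frames, ignore_index=True)

    # clinical outcomes from the standardised true diversity feature
    ent = np.array([truth_entropy[p] for p in patient_ids])
    sd = ent.std(ddof=0)
    z = (ent - ent.mean()) / sd if sd > 0 else np.zeros_like(ent)
    surv = config.survival
    beta = float(surv.beta_per_feature.get("phenotype_entropy", 0.0))
    treat_names = list(config.treatment_probs)
    treat_p = np.array([config.treatment_probs[k] for k in treat_names], float)
    treatment = clinical_rng.choice(treat_names, size=len(patient_ids), p=treat_p / treat_p.sum())
    flipi = clinical_rng.binomial(5, 0.35, len(patient_ids)).astype(float)
    lp = beta * z + surv.flipi_log_hr * (flipi - flipi.mean())
    os_months, os_event = draw_survival_times(lp, surv, clinical_rng)
    pfs_months, pfs_event = draw_survival_times(
        lp, surv, clinical_rng,
        scale_months=surv.pfs_scale_months,
        censoring_rate=surv.pfs_censoring_rate,
    )
    flipi_missing = clinical_rng.random(len(patient_ids)) < config.flipi_missing_frac
    flipi[flipi_missing] = np.nan

    rituximab = treatment == "rituximab"
    pfs_months = np.where(rituximab, pfs_months, np.nan)
    pfs_event_col = np.where(rituximab, pfs_event.astype(float), np.nan)
    early = pfs_event & (pfs_months <= 24)
    defined = rituximab & (early | (np.nan_to_num(pfs_months) >= 24))
    pod24 = np.where(defined, early.astype(float), np.nan)

    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "treatment": treatment,
            "flipi": flipi,
            "os_months": os_months,
            "os_event": os_event.astype(int),
            "pfs_months": pfs_months,
            "pfs_event": pfs_event_col,
            "pod24": pod24,
            "followup_months": os_months,
        }
    )
    truth = GroundTruth(
        patient_proportions=truth_props,
        patient_entropy=truth_entropy,
        betas={"phenotype_entropy": beta, "flipi": surv.flipi_log_hr},
        cd21_fraction=truth_cd21,
        seed=int(config.seed),
    )
    return SyntheticCohort(
        cells=cells, annotations=annotations, clinical=clinical,
        truth=truth, config=config,
    )
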