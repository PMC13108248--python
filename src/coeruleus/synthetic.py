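"""Synthetic phantoms and cohorts with known ground truth.

This module emulates the structure of a longitudinal neuromelanin-MRI /
amyloid-tau PET / neuropsychology study of the locus coeruleus (LC) in
cognitively unimpaired older adults, so that every downstream stage —
slicewise normalization, brightest-contiguous-voxel extraction, per-subject
degeneration slopes, mixed-effects trajectory models, and voxelwise TFCE
permutation inference — can be exercised against planted truth without any
data download.

Four generators are provided:

``generate_phantom``
    An axial slab containing a hyperintense LC blob inside each of two
    bilateral search-space boxes, a large homogeneous pontomesencephalic
    reference region, per-slice multiplicative intensity drift (TSE slab
    shading) and additive Gaussian noise.
``generate_cohort``
    Per-subject baseline LC relative intensity (LC_RI), linear within-subject
    decline with between-subject variation, an age gradient on baseline
    level, demographics and a bimodal global-amyloid burden.  Phantom volumes
    for every session can be rendered on demand.
``generate_tau_maps``
    Per-subject SUVR-like volumes whose intensity inside designated signal
    regions depends linearly on subject covariates and their interactions
    (e.g. ``dlc_x_abeta``), with configurable sign per region.
``generate_cognition``
    Longitudinal five-domain cognition tables with planted ``time``,
    ``time x bl_lc``, ``time x dlc``, ``time x abeta`` and three-way
    interaction structure plus a subject random intercept.

All randomness flows from a single ``numpy.random.default_rng`` seed; equal
spec + seed gives bitwise-equal output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import MaskSet, VolumeGrid

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "TauEffectRegion",
    "GroundTruth",
    "Cohort",
    "COGNITION_DOMAINS",
    "generate_phantom",
    "generate_cohort",
    "generate_tau_maps",
    "generate_cognition",
]

COGNITION_DOMAINS = (
    "total",
    "attention",
    "immediate_memory",
    "delayed_memory",
    "language",
    "visuospatial",
)

#: Subject-level terms a planted tau or cognition effect may load on.
#: All continuous covariates are z-scored across the cohort before the
#: products are formed, so planted coefficients are per-SD.
EFFECT_TERMS = ("bl_lc", "dlc", "abeta", "bl_lc_x_abeta", "dlc_x_abeta")


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of the neuromelanin slab phantom.

    The default grid is 64 x 64 x 20 voxels of 0.7 x 0.7 x 1.8 mm, mimicking
    a TSE brainstem slab.  Each LC is a compact blob of ``lc_extent`` voxels
    (>= 10, so that a 10-voxel contiguous mask always exists) planted at
    ``lc_true_intensity`` times the local reference level, strictly inside
    its search-space box.  The reference region is a large homogeneous box
    covering every slice the search spaces touch.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 20)
    voxel_size: tuple[float, float, float] = (0.7, 0.7, 1.8)
    lc_center_left: tuple[int, int, int] = (22, 36, 10)
    lc_center_right: tuple[int, int, int] = (42, 36, 10)
    lc_true_intensity: float = 1.2
    lc_extent: int = 12
    search_halfwidth: tuple[int, int, int] = (4, 4, 4)
    reference_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (12, 52),
        (12, 28),
        (2, 18),
    )
    ref_mean_raw: float = 300.0
    slice_drift_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lc_true_intensity <= 1:
            raise ValueError("lc_true_intensity must exceed 1 (hyperintense LC)")
        if self.lc_extent < 10:
            raise ValueError("lc_extent must be >= 10 voxels")
        if self.ref_mean_raw <= 0:
            raise ValueError("ref_mean_raw must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.slice_drift_range
        if not (0 < lo <= hi):
            raise ValueError("slice_drift_range must satisfy 0 < low <= high")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        shape = self.grid_shape
        for (a, b), n in zip(self.reference_box, shape):
            if not (0 <= a < b <= n):
                raise ValueError(
                    f"reference box {self.reference_box} does not fit grid {shape}"
                )
        for center in (self.lc_center_left, self.lc_center_right):
            for c, hw, n in zip(center, self.search_halfwidth, shape):
                if c - hw < 0 or c + hw + 1 > n:
                    raise ValueError(
                        f"search space around {center} (halfwidth "
                        f"{self.search_halfwidth}) exceeds grid {shape}"
                    )


@dataclass
class CohortSpec:
    """Population parameters of the simulated longitudinal cohort.

    Defaults emulate the design of a familial-risk aging cohort: ~200
    subjects, 2-3 neuromelanin-MRI sessions ~28.8 months apart, baseline age
    68.3 +/- 5.2 years, baseline LC_RI 119.7 +/- 3.1 (reference = 100), a
    mean decline of -0.187 LC_RI units per year, and roughly 8 annual
    cognition visits.  ``decline_sd`` is the *true* between-subject slope SD;
    ``lc_ri_noise_sd`` is session-level measurement noise, which together
    reproduce an observed slope spread of ~0.63 units/year at these
    intervals.
    """

    n_subjects: int = 199
    sessions_min: int = 2
    sessions_max: int = 3
    interval_mean_months: float = 28.8
    interval_sd_months: float = 6.4
    age_mean: float = 68.3
    age_sd: float = 5.2
    female_fraction: float = 0.698
    education_mean: float = 15.0
    education_sd: float = 3.0
    bl_lc_ri_mean: float = 119.7
    bl_lc_ri_sd: float = 3.1
    true_decline_rate: float = -0.187  # LC_RI units / year, population mean
    decline_sd: float = 0.2  # between-subject SD of the true slope
    slope_bl_coupling: float = 0.0  # slope units/yr per SD of baseline LC_RI
    age_effect: float = -0.08  # LC_RI units per year of baseline age
    lc_ri_noise_sd: float = 1.0  # measurement noise on observed LC_RI
    abeta_positive_fraction: float = 0.3
    abeta_negative_mean: float = 1.15
    abeta_negative_sd: float = 0.10
    abeta_positive_mean: float = 1.60
    abeta_positive_sd: float = 0.20
    cognition_visits_mean: float = 7.5
    cognition_visits_sd: float = 2.3
    cognition_visits_range: tuple[int, int] = (2, 11)
    cognition_interval_months: float = 12.0
    cognition_interval_sd: float = 2.0
    cognition_effects: dict | None = None
    cognition_intercept: float = 90.0
    cognition_random_intercept_sd: float = 7.0
    cognition_residual_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sessions_min < 2:
            raise ValueError("every retained subject needs >= 2 sessions")
        if self.sessions_max < self.sessions_min:
            raise ValueError("sessions_max < sessions_min")
        for name in (
            "interval_sd_months",
            "age_sd",
            "education_sd",
            "bl_lc_ri_sd",
            "decline_sd",
            "lc_ri_noise_sd",
            "abeta_negative_sd",
            "abeta_positive_sd",
            "cognition_visits_sd",
            "cognition_interval_sd",
            "cognition_random_intercept_sd",
            "cognition_residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.abeta_positive_fraction <= 1:
            raise ValueError("abeta_positive_fraction must lie in [0, 1]")

    def effects_for(self, domain: str) -> dict[str, float]:
        """Planted per-year fixed effects for one cognition domain.

        Keys: ``time`` plus ``time_x_<term>`` for term in ``bl_lc``, ``dlc``,
        ``abeta``, ``bl_lc_x_abeta``, ``dlc_x_abeta`` (covariates z-scored).
        Missing keys default to 0.
        """
        if domain not in COGNITION_DOMAINS:
            raise ValueError(f"unknown cognition domain {domain!r}")
        base = {"time": 0.0}
        user = (self.cognition_effects or {}).get(domain, {})
        base.update(user)
        return base


@dataclass
class TauEffectRegion:
    """A planted signal region in the tau phantom.

    ``box`` gives inclusive-exclusive index ranges per axis; ``coefficients``
    maps effect terms (see ``EFFECT_TERMS``) to SUVR units per SD of the
    term.  A negative coefficient mimics the occipital sign flip.
    """

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    coefficients: dict[str, float] = field(default_factory=dict)

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        for (a, b), n in zip(self.box, shape):
            if not (0 <= a < b <= n):
                raise ValueError(
                    f"effect region {self.name!r} box {self.box} outside grid {shape}"
                )
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass
class GroundTruth:
    """Planted truth for every generated observable.

    ``subjects`` has one row per simulated subject: baseline covariates,
    true bl_lc_ri, true dlc_ri (units/year), true global amyloid and its
    positivity component.  Phantom-level truth (planted blob masks, the
    exact expected LC_RI) and tau-region masks are attached by the
    generators that create them.
    """

    subjects: pd.DataFrame | None = None
    lc_blob_left: np.ndarray | None = None
    lc_blob_right: np.ndarray | None = None
    expected_lc_ri: float | None = None
    tau_regions: list[TauEffectRegion] | None = None
    tau_signal_mask: np.ndarray | None = None
    cognition_slopes: pd.DataFrame | None = None

    def has_subject(self, subject_id: str) -> bool:
        if self.subjects is None:
            return False
        return subject_id in set(self.subjects["subject_id"])


@dataclass
class Cohort:
    """Output bundle of ``generate_cohort``."""

    sessions: pd.DataFrame
    truth: GroundTruth
    volumes: list[tuple[str, int, VolumeGrid, MaskSet]] | None = None


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------


def _box_mask(shape, box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def _search_mask(spec: PhantomSpec, center) -> np.ndarray:
    box = tuple(
        (c - hw, c + hw + 1) for c, hw in zip(center, spec.search_halfwidth)
    )
    return _box_mask(spec.grid_shape, box)


def _lc_blob(spec: PhantomSpec, center) -> np.ndarray:
    """Compact blob of ``lc_extent`` voxels nearest ``center`` in mm.

    Nearest-by-physical-distance growth yields a contiguous (face-connected)
    blob on the anisotropic grid; ties break lexicographically for
    determinism.
    """
    search = _search_mask(spec, center)
    idx = np.argwhere(search)
    d2 = np.sum(((idx - np.asarray(center)) * np.asarray(spec.voxel_size)) ** 2, axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[: spec.lc_extent]]
    if len(chosen) < spec.lc_extent:
        raise ValueError("search space too small for requested lc_extent")
    blob = np.zeros(spec.grid_shape, dtype=bool)
    blob[tuple(chosen.T)] = True
    return blob


def build_masks(spec: PhantomSpec) -> MaskSet:
    """Search-space and reference masks implied by a phantom spec."""
    left = _search_mask(spec, spec.lc_center_left)
    right = _search_mask(spec, spec.lc_center_right)
    ref = _box_mask(spec.grid_shape, spec.reference_box)
    if (ref & (left | right)).any():
        raise ValueError("reference box overlaps an LC search space")
    # every slice with LC candidates needs reference coverage for normalization
    z_search = np.unique(np.argwhere(left | right)[:, 2])
    z_ref = set(np.unique(np.argwhere(ref)[:, 2]))
    missing = [int(z) for z in z_search if int(z) not in z_ref]
    if missing:
        raise ValueError(f"reference box misses search-space slices {missing}")
    return MaskSet(left, right, ref, spec.voxel_size)


def generate_phantom(
    spec: PhantomSpec,
    session_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeGrid, MaskSet, GroundTruth]:
    """Render one neuromelanin slab phantom.

    The whole slab sits at the reference level ``ref_mean_raw`` modulated by
    a per-slice multiplicative drift factor; the two planted LC blobs sit at
    ``lc_true_intensity * session_scale`` times the local reference level;
    Gaussian noise of SD ``noise_sd`` (scanner units) is added everywhere.
    After slicewise reference normalization the planted blobs therefore read
    ``100 * lc_true_intensity * session_scale`` exactly in the noiseless
    limit.
    """
    if session_scale <= 0:
        raise ValueError("session_scale must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    masks = build_masks(spec)
    blob_l = _lc_blob(spec, spec.lc_center_left)
    blob_r = _lc_blob(spec, spec.lc_center_right)
    if not (blob_l & masks.lc_search_left).sum() == blob_l.sum():
        raise ValueError("left LC blob leaks outside its search space")
    if not (blob_r & masks.lc_search_right).sum() == blob_r.sum():
        raise ValueError("right LC blob leaks outside its search space")

    nz = spec.grid_shape[2]
    drift = rng.uniform(*spec.slice_drift_range, size=nz)
    data = np.broadcast_to(drift, spec.grid_shape).copy() * spec.ref_mean_raw
    lc = blob_l | blob_r
    data[lc] *= spec.lc_true_intensity * session_scale
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    volume = VolumeGrid(data, spec.voxel_size, slice_axis=2)
    truth = GroundTruth(
        lc_blob_left=blob_l,
        lc_blob_right=blob_r,
        expected_lc_ri=100.0 * spec.lc_true_intensity * session_scale,
    )
    return volume, masks, truth


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def subject_effect_columns(subjects: pd.DataFrame) -> pd.DataFrame:
    """Z-scored covariates and interaction products used to plant effects."""
    z_bl = _zscore(subjects["bl_lc_ri"].to_numpy(float))
    z_dlc = _zscore(subjects["dlc_ri"].to_numpy(float))
    z_ab = _zscore(subjects["abeta"].to_numpy(float))
    return pd.DataFrame(
        {
            "bl_lc": z_bl,
            "dlc": z_dlc,
            "abeta": z_ab,
            "bl_lc_x_abeta": z_bl * z_ab,
            "dlc_x_abeta": z_dlc * z_ab,
        },
        index=subjects.index,
    )


def generate_cohort(
    cspec: CohortSpec,
    pspec: PhantomSpec | None = None,
    render_volumes: bool = False,
    seed: int | None = None,
) -> Cohort:
    """Simulate the longitudinal neuromelanin cohort.

    Per subject: baseline age, sex (1 = female), education, a true baseline
    LC_RI with an age gradient, a true linear decline slope (units/year)
    drawn around ``true_decline_rate``, global amyloid from a two-component
    mixture, and 2-3 sessions at noisy multi-month intervals.  The observed
    ``lc_ri`` column carries measurement noise of SD ``lc_ri_noise_sd``;
    with ``render_volumes=True`` a phantom volume whose session scale follows
    the subject's true trajectory is rendered for every session (phantom
    noise then models the measurement error instead, so the table carries
    the noiseless truth for reference).
    """
    rng = np.random.default_rng(cspec.seed if seed is None else seed)
    n = cspec.n_subjects
    sid = np.array([f"sub-{i:04d}" for i in range(n)])
    age = rng.normal(cspec.age_mean, cspec.age_sd, n)
    sex = (rng.random(n) < cspec.female_fraction).astype(int)  # 1 = female
    edu = np.clip(np.round(rng.normal(cspec.education_mean, cspec.education_sd, n)), 6, 22)
    bl = (
        rng.normal(cspec.bl_lc_ri_mean, cspec.bl_lc_ri_sd, n)
        + cspec.age_effect * (age - cspec.age_mean)
    )
    slope = rng.normal(cspec.true_decline_rate, cspec.decline_sd, n)
    if cspec.slope_bl_coupling != 0.0:
        slope = slope + cspec.slope_bl_coupling * _zscore(bl)
    positive = rng.random(n) < cspec.abeta_positive_fraction
    abeta = np.where(
        positive,
        rng.normal(cspec.abeta_positive_mean, cspec.abeta_positive_sd, n),
        rng.normal(cspec.abeta_negative_mean, cspec.abeta_negative_sd, n),
    )
    abeta = np.clip(abeta, 0.7, None)

    subjects = pd.DataFrame(
        {
            "subject_id": sid,
            "age_bl": age,
            "sex": sex,
            "education": edu.astype(int),
            "bl_lc_ri": bl,
            "dlc_ri": slope,
            "abeta": abeta,
            "abeta_positive": positive,
        }
    )
    truth = GroundTruth(subjects=subjects)

    rows = []
    volumes: list[tuple[str, int, VolumeGrid, MaskSet]] | None = (
        [] if render_volumes else None
    )
    for i in range(n):
        n_sess = int(rng.integers(cspec.sessions_min, cspec.sessions_max + 1))
        gaps = np.abs(
            rng.normal(cspec.interval_mean_months, cspec.interval_sd_months, n_sess - 1)
        )
        months = np.concatenate([[0.0], np.cumsum(np.maximum(gaps, 1.0))])
        lc_true = bl[i] + slope[i] * months / 12.0
        if render_volumes:
            observed = lc_true.copy()
        else:
            observed = lc_true + rng.normal(0.0, cspec.lc_ri_noise_sd, n_sess)
        for s in range(n_sess):
            rows.append(
                {
                    "subject_id": sid[i],
                    "session": s,
                    "months": months[s],
                    "age_bl": age[i],
                    "sex": sex[i],
                    "education": int(edu[i]),
                    "lc_ri": observed[s],
                    "lc_ri_true": lc_true[s],
                    "abeta": abeta[i],
                }
            )
            if render_volumes:
                if pspec is None:
                    raise ValueError("render_volumes=True requires a PhantomSpec")
                sub_spec = replace(pspec, lc_true_intensity=bl[i] / 100.0)
                scale = lc_true[s] / bl[i]
                vol, masks, _ = generate_phantom(sub_spec, scale, rng=rng)
                volumes.append((sid[i], s, vol, masks))
    sessions = pd.DataFrame(rows)
    return Cohort(sessions=sessions, truth=truth, volumes=volumes)


# --------------------------------------------------------------------------
# tau maps
# --------------------------------------------------------------------------


def generate_tau_maps(
    truth: GroundTruth,
    effect_regions: Sequence[TauEffectRegion],
    grid_shape: tuple[int, int, int] = (16, 16, 8),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    baseline_suvr: float = 1.2,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[VolumeGrid], GroundTruth]:
    """Per-subject tau SUVR phantoms with planted covariate effects.

    Inside each effect region, voxel value = ``baseline_suvr`` plus the sum
    of planted coefficients times the subject's (z-scored) covariate or
    interaction term, plus noise; elsewhere pure ``baseline_suvr`` + noise.
    Maps are returned in ``truth.subjects`` row order; the union signal mask
    and regions are recorded back onto the returned GroundTruth.
    """
    if truth.subjects is None:
        raise ValueError("cohort truth with a subjects table is required")
    rng = np.random.default_rng(seed)
    terms = subject_effect_columns(truth.subjects)
    region_masks = [r.mask(grid_shape) for r in effect_regions]
    maps: list[VolumeGrid] = []
    for i in range(len(truth.subjects)):
        data = np.full(grid_shape, baseline_suvr, dtype=float)
        for region, mask in zip(effect_regions, region_masks):
            bump = 0.0
            for term, coef in region.coefficients.items():
                if term not in EFFECT_TERMS:
                    raise ValueError(f"unknown effect term {term!r}")
                bump += coef * terms.iloc[i][term]
            data[mask] += bump
        if noise_sd > 0:
            data += rng.normal(0.0, noise_sd, size=grid_shape)
        maps.append(VolumeGrid(data, voxel_size))
    signal = np.zeros(grid_shape, dtype=bool)
    for mask in region_masks:
        signal |= mask
    out_truth = replace(
        truth, tau_regions=list(effect_regions), tau_signal_mask=signal
    )
    return maps, out_truth


# --------------------------------------------------------------------------
# cognition
# --------------------------------------------------------------------------


def generate_cognition(
    truth: GroundTruth,
    cspec: CohortSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Longitudinal cognition table with planted trajectory structure.

    Score(domain, t) = intercept + b_i(domain) + slope_i(domain) * t_years
    + residual, where slope_i = time effect + planted interaction effects
    evaluated at the subject's z-scored covariates, and b_i is a subject
    random intercept.  Visit schedules are annual with jitter; counts follow
    a truncated normal (2-11 visits).  The per-subject deterministic slopes
    are recorded in ``truth.cognition_slopes``.
    """
    if truth.subjects is None:
        raise ValueError("cohort truth with a subjects table is required")
    rng = np.random.default_rng(cspec.seed + 1 if seed is None else seed)
    subjects = truth.subjects
    n = len(subjects)
    terms = subject_effect_columns(subjects)

    lo, hi = cspec.cognition_visits_range
    n_visits = np.clip(
        np.round(rng.normal(cspec.cognition_visits_mean, cspec.cognition_visits_sd, n)),
        lo,
        hi,
    ).astype(int)

    rows = []
    slope_rows = []
    for i in range(n):
        gaps = np.abs(
            rng.normal(
                cspec.cognition_interval_months,
                cspec.cognition_interval_sd,
                n_visits[i] - 1,
            )
        )
        months = np.concatenate([[0.0], np.cumsum(np.maximum(gaps, 1.0))])
        rints = {
            d: rng.normal(0.0, cspec.cognition_random_intercept_sd)
            for d in COGNITION_DOMAINS
        }
        for d in COGNITION_DOMAINS:
            eff = cspec.effects_for(d)
            slope = eff.get("time", 0.0)
            for term in EFFECT_TERMS:
                slope += eff.get(f"time_x_{term}", 0.0) * terms.iloc[i][term]
            slope_rows.append(
                {"subject_id": subjects["subject_id"].iloc[i], "domain": d, "slope_per_year": slope}
            )
            noise = (
                rng.normal(0.0, cspec.cognition_residual_sd, len(months))
                if cspec.cognition_residual_sd > 0
                else np.zeros(len(months))
            )
            for t, e in zip(months, noise):
                rows.append(
                    {
                        "subject_id": subjects["subject_id"].iloc[i],
                        "months": t,
                        "domain": d,
                        "score": cspec.cognition_intercept
                        + rints[d]
                        + slope * t / 12.0
                        + e,
                    }
                )
    table = pd.DataFrame(rows)
    out_truth = replace(truth, cognition_slopes=pd.DataFrame(slope_rows))
    return table, out_truth
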