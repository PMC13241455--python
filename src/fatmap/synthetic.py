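"""Synthetic cohort generator: covariates, muscle slices, and curve-level noise fields.

Everything downstream of image acquisition is testable against this module because
the spatial fat-infiltration structure and every covariate link are known exactly.
The generator emulates a chronic low-back-pain imaging cohort: per-subject axial
fat-fraction rasters with crescent-shaped multifidus masks posterolateral to the
vertebral center of rotation (CoR), at two lumbar levels times two slices, plus a
covariate table (age, sex, BMI, pain NRS, chronicity, weekly MET-minutes, and a
Pfirrmann disc grade per level).

Covariate-linked spatial effects are injected as ``EffectSpec`` entries: a slope in
FI% per standard deviation of a covariate, confined to a depth window expressed in
percent of radial muscle width (0% = deepest, adjacent to the CoR).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

LEVELS = ("L4L5", "L5S1")

# Pooled defaults for a 223-subject chronic low-back-pain cohort
# (103 male / 120 female; chronicity averages 11.9 yr, activity 3164.8 MET-min/wk).
_N_DEFAULT = 223
_F_FRACTION = 120 / 223


def _pooled(mean_m, sd_m, mean_f, sd_f, n_m=103, n_f=120):
    n = n_m + n_f
    mean = (n_m * mean_m + n_f * mean_f) / n
    # pooled SD including the between-group mean spread
    var = (n_m * (sd_m**2 + (mean_m - mean) ** 2) + n_f * (sd_f**2 + (mean_f - mean) ** 2)) / n
    return round(mean, 2), round(math.sqrt(var), 2)


_AGE = _pooled(51.4, 14.7, 54.4, 15.9)
_BMI = _pooled(26.2, 3.8, 26.0, 4.8)
_PAIN = _pooled(4.4, 1.8, 4.5, 2.0)
_CHRON = (11.9, 12.7)
_MET = (3164.8, 2920.4)

# Disc degeneration at the lower lumbar levels of a middle-aged cLBP cohort is
# concentrated at Pfirrmann grades 3-4; grade 1 (pristine) discs are rare.
_PFIRRMANN_DEFAULT = (0.03, 0.15, 0.37, 0.32, 0.13)

CHRONICITY_FLOOR_YR = 0.25  # inclusion requires pain for >= 3 of the past 6 months


@dataclass
class CovariateSpec:
    """Marginal distributions for one synthetic cohort.

    Chronicity and MET-minutes are drawn from truncated normals (left-truncated
    at :data:`CHRONICITY_FLOOR_YR` years and 0 respectively) whose *truncated*
    mean is solved to equal the requested mean, so sample means converge to the
    spec values. Pain is a normal clipped to the 0-10 NRS range.
    """

    n_subjects: int = _N_DEFAULT
    age_mean_sd: tuple[float, float] = _AGE
    bmi_mean_sd: tuple[float, float] = _BMI
    chronicity_mean_sd: tuple[float, float] = _CHRON
    met_mean_sd: tuple[float, float] = _MET
    pain_mean_sd: tuple[float, float] = _PAIN
    sex_fraction_female: float = _F_FRACTION
    pfirrmann_probs: tuple[float, ...] = _PFIRRMANN_DEFAULT
    seed: int = 0

    def validate(self) -> None:
        pairs = {
            "age": self.age_mean_sd,
            "bmi": self.bmi_mean_sd,
            "chronicity": self.chronicity_mean_sd,
            "met": self.met_mean_sd,
            "pain": self.pain_mean_sd,
        }
        for name, (m, s) in pairs.items():
            if not (np.isfinite(m) and np.isfinite(s)):
                raise ValueError(f"non-finite {name} mean/sd: {(m, s)}")
            if s < 0:
                raise ValueError(f"negative {name} sd: {s}")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ValueError("sex_fraction_female must be in [0,1]")
        p = np.asarray(self.pfirrmann_probs, dtype=float)
        if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pfirrmann_probs must be 5 nonnegative values summing to 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


@dataclass
class EffectSpec:
    """A covariate-linked spatial effect confined to a radial depth window."""

    target_covariate: str
    depth_window: tuple[float, float]  # percent of radial width, [start, end]
    slope: float  # FI% change per 1 SD of the covariate
    level: str = "both"  # L4L5 | L5S1 | both
    sign: int = +1

    def validate(self) -> None:
        lo, hi = self.depth_window
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"depth window must satisfy 0 <= start < end <= 100: {self.depth_window}")
        if self.level not in (*LEVELS, "both"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")

    def applies_to(self, level: str) -> bool:
        return self.level == "both" or self.level == level


@dataclass
class SliceGeometry:
    """Half-annulus sector geometry for a synthetic multifidus mask.

    The muscle is modelled as two mirror-image annular sectors posterior to the
    CoR: radial extent ``r_inner``..``r_outer`` pixels, each side spanning
    ``ang_half_deg`` degrees away from the posterior midline. Pixel spacing is
    1.0 unit by default.
    """

    shape: tuple[int, int] = (96, 96)
    cor: tuple[float, float] = (24.0, 47.5)  # (row, col); posterior = increasing row
    r_inner: float = 10.0
    r_outer: float = 34.0
    ang_gap_deg: float = 8.0  # midline gap between left and right muscle
    ang_half_deg: float = 55.0
    pixel_spacing: float = 1.0

    def side_mask(self, side: str) -> np.ndarray:
        rows, cols = np.indices(self.shape)
        dr = rows - self.cor[0]
        dc = cols - self.cor[1]
        d = np.hypot(dr, dc)
        ang = np.degrees(np.arctan2(dc, dr))  # 0 deg = straight posterior
        lo, hi = self.ang_gap_deg / 2.0, self.ang_gap_deg / 2.0 + self.ang_half_deg
        if side == "left":
            in_sector = (ang >= lo) & (ang <= hi)
        elif side == "right":
            in_sector = (ang <= -lo) & (ang >= -hi)
        else:
            raise ValueError(f"unknown side {side!r}")
        mask = in_sector & (d >= self.r_inner) & (d <= self.r_outer)
        if not mask.any():
            raise ValueError("geometry produces an empty mask")
        return mask


def default_baseline_profile(depth_pct: np.ndarray) -> np.ndarray:
    """Baseline radial FI profile: fattier deep muscle falling toward ~mid-depth
    then rising again superficially, in a plausible 10-35 FI% range."""
    x = np.asarray(depth_pct, dtype=float) / 100.0
    return 22.0 - 10.0 * np.sin(np.pi * x) + 8.0 * (1.0 - x) ** 2


def _solve_truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location mu such that a normal(mu, sd) left-truncated at `lower` has the
    requested mean."""
    if sd == 0:
        return max(target_mean, lower)

    def trunc_mean(mu):
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd)

    lo = target_mean - 6 * sd
    hi = target_mean + sd
    return optimize.brentq(lambda mu: trunc_mean(mu) - target_mean, lo, hi, xtol=1e-8)


def draw_covariates(spec: CovariateSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one subject table (one row per subject) from a :class:`CovariateSpec`.

    Returns columns: id, age, sex (M/F), bmi, pain_nrs, chronicity_yr,
    met_min_wk, pfirrmann_L4L5, pfirrmann_L5S1.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    def trunc_draw(mean, sd, lower):
        if sd == 0:
            return np.full(n, max(mean, lower))
        mu = _solve_truncnorm_loc(mean, sd, lower)
        a = (lower - mu) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)

    age = rng.normal(*spec.age_mean_sd, size=n)
    bmi = rng.normal(*spec.bmi_mean_sd, size=n)
    pain = np.clip(rng.normal(*spec.pain_mean_sd, size=n), 0.0, 10.0)
    chron = trunc_draw(*spec.chronicity_mean_sd, CHRONICITY_FLOOR_YR)
    met = trunc_draw(*spec.met_mean_sd, 0.0)
    sex = np.where(rng.random(n) < spec.sex_fraction_female, "F", "M")
    grades = {
        lv: rng.choice(np.arange(1, 6), size=n, p=np.asarray(spec.pfirrmann_probs)) for lv in LEVELS
    }
    return pd.DataFrame(
        {
            "id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "pain_nrs": pain,
            "chronicity_yr": chron,
            "met_min_wk": met,
            "pfirrmann_L4L5": grades["L4L5"],
            "pfirrmann_L5S1": grades["L5S1"],
        }
    )


_COVARIATE_COLUMNS = {
    "age": "age",
    "bmi": "bmi",
    "pain": "pain_nrs",
    "pain_nrs": "pain_nrs",
    "chronicity": "chronicity_yr",
    "chronicity_yr": "chronicity_yr",
    "met": "met_min_wk",
    "met_min_wk": "met_min_wk",
    "activity": "met_min_wk",
}


def covariate_column(name: str) -> str:
    """Map a covariate alias (e.g. 'chronicity', 'activity') to its table column."""
    try:
        return _COVARIATE_COLUMNS[name]
    except KeyError:
        raise KeyError(f"unknown covariate {name!r}; known: {sorted(set(_COVARIATE_COLUMNS))}")


def standardized_covariate(cohort: pd.DataFrame, name: str) -> np.ndarray:
    col = covariate_column(name)
    x = cohort[col].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def render_muscle_slice(
    record: pd.Series,
    z_scores: dict[str, float],
    geometry: SliceGeometry,
    level: str,
    slice_index: int,
    baseline=default_baseline_profile,
    effects: list[EffectSpec] | None = None,
    noise_sd: float = 4.0,
    rng: np.random.Generator | None = None,
    offset: float = 0.0,
):
    """Render one axial fat-fraction slice for one subject.

    Pixel FI = baseline(depth%) + sum of active effects x standardized covariate
    + Gaussian noise, clipped to [0,100]. Left/right masks get independent noise.
    ``z_scores`` holds the subject's cohort-standardized covariate values.

    Returns a :class:`fatmap.mapping.FatFractionSlice`.
    """
    from .mapping import FatFractionSlice  # local import to avoid a cycle

    if rng is None:
        rng = np.random.default_rng(0)
    effects = effects or []
    for e in effects:
        e.validate()

    fat = np.zeros(geometry.shape, dtype=float)
    masks = {}
    rows, cols = np.indices(geometry.shape)
    d = np.hypot(rows - geometry.cor[0], cols - geometry.cor[1]) * geometry.pixel_spacing
    for side in ("left", "right"):
        mask = geometry.side_mask(side)
        dm = d[mask]
        span = dm.max() - dm.min()
        depth_pct = np.zeros_like(dm) if span == 0 else (dm - dm.min()) / span * 100.0
        vals = baseline(depth_pct).astype(float) + offset
        for e in effects:
            if not e.applies_to(level):
                continue
            lo, hi = e.depth_window
            in_win = (depth_pct >= lo) & (depth_pct <= hi)
            z = z_scores.get(e.target_covariate, z_scores.get(covariate_column(e.target_covariate), 0.0))
            vals[in_win] += e.sign * e.slope * z
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        fat[mask] = np.clip(vals, 0.0, 100.0)
        masks[side] = mask
    return FatFractionSlice(
        fat=fat,
        masks=masks,
        cor=geometry.cor,
        level=level,
        slice_index=slice_index,
        pixel_spacing=geometry.pixel_spacing,
        subject=str(record.get("id", "?")),
    )


@dataclass
class SyntheticSubject:
    record: pd.Series
    slices: list  # FatFractionSlice, 2 levels x 2 slices
    truth: list[EffectSpec] = field(default_factory=list)


def generate_cohort(
    spec: CovariateSpec,
    effects: list[EffectSpec] | None = None,
    geometry: SliceGeometry | None = None,
    noise_sd: float = 4.0,
    subject_sd: float = 0.0,
    baseline=default_baseline_profile,
) -> tuple[pd.DataFrame, list[SyntheticSubject]]:
    """Generate a full synthetic cohort: covariate table + rendered slices.

    ``subject_sd`` adds a per-subject constant FI offset shared by all of a
    subject's slices (between-subject variation beyond the covariate links).
    Deterministic for a fixed spec (the spec's seed is fanned out via
    ``SeedSequence`` to the covariate draw and each subject's renderer).
    """
    spec.validate()
    effects = effects or []
    geometry = geometry or SliceGeometry()
    ss = np.random.SeedSequence(spec.seed)
    cov_seed, *subject_seeds = ss.spawn(1 + spec.n_subjects)
    cohort = draw_covariates(spec, np.random.default_rng(cov_seed))

    z_by_name = {}
    for e in effects:
        z_by_name[e.target_covariate] = standardized_covariate(cohort, e.target_covariate)

    subjects = []
    for i, (_, rec) in enumerate(cohort.iterrows()):
        rng = np.random.default_rng(subject_seeds[i])
        offset = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        z_scores = {name: z[i] for name, z in z_by_name.items()}
        slices = [
            render_muscle_slice(
                rec, z_scores, geometry, level, k, baseline=baseline,
                effects=effects, noise_sd=noise_sd, rng=rng, offset=offset,
            )
            for level in LEVELS
            for k in (1, 2)
        ]
        subjects.append(SyntheticSubject(record=rec, slices=slices, truth=list(effects)))
    return cohort, subjects


# ---------------------------------------------------------------------------
# Curve-level generation (desk-scale simulations: FWER calibration, recovery)
# ---------------------------------------------------------------------------

def smooth_gaussian_curves(
    n: int,
    n_nodes: int = 101,
    fwhm: float = 10.0,
    sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n smooth unit-variance Gaussian curves with the given correlation FWHM.

    White noise convolved (circularly, for stationarity) with a Gaussian kernel
    of the same FWHM yields a field whose random-field-theory smoothness equals
    the kernel FWHM; the result is rescaled to pointwise sd ``sd``.
    """
    from scipy.ndimage import gaussian_filter1d

    if rng is None:
        rng = np.random.default_rng(0)
    white = rng.standard_normal((n, n_nodes))
    if fwhm <= 0:
        return sd * white
    sigma = fwhm / math.sqrt(8.0 * math.log(2.0))
    smooth = gaussian_filter1d(white, sigma, axis=1, mode="wrap")
    # exact pointwise variance of circularly smoothed white noise = sum of
    # squared kernel weights; renormalize so the field has pointwise sd `sd`
    impulse = np.zeros(n_nodes)
    impulse[0] = 1.0
    w = gaussian_filter1d(impulse, sigma, mode="wrap")
    return sd * smooth / math.sqrt(float(np.sum(w**2)))


def synthetic_curve_cohort(
    spec: CovariateSpec,
    effects: list[EffectSpec] | None = None,
    noise_sd: float = 4.0,
    noise_fwhm: float = 10.0,
    subject_sd: float = 0.0,
    n_nodes: int = 101,
    baseline=default_baseline_profile,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Generate per-level subject x node curve matrices directly (no rendering).

    The curve model matches :func:`render_muscle_slice` — baseline profile plus
    depth-windowed covariate effects — but noise is injected per curve node as a
    smooth Gaussian field, which is the natural scale for power/error-rate
    simulations of the SPM stage.
    """
    spec.validate()
    effects = effects or []
    for e in effects:
        e.validate()
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    cov_seed, noise_seed = ss.spawn(2)
    cohort = draw_covariates(spec, np.random.default_rng(cov_seed))
    grid = np.linspace(0.0, 100.0, n_nodes)
    base = baseline(grid)
    noise_rng = np.random.default_rng(noise_seed)
    offsets = (noise_rng.normal(0.0, subject_sd, spec.n_subjects)
               if subject_sd > 0 else np.zeros(spec.n_subjects))

    curves = {}
    for level in LEVELS:
        y = np.tile(base, (spec.n_subjects, 1)) + offsets[:, None]
        for e in effects:
            if not e.applies_to(level):
                continue
            z = standardized_covariate(cohort, e.target_covariate)
            lo, hi = e.depth_window
            win = (grid >= lo) & (grid <= hi)
            y[:, win] += (e.sign * e.slope * z)[:, None]
        if noise_sd > 0:
            y = y + smooth_gaussian_curves(spec.n_subjects, n_nodes, noise_fwhm, noise_sd, noise_rng)
        curves[level] = y
    return cohort, curves


# ---------------------------------------------------------------------------
# IPAQ scoring
# ---------------------------------------------------------------------------

IPAQ_WEIGHTS = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}


def met_minutes_from_ipaq(
    vigorous_days: float = 0, vigorous_min: float = 0,
    moderate_days: float = 0, moderate_min: float = 0,
    walking_days: float = 0, walking_min: float = 0,
) -> float:
    """Weekly MET-minutes from IPAQ activity frequencies/durations.

    Standard IPAQ scoring: MET-min/wk = 8.0 x vigorous days x min/day
    + 4.0 x moderate + 3.3 x walking.
    """
    vals = dict(
        vigorous=(vigorous_days, vigorous_min),
        moderate=(moderate_days, moderate_min),
        walking=(walking_days, walking_min),
    )
    total = 0.0
    for kind, (days, minutes) in vals.items():
        if days < 0 or minutes < 0:
            raise ValueError(f"negative {kind} input")
        if minutes > 1440:
            raise ValueError(f"{kind} minutes/day exceeds 1440")
        total += IPAQ_WEIGHTS[kind] * days * minutes
    return total
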