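"""Synthetic phantoms and cohort simulation with analytic ground truth.

Two generators make the whole pipeline testable without any acquisition:

``make_phantom``
    An annular "myocardium" on a pixel grid with a controllable transmural
    MBF profile (uniform, linear in transmural depth, or a step at midwall)
    plus optional Gaussian noise, together with its endo/epi contours, an
    RV-insertion landmark and the analytically known layer means/gradient.

``make_cohort``
    A simulated healthy cohort whose layer, slice, territory and global
    metrics carry the statistical structure reported for healthy adults:
    higher absolute MBF in women than men, an age-related decline of stress
    MBF but not rest MBF, a rest endo-to-epi ratio above one against a
    stress ratio near or below one, and mid-slice reserves below the basal
    and apical ones.  Per-subject values are drawn from truncated normal
    distributions with multiplicative sex/slice/territory effects; the
    printed cohort summary statistics are the anchors for the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate
from shapely.geometry import Polygon

from . import metrics as pm
from .geometry import BACKGROUND, ContourSet, PerfusionMap
from .metrics import SubjectRecord

__all__ = [
    "PhantomSpec", "make_phantom", "annulus_contours",
    "CohortSpec", "make_cohort", "cohort_to_frame", "make_subject_maps",
]

_PROFILES = ("uniform", "linear", "step")


def _pair(v) -> tuple[float, float]:
    if np.isscalar(v):
        return (float(v), float(v))
    a, b = v
    return (float(a), float(b))


@dataclass
class PhantomSpec:
    """Recipe for one annular perfusion phantom.

    Radii may be scalars (circles) or (rx, ry) pairs (axis-aligned ellipses).
    ``endo_value`` / ``epi_value`` are the MBF values at the endocardial and
    epicardial borders in mL/min/g; the profile interpolates between them as
    a function of normalised transmural depth (0 at endo border, 1 at epi).
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.0
    center: tuple[float, float] | None = None  # defaults to grid centre
    endo_radius: float | tuple[float, float] = 20.0
    epi_radius: float | tuple[float, float] = 30.0
    endo_value: float = 2.0
    epi_value: float = 2.0
    profile: str = "uniform"
    noise_sd: float = 0.0
    rv_insertion_angle: float = 90.0
    slice_label: str = "mid"
    state: str = "stress"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        er, pr = _pair(self.endo_radius), _pair(self.epi_radius)
        if not (pr[0] > er[0] > 0 and pr[1] > er[1] > 0):
            raise ValueError("need epi_radius > endo_radius > 0 on both axes")
        if self.center is None:
            self.center = (self.grid_shape[1] * self.pixel_spacing / 2,
                           self.grid_shape[0] * self.pixel_spacing / 2)
        cx, cy = self.center
        h = self.grid_shape[0] * self.pixel_spacing
        w = self.grid_shape[1] * self.pixel_spacing
        if (cx - pr[0] < 0 or cx + pr[0] > w or cy - pr[1] < 0
                or cy + pr[1] > h):
            raise ValueError(
                "grid does not cover the epicardial contour; enlarge the grid "
                "or shrink the radii")

    @property
    def is_circular(self) -> bool:
        er, pr = _pair(self.endo_radius), _pair(self.epi_radius)
        return er[0] == er[1] and pr[0] == pr[1]


def _ellipse_polygon(center, radii, n_vertices=360) -> Polygon:
    cx, cy = center
    rx, ry = _pair(radii)
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return Polygon(np.column_stack([cx + rx * np.cos(ang),
                                    cy + ry * np.sin(ang)]))


def annulus_contours(spec: PhantomSpec, n_vertices: int = 360) -> ContourSet:
    """Endo/epi contours and RV-insertion landmark for a phantom spec."""
    endo = _ellipse_polygon(spec.center, spec.endo_radius, n_vertices)
    epi = _ellipse_polygon(spec.center, spec.epi_radius, n_vertices)
    rx, ry = _pair(spec.epi_radius)
    a = math.radians(spec.rv_insertion_angle)
    rv = (spec.center[0] + rx * math.cos(a), spec.center[1] + ry * math.sin(a))
    return ContourSet(endo, epi, rv)


def _transmural_depth(spec: PhantomSpec, x: np.ndarray, y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Normalised depth in [0, 1] and an in-annulus mask for points (mm).

    Circular phantoms use the exact radial formula; elliptical ones the
    distance rule d_endo / (d_endo + d_epi) against the two contour rings.
    """
    cx, cy = spec.center
    if spec.is_circular:
        r_endo = _pair(spec.endo_radius)[0]
        r_epi = _pair(spec.epi_radius)[0]
        r = np.hypot(x - cx, y - cy)
        inside = (r >= r_endo) & (r <= r_epi)
        t = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
        return t, inside
    import shapely
    endo = _ellipse_polygon(spec.center, spec.endo_radius)
    epi = _ellipse_polygon(spec.center, spec.epi_radius)
    pts = shapely.points(np.column_stack([np.ravel(x), np.ravel(y)]))
    d_endo = shapely.distance(pts, endo.exterior).reshape(np.shape(x))
    d_epi = shapely.distance(pts, epi.exterior).reshape(np.shape(x))
    inside = (shapely.intersects_xy(epi, np.ravel(x), np.ravel(y))
              & ~shapely.contains_xy(endo, np.ravel(x), np.ravel(y))
              ).reshape(np.shape(x))
    t = d_endo / np.maximum(d_endo + d_epi, 1e-12)
    return np.clip(t, 0.0, 1.0), inside


def _profile_values(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    if spec.profile == "uniform":
        return np.full_like(t, spec.endo_value)
    if spec.profile == "linear":
        return spec.endo_value + (spec.epi_value - spec.endo_value) * t
    # step at midwall; the tie t == 0.5 goes with the inner half, matching
    # the midline tie-break used in layer assignment
    return np.where(t <= 0.5, spec.endo_value, spec.epi_value)


def phantom_ground_truth(spec: PhantomSpec) -> dict[str, float]:
    """Analytic layer means and endo-to-epi gradient for a noise-free phantom.

    Layer membership is depth < 1/2 (inner half of the wall).  Circular
    linear profiles are integrated in closed form (radial quadrature); other
    elliptical cases fall back to dense numerical quadrature on a 0.1 mm
    grid.  Means are area-weighted over each half-annulus.
    """
    if spec.profile == "uniform":
        g = 1.0
        return {"endo_mean": spec.endo_value, "epi_mean": spec.endo_value,
                "gradient": g}
    if spec.profile == "step":
        return {"endo_mean": spec.endo_value, "epi_mean": spec.epi_value,
                "gradient": spec.endo_value / spec.epi_value}
    if spec.is_circular:
        a = _pair(spec.endo_radius)[0]
        b = _pair(spec.epi_radius)[0]
        m = 0.5 * (a + b)

        def v(r):
            return spec.endo_value + (spec.epi_value - spec.endo_value) \
                * (r - a) / (b - a)

        def layer_mean(lo, hi):
            num, _ = integrate.quad(lambda r: v(r) * r, lo, hi)
            den, _ = integrate.quad(lambda r: r, lo, hi)
            return num / den

        endo_mean = layer_mean(a, m)
        epi_mean = layer_mean(m, b)
    else:
        step = 0.1
        rx, ry = _pair(spec.epi_radius)
        cx, cy = spec.center
        xs = np.arange(cx - rx - step, cx + rx + step, step)
        ys = np.arange(cy - ry - step, cy + ry + step, step)
        X, Y = np.meshgrid(xs, ys)
        t, inside = _transmural_depth(spec, X, Y)
        vals = _profile_values(spec, t)
        endo_mean = float(vals[inside & (t < 0.5)].mean())
        epi_mean = float(vals[inside & (t >= 0.5)].mean())
    return {"endo_mean": float(endo_mean), "epi_mean": float(epi_mean),
            "gradient": float(endo_mean / epi_mean)}


def make_phantom(spec: PhantomSpec
                 ) -> tuple[PerfusionMap, ContourSet, dict[str, float]]:
    """Build one annular perfusion phantom with its analytic ground truth.

    Pixels outside the annulus carry the background sentinel (NaN); inside,
    values follow the requested transmural profile plus Gaussian noise
    (clipped at zero so the non-negativity invariant holds).
    """
    rows, cols = spec.grid_shape
    y = (np.arange(rows) + 0.5) * spec.pixel_spacing
    x = (np.arange(cols) + 0.5) * spec.pixel_spacing
    X, Y = np.meshgrid(x, y)
    t, inside = _transmural_depth(spec, X, Y)
    values = np.full((rows, cols), BACKGROUND)
    values[inside] = _profile_values(spec, t)[inside]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=int(inside.sum()))
        values[inside] = np.maximum(values[inside] + noise, 0.0)
    pmap = PerfusionMap(values, spec.pixel_spacing, spec.slice_label, spec.state)
    return pmap, annulus_contours(spec), phantom_ground_truth(spec)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

SLICES = ("basal", "mid", "apical")


def _sex_dict(female: float, male: float) -> dict[str, float]:
    return {"female": float(female), "male": float(male)}


@dataclass
class CohortSpec:
    """Parameters of the simulated healthy cohort.

    Defaults are anchored to the healthy-adult summary statistics of a
    138-subject two-centre reference cohort: global rest MBF 0.68 +/- 0.13
    (women) vs 0.56 +/- 0.17 (men) mL/min/g, stress 2.41 +/- 0.47 vs
    2.12 +/- 0.53, a rest endo-to-epi ratio around 1.11 against a stress
    ratio around 0.98, slice-dependent effects that leave the mid slice with
    the lowest reserve, and a stress-only age decline sized so the stress
    endo-MBF vs age correlation lands near -0.47 over ages 19-79.
    """

    n_subjects: int = 138
    sex_ratio: float = 54 / 138          # fraction female
    age_range: tuple[float, float] = (19.0, 79.0)

    rest_mbf_mean: dict[str, float] = field(
        default_factory=lambda: _sex_dict(0.68, 0.56))
    rest_mbf_sd: dict[str, float] = field(
        default_factory=lambda: _sex_dict(0.13, 0.17))
    stress_mbf_mean: dict[str, float] = field(
        default_factory=lambda: _sex_dict(2.41, 2.12))
    stress_mbf_sd: dict[str, float] = field(
        default_factory=lambda: _sex_dict(0.47, 0.53))
    rest_stress_corr: float = 0.3        # within-subject rest/stress coupling

    age_slope_stress: float = -0.0135    # mL/min/g per year
    age_slope_rest: float = 0.0

    # endo-to-epi layer ratio per state and slice (rGRAD-like > 1 at rest,
    # ~1 or below at stress), with subject- and slice-level variability
    layer_ratio_rest: dict[str, float] = field(
        default_factory=lambda: {"basal": 1.08, "mid": 1.09, "apical": 1.16})
    layer_ratio_stress: dict[str, float] = field(
        default_factory=lambda: {"basal": 0.98, "mid": 0.92, "apical": 1.03})
    ratio_sd_subject: dict[str, float] = field(
        default_factory=lambda: {"stress": 0.06, "rest": 0.055})
    ratio_sd_slice: dict[str, float] = field(
        default_factory=lambda: {"stress": 0.10, "rest": 0.07})

    # multiplicative slice effects on MBF magnitude, per state; their
    # stress/rest quotient sets the slice pattern of the reserves
    slice_effects_stress: dict[str, float] = field(
        default_factory=lambda: {"basal": 1.04, "mid": 0.96, "apical": 1.00})
    slice_effects_rest: dict[str, float] = field(
        default_factory=lambda: {"basal": 1.02, "mid": 1.02, "apical": 0.96})
    slice_noise_sd: float = 0.05         # multiplicative, per slice x state

    # coronary-territory structure (LAD highest, RCA lowest)
    territory_factors: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rest": {"LAD": 1.07, "LCX": 0.97, "RCA": 0.93},
            "stress": {"LAD": 1.05, "LCX": 1.00, "RCA": 0.94}})
    territory_ratio_adjust: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rest": {"LAD": 0.97, "LCX": 1.04, "RCA": 0.99},
            "stress": {"LAD": 1.00, "LCX": 0.97, "RCA": 1.02}})
    territory_noise_sd: float = 0.03

    hr_rest: dict[str, float] = field(default_factory=lambda: _sex_dict(65, 63))
    hr_rest_sd: dict[str, float] = field(default_factory=lambda: _sex_dict(9, 9))
    sbp_rest: dict[str, float] = field(default_factory=lambda: _sex_dict(112, 120))
    sbp_rest_sd: dict[str, float] = field(default_factory=lambda: _sex_dict(19, 19))
    hr_stress: dict[str, float] = field(default_factory=lambda: _sex_dict(95, 86))
    hr_stress_sd: dict[str, float] = field(default_factory=lambda: _sex_dict(15, 14))
    sbp_stress: dict[str, float] = field(default_factory=lambda: _sex_dict(116, 125))
    sbp_stress_sd: dict[str, float] = field(default_factory=lambda: _sex_dict(22, 17))

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort statistics need at least 2 subjects")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for d in (self.rest_mbf_sd, self.stress_mbf_sd, self.hr_rest_sd,
                  self.hr_stress_sd, self.sbp_rest_sd, self.sbp_stress_sd):
            if min(d.values()) < 0:
                raise ValueError("standard deviations must be non-negative")
        for d in (self.slice_effects_stress, self.slice_effects_rest):
            if min(d.values()) <= 0:
                raise ValueError("slice effects must be positive")

    def with_zero_noise(self) -> "CohortSpec":
        """Copy with every stochastic term silenced (degenerate cohort)."""
        zero_sex = _sex_dict(0, 0)
        return replace(
            self,
            rest_mbf_sd=dict(zero_sex), stress_mbf_sd=dict(zero_sex),
            ratio_sd_subject={"stress": 0.0, "rest": 0.0},
            ratio_sd_slice={"stress": 0.0, "rest": 0.0},
            slice_noise_sd=0.0, territory_noise_sd=0.0,
            hr_rest_sd=dict(zero_sex), hr_stress_sd=dict(zero_sex),
            sbp_rest_sd=dict(zero_sex), sbp_stress_sd=dict(zero_sex),
        )


def _age_sd(age_range: tuple[float, float]) -> float:
    return (age_range[1] - age_range[0]) / math.sqrt(12.0)


def _residual_sd(total_sd: float, slope: float, age_sd: float) -> float:
    """SD of the noise term so the marginal SD matches the printed total."""
    explained = (slope * age_sd) ** 2
    return math.sqrt(max(total_sd ** 2 - explained, (0.25 * total_sd) ** 2))


def make_cohort(spec: CohortSpec, seed: int | None = None
                ) -> list[SubjectRecord]:
    """Simulate one cohort; reproducible for a fixed spec and seed.

    Every record carries the same metric keys that ``subject_pipeline``
    produces for measured maps (minus the per-segment entries), so the cohort
    table feeds the normative analysis unchanged.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    age_ref = 0.5 * (spec.age_range[0] + spec.age_range[1])
    age_sd = _age_sd(spec.age_range)
    rho = spec.rest_stress_corr
    records: list[SubjectRecord] = []

    for i in range(spec.n_subjects):
        sex = "female" if rng.random() < spec.sex_ratio else "male"
        age = float(rng.uniform(*spec.age_range))

        z_r = rng.standard_normal()
        z_s = rho * z_r + math.sqrt(1 - rho ** 2) * rng.standard_normal()
        sd_r = _residual_sd(spec.rest_mbf_sd[sex], spec.age_slope_rest, age_sd)
        sd_s = _residual_sd(spec.stress_mbf_sd[sex], spec.age_slope_stress, age_sd)
        base = {
            "rest": max(spec.rest_mbf_mean[sex]
                        + spec.age_slope_rest * (age - age_ref) + sd_r * z_r,
                        0.05),
            "stress": max(spec.stress_mbf_mean[sex]
                          + spec.age_slope_stress * (age - age_ref) + sd_s * z_s,
                          0.05),
        }
        g_off = {st: rng.normal(0.0, spec.ratio_sd_subject[st])
                 for st in ("stress", "rest")}

        layer_ratio = {"stress": spec.layer_ratio_stress,
                       "rest": spec.layer_ratio_rest}
        slice_eff = {"stress": spec.slice_effects_stress,
                     "rest": spec.slice_effects_rest}

        m: dict[str, float] = {}
        endo_acc: dict[str, list[float]] = {"stress": [], "rest": []}
        epi_acc: dict[str, list[float]] = {"stress": [], "rest": []}
        terr_endo: dict[tuple[str, str], list[float]] = {}
        terr_epi: dict[tuple[str, str], list[float]] = {}

        for sl in SLICES:
            for st, prefix in (("stress", "s"), ("rest", "r")):
                whole = base[st] * slice_eff[st][sl] \
                    * max(1.0 + rng.normal(0.0, spec.slice_noise_sd), 0.1)
                g = max(layer_ratio[st][sl] + g_off[st]
                        + rng.normal(0.0, spec.ratio_sd_slice[st]), 0.3)
                endo = whole * 2 * g / (1 + g)
                epi = whole * 2 / (1 + g)
                m[f"{prefix}MBF_{sl}"] = whole
                m[f"{prefix}MBF_ENDO_{sl}"] = endo
                m[f"{prefix}MBF_EPI_{sl}"] = epi
                m[f"{prefix}GRAD_{sl}"] = pm.transmural_gradient(endo, epi)
                endo_acc[st].append(endo)
                epi_acc[st].append(epi)
                for terr in ("LAD", "LCX", "RCA"):
                    tw = whole * spec.territory_factors[st][terr] \
                        * max(1.0 + rng.normal(0.0, spec.territory_noise_sd), 0.1)
                    tg = max(g * spec.territory_ratio_adjust[st][terr], 0.3)
                    terr_endo.setdefault((st, terr), []).append(tw * 2 * tg / (1 + tg))
                    terr_epi.setdefault((st, terr), []).append(tw * 2 / (1 + tg))

        for st, prefix in (("stress", "s"), ("rest", "r")):
            endo_g = float(np.mean(endo_acc[st]))
            epi_g = float(np.mean(epi_acc[st]))
            m[f"{prefix}MBF_ENDO"] = endo_g
            m[f"{prefix}MBF_EPI"] = epi_g
            m[f"{prefix}MBF"] = 0.5 * (endo_g + epi_g)
            m[f"{prefix}GRAD"] = pm.transmural_gradient(endo_g, epi_g)
            for terr in ("LAD", "LCX", "RCA"):
                te = float(np.mean(terr_endo[(st, terr)]))
                tp = float(np.mean(terr_epi[(st, terr)]))
                m[f"{prefix}MBF_ENDO_{terr}"] = te
                m[f"{prefix}MBF_EPI_{terr}"] = tp
                m[f"{prefix}MBF_{terr}"] = 0.5 * (te + tp)
                m[f"{prefix}GRAD_{terr}"] = pm.transmural_gradient(te, tp)

        for suffix in ["", "_ENDO", "_EPI",
                       "_LAD", "_LCX", "_RCA",
                       "_ENDO_LAD", "_ENDO_LCX", "_ENDO_RCA",
                       "_EPI_LAD", "_EPI_LCX", "_EPI_RCA",
                       "_basal", "_mid", "_apical",
                       "_ENDO_basal", "_ENDO_mid", "_ENDO_apical",
                       "_EPI_basal", "_EPI_mid", "_EPI_apical"]:
            m[f"MPR{suffix}"] = pm.mpr(m[f"sMBF{suffix}"], m[f"rMBF{suffix}"])

        hr_r = max(rng.normal(spec.hr_rest[sex], spec.hr_rest_sd[sex]), 40.0)
        hr_s = max(rng.normal(spec.hr_stress[sex], spec.hr_stress_sd[sex]), 40.0)
        bp_r = max(rng.normal(spec.sbp_rest[sex], spec.sbp_rest_sd[sex]), 80.0)
        bp_s = max(rng.normal(spec.sbp_stress[sex], spec.sbp_stress_sd[sex]), 80.0)
        m.update(pm.hemodynamic_metrics(hr_r, bp_r, hr_s, bp_s,
                                        m["rMBF"], m["sMBF"]))
        records.append(SubjectRecord(
            subject_id=f"sim{i:04d}", sex=sex, age=age,
            hr_rest=hr_r, hr_stress=hr_s, sbp_rest=bp_r, sbp_stress=bp_s,
            metrics=m))
    return records


def cohort_to_frame(records: Sequence[SubjectRecord]):
    """One row per subject with demographics, hemodynamics and all metrics."""
    import pandas as pd
    return pd.DataFrame([r.as_dict() for r in records])


def make_subject_maps(record: SubjectRecord, grid_shape=(128, 128),
                      pixel_spacing: float = 0.5, endo_radius: float = 20.0,
                      epi_radius: float = 30.0, noise_sd: float = 0.0,
                      seed: int = 0):
    """Render a simulated subject's layer values as step-profile phantom maps.

    Returns ``(maps, contours)`` in the shapes ``subject_pipeline`` expects;
    each slice/state map is a step-at-midwall annulus whose inner/outer
    values are the subject's generated endo/epi layer MBF for that slice.
    """
    maps: dict[tuple[str, str], PerfusionMap] = {}
    contours: dict[str, ContourSet] = {}
    for k, sl in enumerate(SLICES):
        for j, (st, prefix) in enumerate((("stress", "s"), ("rest", "r"))):
            spec = PhantomSpec(
                grid_shape=grid_shape, pixel_spacing=pixel_spacing,
                endo_radius=endo_radius, epi_radius=epi_radius,
                endo_value=record.metrics[f"{prefix}MBF_ENDO_{sl}"],
                epi_value=record.metrics[f"{prefix}MBF_EPI_{sl}"],
                profile="step", noise_sd=noise_sd, slice_label=sl, state=st,
                seed=seed + 10 * k + j)
            pmap, ctr, _ = make_phantom(spec)
            maps[(sl, st)] = pmap
            contours[sl] = ctr
    return maps, contours
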