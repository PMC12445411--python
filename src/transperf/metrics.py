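"""Scalar transmural perfusion metrics.

Implements the quantities derived from layered MBF maps: layer / segment /
territory / global / slice mean MBF, myocardial perfusion reserve (MPR =
sMBF/rMBF) per layer, the stress and rest endo-to-epi transmural gradients
(sGRAD = sMBF_ENDO/sMBF_EPI, rGRAD = rMBF_ENDO/rMBF_EPI), the rate-pressure
product (RPP = HR x systolic BP) and the RPP-normalised rest flow
rMBF_c = rMBF / (RPP/10000) with its reserve MPR_c = sMBF / rMBF_c.

Global and territory MBF values are pixel means over the pooled myocardial
pixels; slice-specific gradients and reserves are unweighted means of the
corresponding per-segment values.  Ratios with a denominator below 1e-9
mL/min/g are reported as missing (NaN), never as infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import aha
from .geometry import ContourSet, PerfusionMap, assign_layers, compute_midline, \
    interpolate_map

DENOM_GUARD = 1e-9


class MetricError(ValueError):
    """Raised when a metric's preconditions are violated."""


def region_mean_mbf(pmap: PerfusionMap, mask: np.ndarray) -> float:
    """Arithmetic mean MBF over the masked pixels (mL/min/g)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise MetricError("mask shape does not match the map grid")
    if not mask.any():
        raise MetricError("empty region mask (parcellation failure?)")
    vals = pmap.values[mask]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise MetricError("region mask covers only background pixels")
    return float(finite.mean())


def _ratio(num: float, den: float, what: str) -> float:
    if not np.isfinite(den) or den <= DENOM_GUARD:
        if den is not None and np.isfinite(den) and den <= 0:
            raise MetricError(f"{what} undefined: denominator {den!r} not positive")
        return float("nan")
    return float(num) / float(den)


def mpr(smbf: float, rmbf: float) -> float:
    """Myocardial perfusion reserve: stress over rest MBF."""
    return _ratio(smbf, rmbf, "MPR")


def transmural_gradient(endo_mbf: float, epi_mbf: float) -> float:
    """Endo-to-epi MBF ratio (sGRAD at stress, rGRAD at rest)."""
    return _ratio(endo_mbf, epi_mbf, "transmural gradient")


def rate_pressure_product(hr: float, sbp: float) -> float:
    """Rate-pressure product: heart rate (bpm) times systolic BP (mmHg)."""
    if hr <= 0 or sbp <= 0:
        raise MetricError("heart rate and systolic BP must be positive")
    return float(hr) * float(sbp)


def rpp_corrected_rmbf(rmbf: float, rpp: float) -> float:
    """Rest MBF normalised by the individual workload, rMBF / (RPP/10000)."""
    if rpp <= 0:
        raise MetricError("RPP must be positive")
    return float(rmbf) * 10000.0 / float(rpp)


def rpp_corrected_mpr(smbf: float, rmbf_c: float) -> float:
    """Workload-corrected reserve sMBF / rMBF_c (= MPR x RPP/10000)."""
    return _ratio(smbf, rmbf_c, "MPR_c")


def slice_metric(segment_values: Mapping[int, float], slice_label: str) -> float:
    """Unweighted mean of a per-segment metric over one slice's segments."""
    ids = aha.slice_segments(slice_label)
    missing = [s for s in ids if s not in segment_values]
    if missing:
        raise MetricError(f"missing segment values for IDs {missing}")
    return float(np.mean([segment_values[s] for s in ids]))


@dataclass
class SubjectRecord:
    """Demographics, hemodynamics and every derived perfusion metric."""

    subject_id: str
    sex: str
    age: float
    hr_rest: float
    hr_stress: float
    sbp_rest: float
    sbp_stress: float
    metrics: dict[str, float] = field(default_factory=dict)
    qc_excluded: bool = False

    def as_dict(self) -> dict[str, float]:
        out = {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "age": self.age,
            "hr_rest": self.hr_rest,
            "hr_stress": self.hr_stress,
            "sbp_rest": self.sbp_rest,
            "sbp_stress": self.sbp_stress,
            "qc_excluded": self.qc_excluded,
        }
        out.update(self.metrics)
        return out


def hemodynamic_metrics(hr_rest: float, sbp_rest: float, hr_stress: float,
                        sbp_stress: float, rmbf: float, smbf: float
                        ) -> dict[str, float]:
    """RPP at both states plus the RPP-corrected rest flow and reserve."""
    rpp_rest = rate_pressure_product(hr_rest, sbp_rest)
    rpp_stress = rate_pressure_product(hr_stress, sbp_stress)
    rmbf_c = rpp_corrected_rmbf(rmbf, rpp_rest)
    return {
        "RPP_rest": rpp_rest,
        "RPP_stress": rpp_stress,
        "rMBF_c": rmbf_c,
        "MPR_c": rpp_corrected_mpr(smbf, rmbf_c),
    }


def _pooled_mean(chunks: list[np.ndarray]) -> float:
    vals = np.concatenate(chunks) if chunks else np.array([])
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise MetricError("no myocardial pixels pooled for a regional mean")
    return float(finite.mean())


def subject_pipeline(maps: Mapping[tuple[str, str], PerfusionMap],
                     contours: Mapping[str, ContourSet],
                     subject_id: str = "subject",
                     sex: str = "female",
                     age: float = 50.0,
                     hr_rest: float = 62.0, sbp_rest: float = 118.0,
                     hr_stress: float = 89.0, sbp_stress: float = 120.0,
                     target_spacing: float = 1.0,
                     n_rays: int = 360) -> SubjectRecord:
    """Run the full per-subject analysis on six contoured slice maps.

    ``maps`` is keyed by ``(slice_label, state)`` for the three slices at both
    states; ``contours`` by slice label.  Each map is resampled to
    ``target_spacing`` mm, split into endo/epi layers by the equidistant
    midline, parcellated into AHA segments, and reduced to the full metric
    set (layer / territory / global / segment / slice means, MPR variants,
    transmural gradients and RPP-corrected quantities).
    """
    slices = ("basal", "mid", "apical")
    for sl in slices:
        for state in ("stress", "rest"):
            if (sl, state) not in maps:
                raise MetricError(f"missing map for slice {sl!r}, state {state!r}")
        if sl not in contours:
            raise MetricError(f"missing contours for slice {sl!r}")

    # per (state, region-key) lists of pixel-value arrays pooled across slices
    pool: dict[tuple[str, str], list[np.ndarray]] = {}
    seg_means: dict[str, dict[int, float]] = {}  # "sMBF_ENDO" -> {seg: value}
    slice_pool: dict[tuple[str, str, str], list[np.ndarray]] = {}

    for sl in slices:
        ctr = contours[sl]
        midline = compute_midline(ctr, n_rays=n_rays)
        for state, prefix in (("stress", "s"), ("rest", "r")):
            try:
                pm = interpolate_map(maps[(sl, state)], target_spacing)
                masks = assign_layers(pm, ctr, midline)
                segs = aha.build_segments(masks, ctr, sl)
            except Exception as exc:
                raise MetricError(
                    f"slice {sl!r}, state {state!r}: {exc}") from exc
            layer_masks = {"": masks.myocardium,
                           "_ENDO": masks.endo_layer, "_EPI": masks.epi_layer}
            for lname, lmask in layer_masks.items():
                key = f"{prefix}MBF{lname}"
                pool.setdefault((state, lname), []).append(pm.values[lmask])
                slice_pool.setdefault((state, lname, sl), []).append(pm.values[lmask])
                for terr in aha.TERRITORIES:
                    tmask = segs.territory_mask(terr) & lmask
                    pool.setdefault((state, f"{lname}_{terr}"), []).append(
                        pm.values[tmask])
                sm = seg_means.setdefault(key, {})
                for seg in segs.segment_ids:
                    sm[seg] = region_mean_mbf(pm, segs.mask(seg) & lmask)

    m: dict[str, float] = {}
    # pooled-pixel global and territory MBF per layer
    for (state, region), chunks in pool.items():
        prefix = "s" if state == "stress" else "r"
        m[f"{prefix}MBF{region}"] = _pooled_mean(chunks)
    # per-segment whole-wall / layer values
    for key, sm in seg_means.items():
        for seg, v in sm.items():
            m[f"{key}_seg{seg:02d}"] = v

    # reserves and gradients at global and territory level
    for region in ["", "_LAD", "_RCA", "_LCX"]:
        for lname in ["", "_ENDO", "_EPI"]:
            suffix = f"{lname}{region}" if region else lname
            m[f"MPR{suffix}"] = mpr(m[f"sMBF{suffix}"], m[f"rMBF{suffix}"])
        m[f"sGRAD{region}"] = transmural_gradient(
            m[f"sMBF_ENDO{region}"], m[f"sMBF_EPI{region}"])
        m[f"rGRAD{region}"] = transmural_gradient(
            m[f"rMBF_ENDO{region}"], m[f"rMBF_EPI{region}"])

    # slice-specific values: gradients and reserves as segment-mean averages,
    # slice MBF as pooled pixel means over the slice
    for sl in slices:
        ids = aha.slice_segments(sl)
        for lname in ["", "_ENDO", "_EPI"]:
            s_seg = seg_means[f"sMBF{lname}"]
            r_seg = seg_means[f"rMBF{lname}"]
            m[f"MPR{lname}_{sl}"] = slice_metric(
                {i: mpr(s_seg[i], r_seg[i]) for i in ids}, sl)
            for state, prefix in (("stress", "s"), ("rest", "r")):
                m[f"{prefix}MBF{lname}_{sl}"] = _pooled_mean(
                    slice_pool[(state, lname, sl)])
        se, pe = seg_means["sMBF_ENDO"], seg_means["sMBF_EPI"]
        re_, rp = seg_means["rMBF_ENDO"], seg_means["rMBF_EPI"]
        m[f"sGRAD_{sl}"] = slice_metric(
            {i: transmural_gradient(se[i], pe[i]) for i in ids}, sl)
        m[f"rGRAD_{sl}"] = slice_metric(
            {i: transmural_gradient(re_[i], rp[i]) for i in ids}, sl)

    m.update(hemodynamic_metrics(hr_rest, sbp_rest, hr_stress, sbp_stress,
                                 m["rMBF"], m["sMBF"]))
    return SubjectRecord(subject_id, sex, age, hr_rest, hr_stress,
                         sbp_rest, sbp_stress, metrics=m)
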