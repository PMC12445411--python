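"""File formats, run configuration and the end-to-end pipeline runner.

Maps travel either as plain-text matrices with a JSON sidecar carrying
``pixel_spacing``, ``slice_label`` and ``state`` (the reference format: text,
lossless, diffable) or as NIfTI with the spacing in the affine and the labels
in the same sidecar.  Contours are JSON polygon lists in mm.  Real scanners
emit vendor formats; converting them to these is the caller's burden.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import explain_validity

from .cohort import TransmuralNormals, TransmuralNormalsResults
from .geometry import ContourSet, GeometryError, PerfusionMap, SLICE_LABELS, STATES
from .metrics import SubjectRecord, subject_pipeline
from .synthetic import CohortSpec, cohort_to_frame, make_cohort, make_subject_maps

log = logging.getLogger("transperf")


class FormatError(ValueError):
    """Raised when an input file is malformed or missing metadata."""


_SIDECAR_FIELDS = ("pixel_spacing", "slice_label", "state")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii", ".txt"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_map(pmap: PerfusionMap, path: str | Path) -> Path:
    """Write a map as text matrix (or NIfTI) plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        affine = np.diag([pmap.pixel_spacing[1], pmap.pixel_spacing[0], 1, 1])
        nib.save(nib.Nifti1Image(pmap.values.astype(np.float64), affine),
                 str(path))
    else:
        np.savetxt(path, pmap.values, fmt="%.17g")
    sidecar = {
        "pixel_spacing": list(pmap.pixel_spacing),
        "slice_label": pmap.slice_label,
        "state": pmap.state,
        "units": "mL/min/g",
        "background": "NaN",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_map(path: str | Path) -> PerfusionMap:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar {sc_path.name} for {path.name}")
    meta = json.loads(sc_path.read_text())
    for f in _SIDECAR_FIELDS:
        if f not in meta:
            raise FormatError(f"sidecar {sc_path.name} lacks field {f!r}")
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib
        values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    else:
        values = np.loadtxt(path, ndmin=2)
    return PerfusionMap(values, tuple(meta["pixel_spacing"]),
                        meta["slice_label"], meta["state"])


def write_contours(contours: ContourSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "endo": np.asarray(contours.endo.exterior.coords)[:-1].tolist(),
        "epi": np.asarray(contours.epi.exterior.coords)[:-1].tolist(),
        "rv_insertion": list(contours.rv_insertion),
        "units": "mm",
    }
    path.write_text(json.dumps(payload))
    return path


def read_contours(path: str | Path) -> ContourSet:
    path = Path(path)
    data = json.loads(path.read_text())
    for key in ("endo", "epi", "rv_insertion"):
        if key not in data:
            raise FormatError(f"contour file {path.name} lacks field {key!r}")
    for name in ("endo", "epi"):
        poly = Polygon(np.asarray(data[name], dtype=float))
        if not (poly.is_valid and poly.is_simple):
            raise FormatError(
                f"{name} contour invalid: {explain_validity(poly)}")
    try:
        return ContourSet(np.asarray(data["endo"], dtype=float),
                          np.asarray(data["epi"], dtype=float),
                          tuple(data["rv_insertion"]))
    except GeometryError as exc:
        raise FormatError(str(exc)) from exc


def read_subject_dir(subject_dir: str | Path):
    """Discover the six slice/state maps and per-slice contours of a subject.

    Expects ``<slice>_<state>.txt`` (or ``.nii.gz``) with sidecars and
    ``contours_<slice>.json``.
    """
    subject_dir = Path(subject_dir)
    maps = {}
    contours = {}
    for sl in SLICE_LABELS:
        for st in STATES:
            hits = [p for ext in (".txt", ".nii.gz", ".nii")
                    for p in [subject_dir / f"{sl}_{st}{ext}"] if p.exists()]
            if not hits:
                raise FormatError(
                    f"{subject_dir}: no map found for slice {sl!r} state {st!r}")
            maps[(sl, st)] = read_map(hits[0])
        cpath = subject_dir / f"contours_{sl}.json"
        if not cpath.exists():
            raise FormatError(f"{subject_dir}: missing {cpath.name}")
        contours[sl] = read_contours(cpath)
    return maps, contours


def write_subject(maps, contours, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    for (sl, st), pmap in maps.items():
        write_map(pmap, out_dir / f"{sl}_{st}.txt")
    for sl, ctr in contours.items():
        write_contours(ctr, out_dir / f"contours_{sl}.json")
    return out_dir


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    out_dir: str = "transperf_out"
    seed: int = 0
    n_subjects: int = 20
    simulate: bool = True            # else: read subjects from input_dir
    input_dir: str | None = None
    with_maps: bool = False          # render phantom maps per simulated subject
    target_spacing: float = 1.0
    n_rays: int = 360
    qc_exclude: list[str] = field(default_factory=list)
    n_boot: int = 2000
    verbosity: int = 1
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be positive")
        if self.n_rays < 8:
            raise ValueError("n_rays must be at least 8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _configure_logging(verbosity: int) -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.DEBUG if verbosity > 1
                 else logging.INFO if verbosity else logging.WARNING)


def run_pipeline(config: RunConfig) -> TransmuralNormalsResults:
    """Simulate-or-load, analyse each subject, and write the report bundle."""
    import time

    import pandas as pd

    _configure_logging(config.verbosity)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if config.simulate:
        spec = CohortSpec(n_subjects=config.n_subjects, seed=config.seed,
                          **config.cohort_overrides)
        records = make_cohort(spec)
        log.info("simulated %d subjects (seed %d)", len(records), config.seed)
        if config.with_maps:
            remeasured = []
            for rec in records:
                maps, contours = make_subject_maps(rec)
                try:
                    new = subject_pipeline(
                        maps, contours, subject_id=rec.subject_id,
                        sex=rec.sex, age=rec.age,
                        hr_rest=rec.hr_rest, sbp_rest=rec.sbp_rest,
                        hr_stress=rec.hr_stress, sbp_stress=rec.sbp_stress,
                        target_spacing=config.target_spacing,
                        n_rays=config.n_rays)
                except Exception:
                    log.error("pipeline stage failed for subject %s",
                              rec.subject_id)
                    raise
                remeasured.append(new)
            records = remeasured
            log.info("re-measured %d subjects from rendered phantom maps",
                     len(records))
    else:
        if config.input_dir is None:
            raise ValueError("input_dir is required when simulate is false")
        records = []
        demo = pd.read_csv(Path(config.input_dir) / "subjects.csv")
        for _, row in demo.iterrows():
            sid = str(row["subject_id"])
            maps, contours = read_subject_dir(Path(config.input_dir) / sid)
            try:
                records.append(subject_pipeline(
                    maps, contours, subject_id=sid, sex=row["sex"],
                    age=row["age"], hr_rest=row["hr_rest"],
                    sbp_rest=row["sbp_rest"], hr_stress=row["hr_stress"],
                    sbp_stress=row["sbp_stress"],
                    target_spacing=config.target_spacing, n_rays=config.n_rays))
            except Exception:
                log.error("pipeline stage failed for subject %s", sid)
                raise

    for rec in records:
        if rec.subject_id in config.qc_exclude:
            rec.qc_excluded = True
    n_excl = sum(r.qc_excluded for r in records)
    if n_excl:
        log.info("excluding %d of %d subjects by QC flag",
                 n_excl, len(records))

    frame = cohort_to_frame(records)
    frame.to_csv(out_dir / "records.csv", index=False)
    results = TransmuralNormals(frame).fit(seed=config.seed,
                                           n_boot=config.n_boot)
    for name, table in results.tables.items():
        table.to_csv(out_dir / f"table_{name}.csv", index=False)
    (out_dir / "summary.txt").write_text(results.summary() + "\n")
    bundle = {
        "n_subjects": results.n_subjects,
        "n_excluded": results.n_excluded,
        "seed": config.seed,
        "normal_ranges": {
            m: list(results.normal_range(m))
            for m in ("MPR_ENDO", "MPR_EPI", "sGRAD", "rGRAD")
            if results._has(m)
        },
    }
    (out_dir / "report.json").write_text(json.dumps(bundle, indent=1))
    log.info("report bundle written to %s (%.1f s)", out_dir,
             time.perf_counter() - t0)
    return results
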