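"""End-to-end orchestration: single sample, NL/LS pair, and cohort runs.

A run executes calibrate -> classify (threshold or trained classifier) ->
coherence expansion (threshold mode) -> compartment geometry -> compartment
split -> cell labeling -> density report, logging every numeric parameter at
INFO. Outputs (CSV/JSON reports, masks) embed the config hash and package
version, so an identical config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .annotations import AnnotationSet, read_annotations
from .calibration import ScaleCalibration, calibrate_from_scale_bar
from .cells import CellSet, default_min_area_px, label_cells
from .density import DensityReport, PairedComparison, build_density_report, compare_pair
from .errors import PipelineError
from .geometry import (
    CompartmentSet,
    Polyline,
    build_epidermis_mask,
    expand_dermal_band,
    polyline_length_um,
)
from .images import CalibratedImage, read_image, write_mask_png
from .stain import (
    ColorRangeSpec,
    PixelClassifier,
    PositiveMask,
    apply_classifier,
    apply_mask_edits,
    coherence_expand,
    threshold_classify,
)

__all__ = ["RunConfig", "SampleResult", "CohortResult", "run_sample", "run_pair",
           "run_cohort", "dilution_t_test"]

logger = logging.getLogger("skinquant")


@dataclass
class RunConfig:
    """Everything one sample run needs. Exactly one classification mode is
    active: ``threshold`` (with a ColorRangeSpec) or ``classifier`` (with a
    trained PixelClassifier or a path to one)."""

    sample_id: str = "sample"
    image: CalibratedImage | None = None
    image_path: str | None = None
    annotations: AnnotationSet | None = None
    annotations_path: str | None = None
    pixels_per_um: float | None = None
    scale_bar_px: float | None = None
    scale_bar_um: float | None = None
    mode: str = "threshold"
    color_spec: ColorRangeSpec | None = None
    classifier: PixelClassifier | None = None
    classifier_path: str | None = None
    expansion_depth_um: float = 400.0
    coherence_radius_px: int = 2
    min_cell_area_px: int | None = None  # None -> 2 um-diameter disk at calibration
    max_cell_area_px: int | None = None
    connectivity: int = 8
    mask_edits: list = field(default_factory=list)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "classifier"):
            raise PipelineError(f"unknown classification mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        calib = doc.pop("calibration", {})
        if "pixels_per_um" in calib:
            kwargs["pixels_per_um"] = float(calib["pixels_per_um"])
        elif "scale_bar" in calib:
            kwargs["scale_bar_px"] = float(calib["scale_bar"]["px"])
            kwargs["scale_bar_um"] = float(calib["scale_bar"]["um"])
        spec = doc.pop("color_spec", None)
        if spec is not None:
            kwargs["color_spec"] = ColorRangeSpec(
                reference_colors=tuple(tuple(c) for c in spec["reference_colors"]),
                tolerance=float(spec.get("tolerance", 60.0)),
            )
        for key in (
            "sample_id", "image_path", "annotations_path", "mode", "classifier_path",
            "expansion_depth_um", "coherence_radius_px", "min_cell_area_px",
            "max_cell_area_px", "connectivity", "out_dir", "seed",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    def calibration(self) -> ScaleCalibration:
        if self.pixels_per_um is not None:
            return ScaleCalibration(self.pixels_per_um)
        if self.scale_bar_px is not None and self.scale_bar_um is not None:
            return calibrate_from_scale_bar(self.scale_bar_px, self.scale_bar_um)
        if self.image is not None:
            return self.image.calibration
        raise PipelineError(
            f"[{self.sample_id}] calibration: no pixels_per_um or scale bar supplied"
        )

    def hashable_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "out_dir":  # analysis parameters only, not output location
                continue
            v = getattr(self, f.name)
            if isinstance(v, (str, int, float, bool, type(None))):
                out[f.name] = v
            elif isinstance(v, ColorRangeSpec):
                out[f.name] = {"colors": v.reference_colors, "tolerance": v.tolerance}
            else:
                out[f.name] = None if v is None else type(v).__name__
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.hashable_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    report: DensityReport
    cells: CellSet
    compartments: CompartmentSet
    positive_mask: PositiveMask
    config: RunConfig
    config_hash: str


def _stage(sample_id: str, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{sample_id}] stage {name}: {exc}") from exc
            return False

    return _Ctx()


def run_sample(config: RunConfig) -> SampleResult:
    """Run the full quantification pipeline for one sample."""
    sid = config.sample_id
    chash = config.config_hash()
    with _stage(sid, "calibration"):
        calib = config.calibration()
    logger.info(
        "[%s] calibration=%.6g px/um depth=%g um coherence_radius=%d px mode=%s",
        sid, calib.pixels_per_um, config.expansion_depth_um,
        config.coherence_radius_px, config.mode,
    )
    with _stage(sid, "calibration_io"):
        image = config.image
        if image is None:
            if config.image_path is None:
                raise PipelineError(f"[{sid}] stage calibration_io: no image supplied")
            image = read_image(config.image_path, calib)
        annotations = config.annotations
        if annotations is None:
            if config.annotations_path is None:
                raise PipelineError(f"[{sid}] stage calibration_io: no annotations supplied")
            annotations = read_annotations(config.annotations_path)

    with _stage(sid, "stain_classification"):
        if config.mode == "threshold":
            if config.color_spec is None:
                raise PipelineError(
                    f"[{sid}] stage stain_classification: threshold mode needs a color spec"
                )
            mask = threshold_classify(image, config.color_spec)
            if config.coherence_radius_px > 0:
                mask = coherence_expand(mask, config.coherence_radius_px)
        else:
            clf = config.classifier
            if clf is None:
                if config.classifier_path is None:
                    raise PipelineError(
                        f"[{sid}] stage stain_classification: classifier mode needs a model"
                    )
                clf = PixelClassifier.load(config.classifier_path)
            mask = apply_classifier(image, clf)
        if config.mask_edits:
            mask = apply_mask_edits(mask, config.mask_edits)
        logger.debug("[%s] positive mask area = %d px", sid, mask.area_px)

    with _stage(sid, "roi_geometry"):
        epi_ann = annotations.first("epidermis")
        if epi_ann is None:
            raise PipelineError(
                f"[{sid}] stage roi_geometry: missing epidermis annotation"
            )
        epi_mask = build_epidermis_mask(epi_ann.geometry, image.shape)

        def _line(role):
            a = annotations.first(role)
            return None if a is None else Polyline.from_shapely(a.geometry)

        comp = CompartmentSet(
            epidermis_mask=epi_mask,
            left_boundary=_line("left_boundary"),
            right_boundary=_line("right_boundary"),
            apical_polyline=_line("apical_polyline"),
            expansion_depth_um=config.expansion_depth_um,
        )
        comp = expand_dermal_band(comp, calib)
        apical = comp.apical_polyline
        if apical is None:
            raise PipelineError(
                f"[{sid}] stage roi_geometry: missing apical polyline (epidermal length)"
            )
        length_um = polyline_length_um(apical, calib)
        logger.debug(
            "[%s] epidermis=%d px dermis=%d px length=%.1f um",
            sid, int(comp.epidermis_mask.sum()), int(comp.dermis_mask.sum()), length_um,
        )

    with _stage(sid, "cell_quantification"):
        min_area = config.min_cell_area_px
        if min_area is None:
            min_area = default_min_area_px(calib)
        cells = label_cells(
            mask,
            min_area_px=min_area,
            max_area_px=config.max_cell_area_px,
            connectivity=config.connectivity,
            calibration=calib,
            compartments=comp,
        )
        logger.info("[%s] min_cell_area=%d px -> %d cells", sid, min_area, len(cells))

    with _stage(sid, "density_metrics"):
        report = build_density_report(cells, comp, length_um, calib, sample_id=sid)

    result = SampleResult(
        report=report, cells=cells, compartments=comp, positive_mask=mask,
        config=config, config_hash=chash,
    )
    if config.out_dir:
        _write_sample_outputs(result)
    return result


def _write_sample_outputs(result: SampleResult) -> None:
    out = result.config.out_dir
    os.makedirs(out, exist_ok=True)
    os.makedirs(os.path.join(out, "masks"), exist_ok=True)
    frame = result.report.to_frame()
    frame.insert(0, "config_hash", result.config_hash)
    frame.insert(0, "skinquant_version", __version__)
    frame.to_csv(os.path.join(out, f"{result.report.sample_id}_report.csv"), index=False)
    payload = {
        "skinquant_version": __version__,
        "config_hash": result.config_hash,
        "report": frame.to_dict(orient="records"),
    }
    with open(os.path.join(out, f"{result.report.sample_id}_report.json"), "w") as fh:
        json.dump(payload, fh, indent=1)
    result.cells.to_csv(os.path.join(out, f"{result.report.sample_id}_cells.csv"))
    sid = result.report.sample_id
    write_mask_png(result.positive_mask.mask, os.path.join(out, "masks", f"{sid}_positive.png"))
    write_mask_png(result.compartments.epidermis_mask,
                   os.path.join(out, "masks", f"{sid}_epidermis.png"))
    write_mask_png(result.compartments.dermis_mask,
                   os.path.join(out, "masks", f"{sid}_dermis.png"))


def run_pair(nl_config: RunConfig, ls_config: RunConfig) -> PairedComparison:
    """Run both members of a paired NL/LS sample and compare them."""
    try:
        if not np.isclose(
            nl_config.calibration().pixels_per_um, ls_config.calibration().pixels_per_um
        ):
            logger.warning(
                "calibration mismatch between pair members (%s vs %s)",
                nl_config.sample_id, ls_config.sample_id,
            )
    except PipelineError:
        pass  # calibration errors surface in run_sample with their stage name
    nl = run_sample(nl_config)
    ls = run_sample(ls_config)
    return compare_pair(nl.report, ls.report)


def dilution_t_test(pairs: list[PairedComparison], compartment: str = "epidermis"):
    """Paired t-test of per-length vs per-area relative increases across
    NL/LS pairs — the cohort-level check that per-area normalization dilutes
    the apparent increase when the epidermis thickens."""
    from .agreement import paired_t_test

    per_length = [p.relative_increase("area_per_length", compartment) for p in pairs]
    per_area = [p.relative_increase("area_per_area", compartment) for p in pairs]
    return paired_t_test(per_length, per_area)


@dataclass
class CohortResult:
    reports_threshold: list[DensityReport]
    reports_classifier: list[DensityReport]
    bland_altman_table: object  # DataFrame, 6 strata
    bland_altman_results: dict
    density_regressions: dict  # (compartment, normalization) -> RegressionResult
    method_regressions: dict  # (compartment, metric) -> RegressionResult
    dilution_test: object | None = None


def run_cohort(
    threshold_configs: list[RunConfig],
    classifier_configs: list[RunConfig],
    pair_comparisons: list[PairedComparison] | None = None,
    out_dir: str | None = None,
) -> CohortResult:
    """Run a matched cohort through both pipelines and produce the full
    statistical layer: six Bland–Altman strata (classifier − threshold), six
    density regressions (stained-area density vs count density, per
    compartment and normalization), six method regressions (classifier vs
    threshold), and — when NL/LS pair comparisons are supplied — the paired
    dilution t-test."""
    from .agreement import AGREEMENT_STRATA, agreement_report, linear_fit

    if len(threshold_configs) != len(classifier_configs):
        raise PipelineError("cohort: the two pipelines need matched sample lists")
    if len(threshold_configs) < 3:
        raise PipelineError("cohort: need at least 3 samples for the regression layer")
    reports_thr = [run_sample(c).report for c in threshold_configs]
    reports_clf = [run_sample(c).report for c in classifier_configs]
    table, ba_results = agreement_report(reports_clf, reports_thr)

    from .errors import AgreementError

    def _fit(key_desc, x, y):
        try:
            return linear_fit(x, y)
        except AgreementError as exc:  # degenerate cohort (e.g. identical samples)
            logger.warning("cohort regression %s skipped: %s", key_desc, exc)
            return None

    density_regressions = {}
    for compartment in ("epidermis", "dermis", "total"):
        density_regressions[(compartment, "per_length")] = _fit(
            f"density/{compartment}/per_length",
            [r.metric("count_per_mm", compartment) for r in reports_clf],
            [r.metric("area_per_length", compartment) for r in reports_clf],
        )
        density_regressions[(compartment, "per_area")] = _fit(
            f"density/{compartment}/per_area",
            [r.metric("count_per_mm2", compartment) for r in reports_clf],
            [r.metric("area_per_area", compartment) for r in reports_clf],
        )
    method_regressions = {}
    for compartment, metric in AGREEMENT_STRATA:
        method_regressions[(compartment, metric)] = _fit(
            f"method/{compartment}/{metric}",
            [r.metric(metric, compartment) for r in reports_thr],
            [r.metric(metric, compartment) for r in reports_clf],
        )
    dilution = None
    if pair_comparisons is not None:
        if len(pair_comparisons) < 2:
            raise PipelineError("cohort: need at least 2 NL/LS pairs for the t-test")
        dilution = dilution_t_test(pair_comparisons)

    result = CohortResult(
        reports_threshold=reports_thr,
        reports_classifier=reports_clf,
        bland_altman_table=table,
        bland_altman_results=ba_results,
        density_regressions=density_regressions,
        method_regressions=method_regressions,
        dilution_test=dilution,
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "bland_altman.csv"), index=False)
        import pandas as pd

        pd.concat([r.to_frame() for r in reports_thr]).to_csv(
            os.path.join(out_dir, "densities_threshold.csv"), index=False
        )
        pd.concat([r.to_frame() for r in reports_clf]).to_csv(
            os.path.join(out_dir, "densities_classifier.csv"), index=False
        )
        reg_rows = [
            {"family": fam, "compartment": key[0], "stratum": key[1],
             "slope": res.slope, "intercept": res.intercept,
             "r_squared": res.r_squared, "n": res.n}
            for fam, regs in (
                ("density", density_regressions), ("method", method_regressions)
            )
            for key, res in regs.items()
            if res is not None
        ]
        pd.DataFrame(reg_rows).to_csv(os.path.join(out_dir, "regressions.csv"), index=False)
    return result
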