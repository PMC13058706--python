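"""End-to-end orchestration: mask -> segment -> features -> gating -> report.

Every run is driven by a :class:`RunConfig`, which is hashable (sha256 of
its canonical YAML) so every output file can carry the exact configuration
that produced it.  Identical config + inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import features as _features
from . import gating as _gating
from . import report as _report
from . import segment as _segment
from . import tissue as _tissue
from .gating import DEFAULT_GATES, GateSet, ThresholdSet
from .segment import LabelMask
from .stack import DEFAULT_CHANNELS, DEFAULT_PIXEL_SIZE_UM, ChannelStack
from .tissue import ExclusionRoi, TissueMask

logger = logging.getLogger("mifquant")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and slide id."""

    def __init__(self, stage: str, slide_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on slide {slide_id!r}: {cause}")
        self.stage = stage
        self.slide_id = slide_id
        self.__cause__ = cause


@dataclass
class MaskParams:
    af_channel: str = "AF"
    blur_sigma: float = 4.0
    method: str = "otsu"
    manual_threshold: float | None = None
    min_component_px: int = 500


@dataclass
class SegmentParams:
    dapi_channel: str = "DAPI"
    smooth_sigma: float = 1.0
    min_area_px: int = 20
    min_peak_distance_px: int = 5
    expand_radius_px: int = 2


@dataclass
class GatingParams:
    threshold_method: str = "gmm2"
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    af_method: str | None = None


@dataclass
class RunConfig:
    """Complete pipeline configuration.

    ``channel_map`` maps channel names to the fluorophore that carries them
    (documentation/provenance only; channel identity comes from the TIFF
    metadata).  ``denominator`` selects the total-cell rule for fractions:
    autofluorescence-passing cells (default) or all in-tissue cells.
    """

    channel_map: dict[str, str] = field(default_factory=lambda: {
        "DAPI": "DAPI", "AF": "CFP", "CD79a": "FITC", "CD38": "Rhodamine 6G",
        "Ki67": "Red 610", "CD19": "Cy5", "CD138": "CY7",
    })
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    mask: MaskParams = field(default_factory=MaskParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    gating: GatingParams = field(default_factory=GatingParams)
    gates: GateSet = field(default_factory=lambda: DEFAULT_GATES)
    denominator: str = "af_pass"
    seed: int = 0

    def validate(self) -> None:
        missing = [ch for ch in DEFAULT_CHANNELS if ch not in self.channel_map]
        if missing:
            raise ValueError(f"channel_map lacks channels: {missing}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.denominator not in ("af_pass", "all"):
            raise ValueError("denominator must be 'af_pass' or 'all'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gates"] = {
            "gates": {name: {"positive": sorted(p), "negative": sorted(n)}
                      for name, (p, n) in self.gates.gates.items()},
            "subfractions": [list(sf) for sf in self.gates.subfractions],
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "mask" in kwargs:
            kwargs["mask"] = MaskParams(**kwargs["mask"])
        if "segment" in kwargs:
            kwargs["segment"] = SegmentParams(**kwargs["segment"])
        if "gating" in kwargs:
            kwargs["gating"] = GatingParams(**kwargs["gating"])
        if "gates" in kwargs:
            g = kwargs["gates"]
            kwargs["gates"] = GateSet(
                gates={name: (frozenset(spec.get("positive", [])),
                              frozenset(spec.get("negative", [])))
                       for name, spec in g["gates"].items()},
                subfractions=[tuple(sf) for sf in g.get("subfractions", [])],
            )
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class SlideResult:
    slide_id: str
    tissue_mask: TissueMask
    labels: LabelMask
    cells: pd.DataFrame
    phenotypes: pd.DataFrame
    thresholds: ThresholdSet
    summary: _report.SlideSummary


def run_slide(config: RunConfig, stack: ChannelStack, slide_id: str,
              labels: LabelMask | None = None,
              rois: list[ExclusionRoi] | None = None,
              thresholds: ThresholdSet | None = None) -> SlideResult:
    """Run the full single-slide pipeline.

    ``labels`` bypasses the builtin segmenter (external instance masks);
    ``thresholds`` bypasses per-slide threshold fitting (cohort-shared
    cutoffs).
    """
    config.validate()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineError(name, slide_id, exc) from exc

    mask = _stage("tissue_mask", _tissue.compute_tissue_mask, stack,
                  af_channel=config.mask.af_channel,
                  blur_sigma=config.mask.blur_sigma,
                  method=config.mask.method,
                  manual_threshold=config.mask.manual_threshold,
                  min_component_px=config.mask.min_component_px)
    if rois:
        mask = _stage("apply_exclusions", _tissue.apply_exclusions, mask, rois)
    logger.info("[%s] tissue mask: %.4f mm2 (%d px)", slide_id,
                mask.area_mm2, int(mask.mask.sum()))

    if labels is None:
        nuclei = _stage("segment", _segment.segment_nuclei, stack,
                        dapi_channel=config.segment.dapi_channel,
                        smooth_sigma=config.segment.smooth_sigma,
                        min_area_px=config.segment.min_area_px,
                        min_peak_distance_px=config.segment.min_peak_distance_px)
        logger.info("[%s] builtin segmentation: %d nuclei", slide_id, nuclei.n_cells)
        if config.segment.expand_radius_px > 0:
            nuclei = _stage("expand_labels", _segment.expand_labels, nuclei,
                            config.segment.expand_radius_px)
        labels = nuclei
        compartment = f"nuclei expanded by {config.segment.expand_radius_px} px"
    else:
        logger.info("[%s] external label mask: %d cells (builtin segmenter "
                    "not invoked)", slide_id, labels.n_cells)
        compartment = "external"

    cells = _stage("features", _features.extract_cell_features, stack,
                   labels, mask, slide_id=slide_id)
    logger.info("[%s] features: %d cells (%d in tissue); MFI compartment: %s",
                slide_id, len(cells), int(cells["in_tissue"].sum()) if len(cells) else 0,
                compartment)

    if thresholds is None:
        markers = sorted(config.gates.markers)
        thresholds = _stage(
            "fit_thresholds", ThresholdSet.fit, cells, markers,
            method=config.gating.threshold_method,
            af_channel=config.mask.af_channel,
            af_method=config.gating.af_method,
            manual_values=config.gating.manual_thresholds,
            seed=config.seed,
        )
    phenotypes = _stage("classify", _gating.classify_cells, cells, thresholds,
                        config.gates)
    n_rej = int(phenotypes["af_rejected"].sum()) if len(phenotypes) else 0
    logger.info("[%s] gating: %d cells in, %d AF-rejected", slide_id,
                len(phenotypes), n_rej)

    summary = _stage("enumerate", _report.enumerate_slide, phenotypes,
                     mask.area_mm2, slide_id, gates=config.gates,
                     denominator=config.denominator)
    return SlideResult(slide_id, mask, labels, cells, phenotypes, thresholds, summary)


@dataclass
class PipelineResult:
    slides: dict[str, SlideResult]
    cohorts: dict[str, _report.CohortSummary]
    config_hash: str


def run_pipeline(config: RunConfig,
                 stacks: dict[str, ChannelStack],
                 labels: dict[str, LabelMask] | None = None,
                 rois: dict[str, list[ExclusionRoi]] | None = None,
                 cohort_of: dict[str, str] | None = None,
                 out_prefix=None) -> PipelineResult:
    """Run several slides and aggregate them into cohorts.

    ``cohort_of`` maps slide id -> cohort label (default: one cohort,
    "all").  When ``out_prefix`` is given, the report triplet is written
    with the config hash embedded.
    """
    config.validate()
    labels = labels or {}
    rois = rois or {}
    cohort_of = cohort_of or {sid: "all" for sid in stacks}

    results: dict[str, SlideResult] = {}
    for sid in stacks:
        results[sid] = run_slide(config, stacks[sid], sid,
                                 labels=labels.get(sid), rois=rois.get(sid))

    by_cohort: dict[str, list[_report.SlideSummary]] = {}
    for sid, res in results.items():
        by_cohort.setdefault(cohort_of.get(sid, "all"), []).append(res.summary)
    cohorts = {
        label: _report.aggregate_cohort(summaries, label)
        for label, summaries in by_cohort.items()
    }

    chash = config.config_hash()
    if out_prefix is not None:
        _report.write_report(list(cohorts.values()),
                             [r.summary for r in results.values()],
                             out_prefix, config_hash=chash)
    return PipelineResult(results, cohorts, chash)
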