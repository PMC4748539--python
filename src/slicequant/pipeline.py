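"""End-to-end orchestration: simulate/load -> quantify -> classify -> report.

`run_pipeline` drives the whole assay analysis from a single declarative
configuration and writes a joinable report bundle (per-field CSV,
per-slice CSV, per-tumor profile JSON, cohort counts, provenance record).
`simulate_and_recover` is the compact simulation loop used to study
threshold recovery: generate a cohort with known true thresholds, push it
through the quantification and threshold-calling stages, and return the
called thresholds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .dose_response import (
    CONTROL_DILUTION,
    DEFAULT_TESTED_DILUTIONS,
    ReadoutSeries,
    call_threshold,
    classify_tumor,
    cohort_counts,
    edu_effect_flags,
    tunel_effect_flags,
)
from .io import read_field, read_manifest, write_cohort
from .quantify import FieldQuantification, SliceSummary, quantify_field, summarize_slice
from .segmentation import SegmentationParams
from .simulate import (
    CohortField,
    FieldSpec,
    TumorSimProfile,
    fraction_summaries,
    generate_cohort,
)

__all__ = [
    "DoseResponseCriteria",
    "RunConfig",
    "run_pipeline",
    "simulate_and_recover",
    "quantify_manifest",
    "summaries_by_slice",
    "profile_cohort",
]

logger = logging.getLogger("slicequant")


@dataclass
class DoseResponseCriteria:
    """Numeric cut-offs of the threshold-calling stage (all configurable)."""

    edu_criterion_fraction: float = 0.5
    tunel_k: float = 1.5
    sensitive_min: int = 7
    resistant_max: int = 2


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    output_dir: str = "slicequant_out"
    master_seed: int = 0
    log_level: str = "INFO"
    manifest: str | None = None
    channel_map: dict[str, int] | None = None
    pixel_size: float | None = None
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    criteria: DoseResponseCriteria = dc_field(default_factory=DoseResponseCriteria)
    simulate: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        crit = DoseResponseCriteria(**raw.pop("dose_response", {}))
        return cls(segmentation=seg, criteria=crit, **raw)


def quantify_manifest(
    manifest: pd.DataFrame,
    params: SegmentationParams,
    channel_map: dict[str, int] | None = None,
    pixel_size: float | None = None,
) -> list[FieldQuantification]:
    """Quantify every field listed in a cohort manifest."""
    out: list[FieldQuantification] = []
    for row in manifest.itertuples():
        try:
            img = read_field(row.field_path, channel_map, pixel_size)
            q = quantify_field(img, params)
        except (OSError, ValueError) as exc:
            logger.error("field %s failed: %s", row.field_path, exc)
            continue
        q.tumor_id = str(row.tumor_id)
        q.day = int(row.day)
        q.dilution = int(row.dilution)
        out.append(q)
    return out


def summaries_by_slice(
    quants: Iterable[FieldQuantification],
) -> dict[tuple[str, int | None, int | None], SliceSummary]:
    """Group field records by (tumor, day, dilution) and summarize each slice."""
    groups: dict[tuple[str, int | None, int | None], list[FieldQuantification]] = {}
    for q in quants:
        groups.setdefault((q.tumor_id, q.day, q.dilution), []).append(q)
    out = {}
    for key, fields in groups.items():
        try:
            out[key] = summarize_slice(fields, *key)
        except ValueError as exc:
            logger.error("slice %s skipped: %s", key, exc)
    return out


def profile_cohort(
    summaries: dict[tuple[str, int | None, int | None], SliceSummary],
    criteria: DoseResponseCriteria | None = None,
):
    """Call per-tumor thresholds and classes from per-slice summaries.

    Requires the untreated control (dilution 11) per tumor; tumors whose
    summaries cover only the control are skipped with a notice. Returns a
    list of response profiles covering the ``edu`` and ``tunel`` readouts.
    """
    criteria = criteria or DoseResponseCriteria()
    by_tumor: dict[str, dict[int, SliceSummary]] = {}
    for (tumor, _day, dilution), s in summaries.items():
        if dilution is None:
            continue
        by_tumor.setdefault(tumor, {})[dilution] = s
    profiles = []
    for tumor, by_dil in sorted(by_tumor.items()):
        tested = sorted(d for d in by_dil if d != CONTROL_DILUTION)
        if CONTROL_DILUTION not in by_dil or not tested:
            logger.info(
                "tumor %s: no treated dilutions with control; threshold "
                "calling skipped",
                tumor,
            )
            continue
        thresholds: dict[str, int | None] = {}
        edu_series = ReadoutSeries("edu", summaries=by_dil, tumor_id=tumor)
        thresholds["edu"] = call_threshold(
            edu_effect_flags(edu_series, criteria.edu_criterion_fraction)
        )
        if by_dil[CONTROL_DILUTION].tunel_pct_median is not None:
            tunel_series = ReadoutSeries("tunel", summaries=by_dil, tumor_id=tumor)
            thresholds["tunel"] = call_threshold(
                tunel_effect_flags(tunel_series, criteria.tunel_k)
            )
        profiles.append(
            classify_tumor(
                tumor, thresholds, criteria.sensitive_min, criteria.resistant_max
            )
        )
    return profiles


def _simulation_from_config(cfg: dict[str, Any], master_seed: int):
    spec_kw = dict(cfg.get("field", {}))
    spec_kw.setdefault("seed", master_seed)
    spec = FieldSpec(**spec_kw)
    profiles = [TumorSimProfile(**t) for t in cfg["tumors"]]
    dilutions = list(cfg.get("dilutions", list(DEFAULT_TESTED_DILUTIONS) + [CONTROL_DILUTION]))
    n_fields = int(cfg.get("n_fields_per_slice", 10))
    day = int(cfg.get("day", 3))
    return profiles, dilutions, n_fields, spec, day


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full pipeline and write the report bundle.

    Stages: (optional) cohort simulation to TIFF + manifest; per-field
    quantification; per-slice summaries; per-tumor threshold calling and
    sensitivity classification; cohort histogram; provenance record. The
    run is deterministic given identical inputs and configuration.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest_path = config.manifest
    if config.simulate is not None:
        profiles_sim, dilutions, n_fields, spec, day = _simulation_from_config(
            config.simulate, config.master_seed
        )
        records = generate_cohort(
            profiles_sim, dilutions, n_fields, spec, day=day, render=True
        )
        manifest_path = str(write_cohort(records, outdir / "fields"))
        logger.info("simulated %d fields -> %s", len(records), manifest_path)
    if manifest_path is None:
        raise ValueError("config provides neither a manifest nor a simulation")

    manifest = read_manifest(manifest_path)
    quants = quantify_manifest(
        manifest, config.segmentation, config.channel_map, config.pixel_size
    )
    fields_df = pd.DataFrame(
        [
            {
                "tumor_id": q.tumor_id,
                "day": q.day,
                "dilution": q.dilution,
                "field_id": q.field_id,
                "keratin_area_px": q.keratin_area_px,
                "keratin_area_um2": q.keratin_area_um2,
                "edu_count": q.edu_count,
                "proliferation_index": q.proliferation_index,
                "tunel_pct": q.tunel_pct,
                "flags": ";".join(q.flags),
            }
            for q in quants
        ]
    )
    fields_csv = outdir / "fields.csv"
    fields_df.to_csv(fields_csv, index=False, float_format="%.6g")

    summaries = summaries_by_slice(quants)
    slices_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries.values()])
    slices_csv = outdir / "slices.csv"
    slices_df.to_csv(slices_csv, index=False, float_format="%.6g")

    profiles = profile_cohort(summaries, config.criteria)
    profiles_json = outdir / "profiles.json"
    profiles_json.write_text(
        json.dumps([dataclasses.asdict(p) for p in profiles], indent=2)
    )
    report: dict[str, Any] = {
        "n_fields": len(quants),
        "n_slices": len(summaries),
        "profiles": {p.tumor_id: p.thresholds for p in profiles},
    }
    if profiles:
        counts: dict[str, Any] = {}
        for readout in sorted({r for p in profiles for r in p.thresholds}):
            hist, missing = cohort_counts(profiles, readout)
            counts[readout] = {"counts": hist, "missing": missing}
        (outdir / "cohort_counts.json").write_text(json.dumps(counts, indent=2))
        report["cohort_counts"] = counts

    provenance = {
        "slicequant_version": __version__,
        "master_seed": config.master_seed,
        "segmentation": dataclasses.asdict(config.segmentation),
        "criteria": dataclasses.asdict(config.criteria),
        "manifest": str(manifest_path),
        "simulate": config.simulate,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    report["output_dir"] = str(outdir)
    return report


def simulate_and_recover(
    profiles: Sequence[TumorSimProfile],
    dilutions: Iterable[int] | None = None,
    n_fields_per_slice: int = 10,
    spec: FieldSpec | None = None,
    params: SegmentationParams | None = None,
    criteria: DoseResponseCriteria | None = None,
    readout: str = "edu",
    render: bool = True,
) -> dict[str, int | None]:
    """Simulate a cohort and return the threshold called for each tumor.

    The parameter-recovery loop: generate fields (or, with
    ``render=False``, realized fractions only) for every tumor x dilution,
    quantify and summarize each slice, apply the effect criterion for the
    chosen readout, and call thresholds. The untreated control is added to
    ``dilutions`` if absent.
    """
    criteria = criteria or DoseResponseCriteria()
    params = params or SegmentationParams()
    dilutions = list(dilutions) if dilutions is not None else list(DEFAULT_TESTED_DILUTIONS)
    if CONTROL_DILUTION not in dilutions:
        dilutions.append(CONTROL_DILUTION)
    records = generate_cohort(
        profiles, dilutions, n_fields_per_slice, spec, render=render
    )
    if render:
        summaries: dict[tuple[str, int], SliceSummary] = {}
        by_slice: dict[tuple[str, int], list[CohortField]] = {}
        for rec in records:
            by_slice.setdefault((rec.tumor_id, rec.dilution), []).append(rec)
        for (tumor, dilution), group in by_slice.items():
            quants = [quantify_field(r.image, params) for r in group]
            summaries[(tumor, dilution)] = summarize_slice(
                quants, tumor_id=tumor, dilution=dilution
            )
    else:
        summaries = fraction_summaries(records)

    out: dict[str, int | None] = {}
    for prof in profiles:
        by_dil = {d: s for (t, d), s in summaries.items() if t == prof.tumor_id}
        series = ReadoutSeries(readout, summaries=by_dil, tumor_id=prof.tumor_id)
        if readout == "edu":
            flags = edu_effect_flags(series, criteria.edu_criterion_fraction)
        elif readout == "tunel":
            flags = tunel_effect_flags(series, criteria.tunel_k)
        else:
            raise ValueError(f"readout must be 'edu' or 'tunel', got {readout!r}")
        out[prof.tumor_id] = call_threshold(flags)
    return out
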