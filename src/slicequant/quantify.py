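"""Per-field proliferation/death metrics and per-slice summaries.

The assay's proliferation readout is the number of EdU-positive cells per
cytokeratin-positive tumor area, which confines the measurement to
carcinoma tissue and ignores stroma and infiltrating lymphocytes. Field-
to-field heterogeneity within a slice is handled by imaging multiple
random fields and reporting the median with the interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import (
    ImageField,
    NoEdgesWarning,
    SegmentationParams,
    count_edu,
    keratin_area,
    tunel_fraction,
)

__all__ = [
    "FieldQuantification",
    "SliceSummary",
    "quantify_field",
    "summarize_slice",
    "longitudinal_table",
]

#: proliferation index reference area, μm² (index = cells per 10^4 μm²)
INDEX_REF_AREA_UM2 = 1.0e4

NO_TISSUE_FLAG = "no tumor tissue in field"
NO_NUCLEI_FLAG = "no nuclei detected"


@dataclass
class FieldQuantification:
    """Quantification record for one microscopy field.

    ``proliferation_index`` (EdU-positive cells per 10^4 μm² of keratin-
    positive area) is ``None`` when the field contains no detectable tumor
    tissue; such records carry the flag ``"no tumor tissue in field"`` and
    are excluded (and counted) by :func:`summarize_slice`.
    """

    field_id: str
    keratin_area_px: int
    keratin_area_um2: float
    edu_count: int
    proliferation_index: float | None
    tunel_pct: float | None = None
    tumor_id: str = ""
    day: int | None = None
    dilution: int | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return NO_TISSUE_FLAG in self.flags


@dataclass
class SliceSummary:
    """Median/IQR summary of the fields imaged on one slice."""

    tumor_id: str = ""
    day: int | None = None
    dilution: int | None = None
    n_fields: int = 0
    n_flagged: int = 0
    proliferation_index_median: float | None = None
    proliferation_index_q1: float | None = None
    proliferation_index_q3: float | None = None
    proliferation_index_iqr: float | None = None
    tunel_pct_median: float | None = None
    tunel_pct_q1: float | None = None
    tunel_pct_q3: float | None = None
    tunel_pct_iqr: float | None = None


def quantify_field(
    img: ImageField,
    params: SegmentationParams | None = None,
) -> FieldQuantification:
    """Quantify one field: keratin area, EdU count, index, TUNEL fraction.

    Requires the ``keratin`` and ``edu`` channels; when ``tunel`` and
    ``dapi`` are both present the TUNEL-positive DAPI-pixel percentage is
    computed as well, otherwise it is left absent.

    The keratin-positive area is converted to μm² with the field's pixel
    size (``area_um2 = area_px * pixel_size**2``) and the proliferation
    index is ``edu_count / area_um2 * 1e4``. A field without detectable
    keratin yields a flagged record with an undefined index rather than an
    error, so sparse fields do not abort a slice.
    """
    params = params or SegmentationParams()
    for required in ("keratin", "edu"):
        if required not in img.channels:
            raise ValueError(f"field {img.field_id!r} lacks {required!r} channel")
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NoEdgesWarning)
        _, area_px = keratin_area(img.normalized("keratin"), params)
    edu_n, _ = count_edu(img.normalized("edu"), params)
    area_um2 = area_px * img.pixel_size**2
    if area_px > 0:
        index = edu_n / area_um2 * INDEX_REF_AREA_UM2
    else:
        index = None
        flags.append(NO_TISSUE_FLAG)

    tunel_pct: float | None = None
    if "tunel" in img.channels and "dapi" in img.channels:
        try:
            tunel_pct = tunel_fraction(
                img.normalized("tunel"), img.normalized("dapi")
            )
        except ValueError:
            flags.append(NO_NUCLEI_FLAG)

    return FieldQuantification(
        field_id=img.field_id,
        keratin_area_px=area_px,
        keratin_area_um2=area_um2,
        edu_count=edu_n,
        proliferation_index=index,
        tunel_pct=tunel_pct,
        flags=flags,
    )


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(q1), float(med), float(q3)


def summarize_slice(
    quants: Iterable[FieldQuantification],
    tumor_id: str = "",
    day: int | None = None,
    dilution: int | None = None,
) -> SliceSummary:
    """Median and interquartile range over the fields of one slice.

    Fields flagged "no tumor tissue" are excluded from the proliferation
    summary and reported in ``n_flagged``; fields without a TUNEL value
    are simply absent from the TUNEL summary. Quartiles use the linear-
    interpolation convention. Raises if every field is flagged
    ("slice unquantifiable").
    """
    quants = list(quants)
    if not quants:
        raise ValueError("no fields to summarize")
    ok = [q for q in quants if not q.flagged]
    if not ok:
        raise ValueError("slice unquantifiable: all fields flagged")
    summary = SliceSummary(
        tumor_id=tumor_id or quants[0].tumor_id,
        day=day if day is not None else quants[0].day,
        dilution=dilution if dilution is not None else quants[0].dilution,
        n_fields=len(quants),
        n_flagged=len(quants) - len(ok),
    )
    pi = [q.proliferation_index for q in ok if q.proliferation_index is not None]
    if pi:
        q1, med, q3 = _quartiles(pi)
        summary.proliferation_index_median = med
        summary.proliferation_index_q1 = q1
        summary.proliferation_index_q3 = q3
        summary.proliferation_index_iqr = q3 - q1
    tp = [q.tunel_pct for q in quants if q.tunel_pct is not None]
    if tp:
        q1, med, q3 = _quartiles(tp)
        summary.tunel_pct_median = med
        summary.tunel_pct_q1 = q1
        summary.tunel_pct_q3 = q3
        summary.tunel_pct_iqr = q3 - q1
    return summary


def longitudinal_table(quants: Iterable[FieldQuantification]) -> pd.DataFrame:
    """Tidy per-tumor, per-day table of median + IQR across pooled fields.

    Groups field-level records by ``(tumor_id, day)`` — duplicated slices
    at one day pool their fields into a single row — and reports the
    median, Q1, Q3 and IQR of the proliferation index and TUNEL
    percentage. An empty input yields an empty table.
    """
    rows = []
    by_key: dict[tuple[str, int | None], list[FieldQuantification]] = {}
    for q in quants:
        by_key.setdefault((q.tumor_id, q.day), []).append(q)
    for (tumor, day), group in sorted(
        by_key.items(), key=lambda kv: (kv[0][0], kv[0][1] if kv[0][1] is not None else -1)
    ):
        row: dict = {"tumor_id": tumor, "day": day, "n_fields": len(group)}
        pi = [q.proliferation_index for q in group if q.proliferation_index is not None]
        if pi:
            q1, med, q3 = _quartiles(pi)
            row.update(
                proliferation_index_median=med,
                proliferation_index_q1=q1,
                proliferation_index_q3=q3,
                proliferation_index_iqr=q3 - q1,
            )
        tp = [q.tunel_pct for q in group if q.tunel_pct is not None]
        if tp:
            q1, med, q3 = _quartiles(tp)
            row.update(
                tunel_pct_median=med,
                tunel_pct_q1=q1,
                tunel_pct_q3=q3,
                tunel_pct_iqr=q3 - q1,
            )
        rows.append(row)
    columns = [
        "tumor_id",
        "day",
        "n_fields",
        "proliferation_index_median",
        "proliferation_index_q1",
        "proliferation_index_q3",
        "proliferation_index_iqr",
        "tunel_pct_median",
        "tunel_pct_q1",
        "tunel_pct_q3",
        "tunel_pct_iqr",
    ]
    return pd.DataFrame(rows, columns=columns)
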