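"""FAC dilution-series design, threshold calling and sensitivity classes.

The ex vivo assay treats tumor slices with the FAC combination
(5-fluorouracil, doxorubicin, and 4-hydroperoxycyclophosphamide standing
in for cyclophosphamide) at a ladder of eleven dilutions: index 1 is the
highest concentration, index 10 the lowest, and index 11 the untreated
control. The three drugs are always mixed at the clinical molar ratio
5-FU : doxorubicin : 4-HC = 46 : 1 : 22, and consecutive dilutions step
down by the repeating pattern /2, /2, /2.5, i.e. one decade every three
steps.

For each tumor and readout (manual nuclear-morphology calls, EdU
proliferation inhibition, TUNEL cell-death induction) a *threshold
dilution* is called: the most dilute concentration at which the effect
criterion still holds, requiring an unbroken run of affected dilutions
from the strongest tested one. A larger threshold index means a more
sensitive tumor. Tumors are classed sensitive (threshold at dilution 7 or
weaker drug), resistant (effect only at dilution 2/1 or never), or
intermediate.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .quantify import SliceSummary

__all__ = [
    "MOLAR_RATIO",
    "DilutionSeries",
    "ReadoutSeries",
    "TumorResponseProfile",
    "build_dilution_table",
    "edu_effect_flags",
    "tunel_effect_flags",
    "call_threshold",
    "classify_threshold",
    "classify_tumor",
    "cohort_counts",
    "NonMonotoneFlagsWarning",
]

#: 5-FU : doxorubicin : 4-HC molar ratio used for every dilution
MOLAR_RATIO = (46.0, 1.0, 22.0)

#: dilution factors applied successively from index 1 (one decade per 3 steps)
_STEP_CYCLE = (2.0, 2.0, 2.5)

CONTROL_DILUTION = 11

#: dilutions tested by default in the assay (plus the untreated control)
DEFAULT_TESTED_DILUTIONS = (2, 3, 4, 5, 6, 7)


class NonMonotoneFlagsWarning(UserWarning):
    """Effect flags are non-contiguous across the dilution ladder."""


@dataclass(frozen=True)
class DilutionSeries:
    """The 11-row FAC concentration ladder.

    ``table`` has columns ``dilution``, ``c_5fu_um``, ``c_dox_um``,
    ``c_4hc_um``; row 11 is the all-zero untreated control.
    """

    table: pd.DataFrame
    molar_ratio: tuple[float, float, float] = MOLAR_RATIO

    def __post_init__(self) -> None:
        t = self.table
        expected_cols = ["dilution", "c_5fu_um", "c_dox_um", "c_4hc_um"]
        if list(t.columns) != expected_cols:
            raise ValueError(f"table must have columns {expected_cols}")
        if list(t["dilution"]) != list(range(1, 12)):
            raise ValueError("table must have dilutions 1..11 in order")
        conc = t.set_index("dilution")
        if not (conc.loc[CONTROL_DILUTION] == 0).all():
            raise ValueError("dilution 11 (control) must be all-zero")
        treated = conc.loc[1:10]
        if not (treated.diff().dropna() < 0).all().all():
            raise ValueError("concentrations must strictly decrease in d over 1..10")

    def concentration(self, dilution: int, drug: str = "dox") -> float:
        """Concentration in μM of one component at a dilution index."""
        col = {"5fu": "c_5fu_um", "dox": "c_dox_um", "4hc": "c_4hc_um"}[drug]
        row = self.table.loc[self.table["dilution"] == dilution, col]
        if row.empty:
            raise ValueError(f"dilution {dilution} not in series")
        return float(row.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _dilution_factors(n: int = 10) -> np.ndarray:
    factors = np.ones(n)
    for i in range(1, n):
        factors[i] = factors[i - 1] / _STEP_CYCLE[(i - 1) % 3]
    return factors


def build_dilution_table(
    top_c_dox: float = 10.0,
    ratio: tuple[float, float, float] = MOLAR_RATIO,
) -> DilutionSeries:
    """Build the FAC dilution ladder from the top doxorubicin concentration.

    With the defaults (``top_c_dox=10`` μM, ratio 46:1:22) this reproduces
    the assay's printed dose table exactly: doxorubicin runs 10, 5, 2.5,
    1, 0.5, 0.25, 0.1, 0.05, 0.025, 0.01 μM over dilutions 1..10, with
    5-FU and 4-HC at 46x and 22x those values, and dilution 11 all zero.
    """
    if top_c_dox <= 0:
        raise ValueError("top_c_dox must be positive")
    if any(r <= 0 for r in ratio):
        raise ValueError("ratio components must be positive")
    dox = top_c_dox * _dilution_factors(10)
    r5fu, rdox, r4hc = ratio
    table = pd.DataFrame(
        {
            "dilution": np.arange(1, 12),
            "c_5fu_um": np.append(dox * r5fu / rdox, 0.0),
            "c_dox_um": np.append(dox, 0.0),
            "c_4hc_um": np.append(dox * r4hc / rdox, 0.0),
        }
    )
    return DilutionSeries(table=table, molar_ratio=ratio)


@dataclass
class ReadoutSeries:
    """Per-dilution measurements of one readout for one tumor.

    For the ``edu`` and ``tunel`` readouts, ``summaries`` maps dilution
    index -> :class:`~slicequant.quantify.SliceSummary` and must include
    the untreated control (dilution 11). For the ``morphology`` readout,
    ``calls`` maps dilution index -> manual binary call (aberrant nuclear
    morphology present), as scored by a pathologist on H&E sections.
    """

    readout: str
    summaries: dict[int, SliceSummary] = field(default_factory=dict)
    calls: dict[int, bool] = field(default_factory=dict)
    tumor_id: str = ""

    def __post_init__(self) -> None:
        if self.readout not in ("morphology", "edu", "tunel"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.readout in ("edu", "tunel") and not self.summaries:
            raise ValueError(f"{self.readout} readout requires summaries")

    @property
    def control(self) -> SliceSummary:
        if CONTROL_DILUTION not in self.summaries:
            raise ValueError("missing control: no summary for dilution 11")
        return self.summaries[CONTROL_DILUTION]

    def tested_dilutions(self) -> list[int]:
        keys = self.calls if self.readout == "morphology" else self.summaries
        return sorted(d for d in keys if d != CONTROL_DILUTION)


def edu_effect_flags(
    series: ReadoutSeries, criterion_fraction: float = 0.5
) -> dict[int, bool]:
    """Flag dilutions at which proliferation is inhibited.

    A dilution is flagged when its median proliferation index falls below
    ``criterion_fraction`` times the untreated control's median.
    """
    if series.readout != "edu":
        raise ValueError("edu_effect_flags requires an 'edu' readout series")
    ctrl = series.control.proliferation_index_median
    if ctrl is None:
        raise ValueError("control slice has no proliferation index")
    cut = criterion_fraction * ctrl
    flags: dict[int, bool] = {}
    for d in series.tested_dilutions():
        med = series.summaries[d].proliferation_index_median
        if med is None:
            raise ValueError(f"dilution {d} has no proliferation index")
        flags[d] = med < cut
    return flags


def tunel_effect_flags(series: ReadoutSeries, k: float = 1.5) -> dict[int, bool]:
    """Flag dilutions at which cell death is induced.

    A dilution is flagged when its median TUNEL-positive pixel percentage
    exceeds the control median by more than ``k`` times the control's
    interquartile range (the assay's field-to-field dispersion measure).
    """
    if series.readout != "tunel":
        raise ValueError("tunel_effect_flags requires a 'tunel' readout series")
    ctrl = series.control
    if ctrl.tunel_pct_median is None or ctrl.tunel_pct_iqr is None:
        raise ValueError("control slice has no TUNEL summary")
    cut = ctrl.tunel_pct_median + k * ctrl.tunel_pct_iqr
    flags: dict[int, bool] = {}
    for d in series.tested_dilutions():
        med = series.summaries[d].tunel_pct_median
        if med is None:
            raise ValueError(f"dilution {d} has no TUNEL summary")
        flags[d] = med > cut
    return flags


def call_threshold(flags: Mapping[int, bool]) -> int | None:
    """Call the threshold dilution from per-dilution effect flags.

    The threshold is the largest dilution index (i.e. the most dilute
    concentration) reachable from the strongest tested dilution through an
    unbroken run of flagged dilutions. ``None`` if the strongest tested
    dilution is not flagged (no effect). Isolated flags at weaker
    dilutions beyond a gap are ignored with a
    :class:`NonMonotoneFlagsWarning`.
    """
    if not flags:
        raise ValueError("empty flag set")
    tested = sorted(flags)  # ascending index = strongest concentration first
    threshold: int | None = None
    broken = False
    stray = False
    for d in tested:
        if flags[d]:
            if broken:
                stray = True
            else:
                threshold = d
        else:
            broken = True
    if stray:
        warnings.warn(
            "non-monotone effect flags: isolated flags at weaker dilutions "
            "were ignored",
            NonMonotoneFlagsWarning,
            stacklevel=2,
        )
    return threshold


def classify_threshold(
    threshold: int | None,
    sensitive_min: int = 7,
    resistant_max: int = 2,
) -> str:
    """Map a threshold dilution to a sensitivity class.

    Sensitive when the effect persists at dilution ``sensitive_min`` or
    weaker (threshold >= 7 by default); resistant when the effect appears
    only at dilution ``resistant_max`` or stronger, or never (threshold
    <= 2 or ``None``); otherwise intermediate.
    """
    if threshold is None or threshold <= resistant_max:
        return "resistant"
    if threshold >= sensitive_min:
        return "sensitive"
    return "intermediate"


@dataclass
class TumorResponseProfile:
    """Per-tumor threshold dilution and response class for each readout."""

    tumor_id: str
    thresholds: dict[str, int | None]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classes:
            self.classes = {
                r: classify_threshold(t) for r, t in self.thresholds.items()
            }


def classify_tumor(
    tumor_id: str,
    thresholds: Mapping[str, int | None],
    sensitive_min: int = 7,
    resistant_max: int = 2,
) -> TumorResponseProfile:
    """Build a response profile from per-readout threshold dilutions."""
    th = dict(thresholds)
    classes = {
        r: classify_threshold(t, sensitive_min, resistant_max)
        for r, t in th.items()
    }
    return TumorResponseProfile(tumor_id=tumor_id, thresholds=th, classes=classes)


def cohort_counts(
    profiles: Iterable[TumorResponseProfile], readout: str
) -> tuple[dict[int, int], int]:
    """Histogram of threshold dilutions across a cohort for one readout.

    Returns ``(counts, n_missing)`` where ``counts`` maps threshold
    dilution -> number of tumors and ``n_missing`` counts tumors without a
    threshold for this readout (never observed, or not measured).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty cohort")
    counts: Counter[int] = Counter()
    missing = 0
    for p in profiles:
        t = p.thresholds.get(readout)
        if t is None:
            missing += 1
        else:
            counts[int(t)] += 1
    return dict(sorted(counts.items())), missing
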