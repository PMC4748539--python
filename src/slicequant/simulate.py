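"""Synthetic multi-channel microscopy fields with known ground truth.

No image data were deposited with the original assay, so this module
stands in for the microscope: it draws fields that carry the statistical
structure the quantification operators assume — well-separated nuclei
(DAPI), a smooth simply-connected keratin-positive tumor region, an
EdU-positive nuclear subset concentrated in the keratin region
(proliferating cells are epithelial), a TUNEL-positive subset, additive
Gaussian noise — together with the exact ground truth for every object.

Dose response across the FAC dilution ladder is modelled per simulated
tumor as a four-parameter logistic in log doxorubicin concentration whose
midpoint sits at the geometric mean of the tumor's threshold dilution and
the next weaker one: the labelled threshold is therefore the weakest
dilution with a supra-criterion effect, which is what the downstream
threshold caller recovers. Field-to-field heterogeneity is modelled by
beta-distributed realized fractions around the dose-effect mean.

Determinism is a contract: identical spec + seed give bit-identical
rasters, and cohorts derive one sub-seed per field from the master seed
(recorded on each record).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.ndimage as ndi

from .dose_response import _STEP_CYCLE, CONTROL_DILUTION, DilutionSeries, build_dilution_table
from .quantify import SliceSummary
from .segmentation import CHANNEL_ORDER, ImageField

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "TumorSimProfile",
    "CohortField",
    "generate_field",
    "dose_effect_model",
    "generate_cohort",
    "fraction_summaries",
]


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic field.

    Intensity levels are on the raw integer scale of ``bit_depth``;
    ``channels`` selects which of dapi/keratin/edu/tunel to render.
    """

    width: int = 512
    height: int = 512
    pixel_size: float = 0.7
    n_nuclei: int = 60
    nucleus_radius_range: tuple[float, float] = (3.0, 5.0)
    edu_fraction: float = 0.15
    tunel_fraction: float = 0.08
    keratin_coverage: float = 0.5
    background_level: float = 1000.0
    foreground_level: float = 45000.0
    noise_sd: float = 500.0
    bit_depth: int = 16
    channels: tuple[str, ...] = CHANNEL_ORDER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width/height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus_radius_range must satisfy 0 < min <= max")
        for name in ("edu_fraction", "tunel_fraction", "keratin_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        unknown = set(self.channels) - set(CHANNEL_ORDER)
        if unknown:
            raise ValueError(f"channels contains unknown names: {sorted(unknown)}")

    @property
    def min_center_separation(self) -> float:
        """Generator guarantee: nucleus centers are at least this far apart.

        ``2 * max_radius + 3`` px, so rendered nuclei never touch and
        object counts have an exact correctness oracle. A geometric
        guarantee of the generator, not a biological claim.
        """
        return 2.0 * self.nucleus_radius_range[1] + 3.0


@dataclass
class GroundTruth:
    """Exact truth for one synthetic field."""

    nucleus_centers: np.ndarray  # (n, 2) row/col
    nucleus_radii: np.ndarray  # (n,)
    nucleus_mask: np.ndarray  # bool, field shape
    keratin_mask: np.ndarray  # bool, field shape
    edu_members: np.ndarray  # indices into nucleus arrays
    tunel_members: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_centers)

    def edu_in_keratin(self) -> int:
        """EdU-positive nuclei whose centers lie in the keratin region."""
        if len(self.edu_members) == 0:
            return 0
        centers = self.nucleus_centers[self.edu_members]
        return int(self.keratin_mask[centers[:, 0], centers[:, 1]].sum())


@dataclass(frozen=True)
class TumorSimProfile:
    """Dose-response parameters of one simulated tumor.

    ``true_threshold`` is the dilution index at which the tumor's response
    switches (``None`` for a fully unresponsive tumor); ``hill_slope``
    controls how sharply the logistic switches between adjacent 2-2.5x
    dilution steps; ``heterogeneity_sd`` is the standard deviation of the
    per-field realized fractions around the dose-effect mean.
    """

    tumor_id: str
    true_threshold: int | None = None
    baseline_edu_fraction: float = 0.15
    baseline_tunel_fraction: float = 0.08
    heterogeneity_sd: float = 0.03
    hill_slope: float = 12.0
    max_tunel_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.true_threshold is not None and not 1 <= self.true_threshold <= 10:
            raise ValueError("true_threshold must be in 1..10 or None")
        for name in ("baseline_edu_fraction", "baseline_tunel_fraction", "max_tunel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.max_tunel_fraction < self.baseline_tunel_fraction:
            raise ValueError("max_tunel_fraction must be >= baseline_tunel_fraction")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")


def _keratin_mask(rng: np.random.Generator, spec: FieldSpec) -> np.ndarray:
    shape = (spec.height, spec.width)
    if spec.keratin_coverage <= 0:
        return np.zeros(shape, dtype=bool)
    if spec.keratin_coverage >= 1:
        return np.ones(shape, dtype=bool)
    # smooth Gaussian random field thresholded at the coverage quantile;
    # holes are filled so the true region is simply connected, and a
    # background margin keeps blob contours closed inside the frame so
    # edge-based area detection has a well-posed truth (coverage is
    # therefore nominal, realized slightly below the requested value)
    g = ndi.gaussian_filter(
        rng.standard_normal(shape), sigma=min(shape) / 8.0, mode="reflect"
    )
    mask = g > np.quantile(g, 1.0 - spec.keratin_coverage)
    mask = ndi.binary_fill_holes(mask)
    margin = 8
    if min(shape) > 2 * margin:
        border = np.zeros(shape, dtype=bool)
        border[margin:-margin, margin:-margin] = True
        mask &= border
    return mask


def _place_nuclei(rng: np.random.Generator, spec: FieldSpec) -> np.ndarray:
    """Rejection-sample nucleus centers honoring the separation guarantee."""
    n = spec.n_nuclei
    if n == 0:
        return np.empty((0, 2), dtype=int)
    margin = int(math.ceil(spec.nucleus_radius_range[1])) + 2
    if spec.height - 2 * margin <= 0 or spec.width - 2 * margin <= 0:
        raise ValueError("field too small for the requested nucleus radii")
    min_sep2 = spec.min_center_separation**2
    centers: list[tuple[int, int]] = []
    max_tries = 2000 * n + 2000
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        r = int(rng.integers(margin, spec.height - margin))
        c = int(rng.integers(margin, spec.width - margin))
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep2 for rr, cc in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise RuntimeError(
            f"could not place {n} nuclei with separation "
            f"{spec.min_center_separation:.1f} px in a "
            f"{spec.height}x{spec.width} field"
        )
    return np.asarray(centers, dtype=int)


def _paint_disks(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    members: Iterable[int],
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for i in members:
        r0, c0 = centers[i]
        rad = radii[i]
        ir = int(math.ceil(rad))
        rr = slice(max(r0 - ir, 0), min(r0 + ir + 1, shape[0]))
        cc = slice(max(c0 - ir, 0), min(c0 + ir + 1, shape[1]))
        yy, xx = np.ogrid[rr, cc]
        mask[rr, cc] |= (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
    return mask


def _choose_members(
    rng: np.random.Generator,
    k: int,
    preferred: np.ndarray,
    others: np.ndarray,
) -> np.ndarray:
    """Draw ``k`` members, exhausting ``preferred`` before ``others``."""
    if k == 0:
        return np.empty(0, dtype=int)
    if k <= len(preferred):
        return np.sort(rng.choice(preferred, size=k, replace=False))
    extra = k - len(preferred)
    picked = rng.choice(others, size=extra, replace=False)
    return np.sort(np.concatenate([preferred, picked]))


def generate_field(spec: FieldSpec) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its ground truth.

    The DAPI channel shows every nucleus, the EdU/TUNEL channels exactly
    their member subsets, and the keratin channel the tumor region; all
    structures are drawn at ``foreground_level`` on ``background_level``
    with additive Gaussian noise of ``noise_sd`` clipped to the bit-depth
    range. Member counts are ``round(fraction * n_nuclei)``; EdU members
    are drawn preferentially from nuclei inside the keratin region and
    TUNEL members preferentially from non-EdU nuclei. Bit-identical for
    identical spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)

    keratin = _keratin_mask(rng, spec)
    centers = _place_nuclei(rng, spec)
    rmin, rmax = spec.nucleus_radius_range
    radii = rng.uniform(rmin, rmax, size=spec.n_nuclei)

    all_idx = np.arange(spec.n_nuclei)
    if spec.n_nuclei:
        inside = keratin[centers[:, 0], centers[:, 1]]
    else:
        inside = np.zeros(0, dtype=bool)
    n_edu = int(round(spec.edu_fraction * spec.n_nuclei))
    edu_members = _choose_members(rng, n_edu, all_idx[inside], all_idx[~inside])
    non_edu = np.setdiff1d(all_idx, edu_members)
    n_tunel = int(round(spec.tunel_fraction * spec.n_nuclei))
    tunel_members = _choose_members(rng, n_tunel, non_edu, edu_members)

    nucleus_mask = _paint_disks(shape, centers, radii, all_idx)
    masks = {
        "dapi": nucleus_mask,
        "keratin": keratin,
        "edu": _paint_disks(shape, centers, radii, edu_members),
        "tunel": _paint_disks(shape, centers, radii, tunel_members),
    }

    top = float(2**spec.bit_depth - 1)
    channels: dict[str, np.ndarray] = {}
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    for name in CHANNEL_ORDER:
        if name not in spec.channels:
            continue
        img = np.where(
            masks[name], spec.foreground_level, spec.background_level
        ).astype(float)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = np.clip(np.rint(img), 0, top).astype(dtype)

    field_obj = ImageField(
        channels=channels, pixel_size=spec.pixel_size, bit_depth=spec.bit_depth
    )
    truth = GroundTruth(
        nucleus_centers=centers,
        nucleus_radii=radii,
        nucleus_mask=nucleus_mask,
        keratin_mask=keratin,
        edu_members=edu_members,
        tunel_members=tunel_members,
    )
    return field_obj, truth


_DEFAULT_SERIES: DilutionSeries | None = None


def _default_series() -> DilutionSeries:
    global _DEFAULT_SERIES
    if _DEFAULT_SERIES is None:
        _DEFAULT_SERIES = build_dilution_table()
    return _DEFAULT_SERIES


def _threshold_c50(series: DilutionSeries, threshold: int) -> float:
    """Logistic midpoint: geometric mean of the threshold dilution's
    doxorubicin concentration and the next weaker step."""
    c_thr = series.concentration(threshold, "dox")
    if threshold < 10:
        c_next = series.concentration(threshold + 1, "dox")
    else:
        c_next = c_thr / _STEP_CYCLE[(10 - 1) % 3]
    return math.sqrt(c_thr * c_next)


def dose_effect_model(
    profile: TumorSimProfile,
    dilution: int,
    series: DilutionSeries | None = None,
) -> tuple[float, float]:
    """Expected (EdU fraction, TUNEL fraction) at one dilution.

    A four-parameter logistic in log10 doxorubicin concentration with
    floor 0: EdU fraction falls from its baseline toward 0 and the TUNEL
    fraction rises from its baseline toward ``max_tunel_fraction`` as
    concentration increases. The untreated control (dilution 11) and an
    unresponsive tumor (``true_threshold=None``) return the baselines
    exactly.
    """
    if not 1 <= dilution <= CONTROL_DILUTION:
        raise ValueError(f"dilution must be in 1..11, got {dilution}")
    b_edu = profile.baseline_edu_fraction
    b_tunel = profile.baseline_tunel_fraction
    if dilution == CONTROL_DILUTION or profile.true_threshold is None:
        return b_edu, b_tunel
    series = series or _default_series()
    c = series.concentration(dilution, "dox")
    c50 = _threshold_c50(series, profile.true_threshold)
    x = (c / c50) ** profile.hill_slope
    edu = b_edu / (1.0 + x)
    tunel = b_tunel + (profile.max_tunel_fraction - b_tunel) * x / (1.0 + x)
    return edu, tunel


def _beta_sample(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with given mean and (capped) sd; degenerate cases pass through."""
    mean = min(max(mean, 0.0), 1.0)
    if sd <= 0 or mean in (0.0, 1.0):
        return mean
    sd = min(sd, 0.95 * math.sqrt(mean * (1.0 - mean)))
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


@dataclass
class CohortField:
    """One simulated field of a tumor x dilution slice, with its truth."""

    tumor_id: str
    dilution: int
    day: int
    field_index: int
    seed: int
    expected_edu_fraction: float
    expected_tunel_fraction: float
    realized_edu_fraction: float
    realized_tunel_fraction: float
    image: ImageField | None = None
    truth: GroundTruth | None = None


def generate_cohort(
    profiles: Sequence[TumorSimProfile],
    dilutions: Iterable[int],
    n_fields_per_slice: int,
    spec: FieldSpec | None = None,
    *,
    day: int = 3,
    render: bool = True,
    series: DilutionSeries | None = None,
) -> list[CohortField]:
    """Simulate a whole dose-response cohort.

    For every tumor x dilution, ``n_fields_per_slice`` fields are drawn:
    the per-field EdU/TUNEL fractions are beta realizations around the
    dose-effect expectations with ``heterogeneity_sd`` (``sd=0`` makes
    all fields of a slice share the expectations exactly), then each field
    is rendered from its own sub-seed derived from the master seed in
    ``spec.seed``. With ``render=False`` only the realized fractions are
    produced — the fast statistical mode for calibrating threshold
    recovery without rasterizing images.
    """
    if not profiles:
        raise ValueError("empty profiles list")
    if n_fields_per_slice < 1:
        raise ValueError("n_fields_per_slice must be >= 1")
    spec = spec or FieldSpec()
    dilutions = list(dilutions)
    master = np.random.SeedSequence(spec.seed)
    records: list[CohortField] = []
    for prof in profiles:
        for d in dilutions:
            e_edu, e_tunel = dose_effect_model(prof, d, series)
            for f in range(n_fields_per_slice):
                (child,) = master.spawn(1)
                rng = np.random.default_rng(child)
                realized_e = _beta_sample(rng, e_edu, prof.heterogeneity_sd)
                realized_t = _beta_sample(rng, e_tunel, prof.heterogeneity_sd)
                sub_seed = int(rng.integers(2**31))
                rec = CohortField(
                    tumor_id=prof.tumor_id,
                    dilution=d,
                    day=day,
                    field_index=f,
                    seed=sub_seed,
                    expected_edu_fraction=e_edu,
                    expected_tunel_fraction=e_tunel,
                    realized_edu_fraction=realized_e,
                    realized_tunel_fraction=realized_t,
                )
                if render:
                    fspec = replace(
                        spec,
                        edu_fraction=realized_e,
                        tunel_fraction=realized_t,
                        seed=sub_seed,
                    )
                    img, truth = generate_field(fspec)
                    img.field_id = f"{prof.tumor_id}_d{d:02d}_f{f:02d}"
                    rec.image = img
                    rec.truth = truth
                records.append(rec)
    return records


def fraction_summaries(
    records: Iterable[CohortField],
) -> dict[tuple[str, int], SliceSummary]:
    """Slice summaries computed directly from realized fractions.

    Uses the realized EdU fraction (x100, arbitrary units) in place of
    the image-derived proliferation index and the realized TUNEL fraction
    as a percentage — the statistical counterpart of quantifying rendered
    fields, for fraction-level (``render=False``) cohorts.
    """
    by_slice: dict[tuple[str, int], list[CohortField]] = {}
    for rec in records:
        by_slice.setdefault((rec.tumor_id, rec.dilution), []).append(rec)
    out: dict[tuple[str, int], SliceSummary] = {}
    for (tumor, dilution), group in by_slice.items():
        pi = np.array([r.realized_edu_fraction for r in group]) * 100.0
        tp = np.array([r.realized_tunel_fraction for r in group]) * 100.0
        pq1, pmed, pq3 = np.percentile(pi, [25, 50, 75])
        tq1, tmed, tq3 = np.percentile(tp, [25, 50, 75])
        out[(tumor, dilution)] = SliceSummary(
            tumor_id=tumor,
            day=group[0].day,
            dilution=dilution,
            n_fields=len(group),
            proliferation_index_median=float(pmed),
            proliferation_index_q1=float(pq1),
            proliferation_index_q3=float(pq3),
            proliferation_index_iqr=float(pq3 - pq1),
            tunel_pct_median=float(tmed),
            tunel_pct_q1=float(tq1),
            tunel_pct_q3=float(tq3),
            tunel_pct_iqr=float(tq3 - tq1),
        )
    return out
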