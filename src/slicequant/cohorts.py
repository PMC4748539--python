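"""The 15-tumor breast-carcinoma reference cohort shipped with the package.

Histopathological descriptors and the per-readout threshold dilutions
(nuclear morphology on H&E, EdU proliferation inhibition, TUNEL cell
death) observed for each tumor in the ex vivo FAC dilution assay.
Threshold dilutions follow the ladder convention: 1 = highest FAC
concentration, 10 = lowest; a larger threshold means a more sensitive
tumor. The EdU threshold of tumor 059 was not available and is encoded
as missing.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort", "reference_thresholds"]

_ROWS = [
    # tumor, histology, size_cm, grade, mitoses/2mm2, ER, PR, HER2, morph, edu, tunel
    ("059", "ductal", 3.4, 2, 9, "+", "-", "-", 5, None, 5),
    ("068", "ductal", 1.5, 1, 2, "+", "+", "-", 3, 5, 3),
    ("070", "lobular", 4.0, 2, 2, "+", "+", "-", 5, 5, 5),
    ("071", "lobular", 5.5, 2, 1, "+", "+", "-", 5, 5, 5),
    ("072", "ductal", 11.0, 2, 2, "+", "+", "-", 2, 2, 2),
    ("083", "ductal", 6.5, 2, 2, "+", "+", "-", 5, 7, 5),
    ("089", "ductal", 3.8, 3, 16, "+", "+", "-", 3, 7, 5),
    ("090", "ductal", 3.4, 3, 13, "+", "-", "-", 2, 3, 2),
    ("102", "lobular", 7.0, 2, 7, "+", "+", "-", 2, 5, 5),
    ("112", "ductal", 3.5, 3, 15, "+", "+", "+", 3, 3, 3),
    ("118", "ductal", 1.7, 3, 12, "+", "+", "-", 3, 3, 5),
    ("119", "ductal", 7.0, 3, 26, "-", "-", "-", 5, 3, 3),
    ("121", "lobular", 9.7, 2, 6, "+", "+", "-", 3, 5, 3),
    ("135", "ductal", 5.5, 3, 16, "+", "+", "-", 3, 3, 3),
    ("141", "ductal", 2.5, 3, 8, "+", "-", "-", 3, 5, 5),
]


def reference_cohort() -> pd.DataFrame:
    """Full reference cohort as a tidy DataFrame (one row per tumor)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "tumor_id",
            "histology",
            "tumor_size_cm",
            "grade",
            "mitoses_per_2mm2",
            "er",
            "pr",
            "her2",
            "threshold_morphology",
            "threshold_edu",
            "threshold_tunel",
        ],
    ).astype({"threshold_edu": "Int64"})


def reference_thresholds(readout: str = "morphology") -> dict[str, int | None]:
    """Per-tumor threshold dilution for one readout.

    ``readout`` is ``morphology``, ``edu`` or ``tunel``; missing values
    come back as ``None``.
    """
    col = f"threshold_{readout}"
    df = reference_cohort()
    if col not in df.columns:
        raise ValueError(f"unknown readout {readout!r}")
    return {
        row.tumor_id: (None if pd.isna(getattr(row, col)) else int(getattr(row, col)))
        for row in df.itertuples()
    }
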