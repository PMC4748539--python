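"""TIFF field IO, ground-truth sidecars and cohort manifests.

Fields are stored as single-file multi-page TIFFs (one page per channel,
channel order dapi, keratin, edu, tunel for the channels present) with a
JSON description recording channel names, pixel size, bit depth and field
id, so a written field round-trips bit-exactly through
:func:`write_field` / :func:`read_field`. Synthetic ground truth travels
in a JSON sidecar and a cohort is indexed by a CSV manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import CHANNEL_ORDER, ImageField
from .simulate import CohortField, GroundTruth

__all__ = [
    "write_field",
    "read_field",
    "write_ground_truth",
    "read_ground_truth",
    "write_cohort",
    "read_manifest",
]


def write_field(path: str | Path, img: ImageField) -> None:
    """Write a field as a multi-page TIFF with channel metadata."""
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in img.channels]
    stack = np.stack([img.channels[c] for c in names])
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "channels": names,
            "pixel_size_um": img.pixel_size,
            "bit_depth": img.bit_depth,
            "field_id": img.field_id,
        },
    )


def read_field(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size: float | None = None,
) -> ImageField:
    """Read a multi-page TIFF into an :class:`ImageField`.

    Channel names come from the file's metadata when present; otherwise
    ``channel_map`` (channel name -> page index) must be supplied. A
    ``pixel_size`` argument overrides the stored value (for files from
    other sources without calibration metadata).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt or non-TIFF input
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise OSError(f"{path}: expected 2D pages, got array of ndim {pages.ndim}")

    if channel_map is not None:
        unknown = set(channel_map) - set(CHANNEL_ORDER)
        if unknown:
            raise ValueError(f"unknown channel names: {sorted(unknown)}")
        names_idx = channel_map.items()
    elif "channels" in meta:
        names_idx = [(str(n), i) for i, n in enumerate(meta["channels"])]
    else:
        raise ValueError(
            f"{path}: no channel metadata; pass channel_map={{name: page_index}}"
        )
    channels = {}
    for name, idx in names_idx:
        if not 0 <= idx < len(pages):
            raise ValueError(f"{path}: page {idx} for channel {name!r} out of range")
        channels[name] = pages[idx]

    bit_depth = int(meta.get("bit_depth", 16 if pages.dtype.itemsize > 1 else 8))
    px = pixel_size if pixel_size is not None else float(meta.get("pixel_size_um", 0.7))
    return ImageField(
        channels=channels,
        pixel_size=px,
        bit_depth=bit_depth,
        field_id=str(meta.get("field_id", path.stem)),
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Write the ground-truth sidecar as JSON.

    Stores nucleus centers and radii, the EdU/TUNEL member index sets,
    and the keratin mask's pixel count; the nucleus masks themselves are
    reconstructible from centers and radii.
    """
    payload = {
        "nucleus_centers": truth.nucleus_centers.tolist(),
        "nucleus_radii": truth.nucleus_radii.tolist(),
        "edu_members": truth.edu_members.tolist(),
        "tunel_members": truth.tunel_members.tolist(),
        "keratin_area_px": int(truth.keratin_mask.sum()),
        "shape": list(truth.keratin_mask.shape),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort(records: list[CohortField], outdir: str | Path) -> Path:
    """Write a rendered cohort: one TIFF + truth sidecar per field and a
    ``manifest.csv`` (tumor_id, dilution, day, field_path) indexing them.

    Returns the manifest path. Records must carry rendered images.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        if rec.image is None:
            raise ValueError("cohort was generated with render=False; no images")
        stem = f"{rec.tumor_id}_d{rec.dilution:02d}_f{rec.field_index:02d}"
        tiff_path = outdir / f"{stem}.tiff"
        write_field(tiff_path, rec.image)
        if rec.truth is not None:
            write_ground_truth(outdir / f"{stem}.truth.json", rec.truth)
        rows.append(
            {
                "tumor_id": rec.tumor_id,
                "dilution": rec.dilution,
                "day": rec.day,
                "field_path": tiff_path.name,
                "seed": rec.seed,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; field paths are resolved against its folder."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"tumor_id": str})
    df["field_path"] = [str(path.parent / p) for p in df["field_path"]]
    return df
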