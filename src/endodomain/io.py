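"""Readers and writers: TIFF images, ROI/curve CSV, FASTA, TSV hit tables."""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from endodomain.iwn import BlastRow, SequenceRecord
from endodomain.roi import DiscROI, PixelImage, RingROI

__all__ = [
    "write_image",
    "read_image",
    "write_rois_csv",
    "read_rois_csv",
    "write_fasta",
    "read_fasta",
    "write_blast_tsv",
    "read_blast_tsv",
    "write_curve_csv",
    "read_curve_csv",
]


def write_image(path: str | os.PathLike, images: PixelImage | list[PixelImage]) -> None:
    """Write one or more channels/frames as a (multi-page) TIFF.

    The pixel size is stored in the ImageJ-style resolution tags
    (pixels per micron, unit "um") so a round trip preserves it.
    """
    if isinstance(images, PixelImage):
        images = [images]
    px = images[0].pixel_size_um
    if any(im.pixel_size_um != px for im in images):
        raise ValueError("all pages must share a pixel size")
    stack = np.stack([im.values for im in images]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(1.0 / px, 1.0 / px),
        metadata={"unit": "um", "axes": "ZYX"},
    )


def read_image(
    path: str | os.PathLike, pixel_size_um: float | None = None
) -> list[PixelImage]:
    """Read a single- or multi-page TIFF into a list of :class:`PixelImage`.

    The pixel size comes from the resolution tags; ``pixel_size_um``
    overrides them and is required when the file has none.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        px = pixel_size_um
        if px is None:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            unit_tag = page.tags.get("ResolutionUnit")
            ij = tif.imagej_metadata or {}
            # a bare (1, 1) resolution with no declared unit is the TIFF
            # placeholder, not a real calibration
            has_unit = "unit" in ij or (
                unit_tag is not None and getattr(unit_tag.value, "name", str(unit_tag.value)) != "NONE"
            )
            if xres is not None and has_unit:
                num, den = xres.value
                if num > 0:
                    px = den / num
        if px is None or px <= 0:
            raise ValueError(
                f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
            )
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2D or 3D TIFF, got shape {data.shape}")
    return [PixelImage(values=plane, pixel_size_um=px) for plane in data]


# ---------------------------------------------------------------------------
# ROI CSV dialect: kind(disc|ring), center_x_px, center_y_px, radius_um, width_um
# ---------------------------------------------------------------------------


def write_rois_csv(path: str | os.PathLike, rois: Iterable[DiscROI | RingROI]) -> None:
    rows = []
    for roi in rois:
        rows.append(
            {
                "kind": "ring" if isinstance(roi, RingROI) else "disc",
                "center_x_px": roi.center[0],
                "center_y_px": roi.center[1],
                "radius_um": roi.radius_um,
                "width_um": roi.width_um if isinstance(roi, RingROI) else "",
            }
        )
    pd.DataFrame(
        rows, columns=["kind", "center_x_px", "center_y_px", "radius_um", "width_um"]
    ).to_csv(path, index=False)


def read_rois_csv(path: str | os.PathLike) -> list[DiscROI | RingROI]:
    df = pd.read_csv(path)
    required = {"kind", "center_x_px", "center_y_px", "radius_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ROI CSV lacks columns {sorted(missing)}")
    rois: list[DiscROI | RingROI] = []
    for i, row in df.iterrows():
        center = (float(row["center_x_px"]), float(row["center_y_px"]))
        if row["kind"] == "disc":
            rois.append(DiscROI(center=center, radius_um=float(row["radius_um"])))
        elif row["kind"] == "ring":
            rois.append(
                RingROI(
                    center=center,
                    radius_um=float(row["radius_um"]),
                    width_um=float(row["width_um"]),
                )
            )
        else:
            raise ValueError(f"{path} row {i}: unknown ROI kind {row['kind']!r}")
    return rois


def write_fasta(path: str | os.PathLike, records: Iterable[SequenceRecord]) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.identifier, description="") for r in records
    ]
    SeqIO.write(bio, path, "fasta")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    return [
        SequenceRecord(identifier=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_blast_tsv(path: str | os.PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_blast_tsv(
    path: str | os.PathLike, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a tab-separated hit table with a header.

    ``column_map`` renames input columns to the canonical names
    (``query_id``, ``subject_id``, ``query_coverage_percent``, ``evalue``,
    ``taxon``), accommodating BLAST outfmt-6 exports with ``qcovs`` appended.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("query_coverage_percent", "evalue"):
        if col not in df.columns:
            raise ValueError(f"{path}: hit table lacks required column {col!r}")
    return df


def blast_rows_from_frame(df: pd.DataFrame) -> list[BlastRow]:
    return [
        BlastRow(
            query_id=str(row.get("query_id", "")),
            subject_id=str(row.get("subject_id", "")),
            query_coverage_percent=float(row["query_coverage_percent"]),
            evalue=float(row["evalue"]),
            taxon=str(row.get("taxon", "")),
        )
        for _, row in df.iterrows()
    ]


def write_curve_csv(
    path: str | os.PathLike,
    times_s: np.ndarray,
    bleach: np.ndarray,
    reference: np.ndarray,
    background: np.ndarray,
) -> None:
    pd.DataFrame(
        {
            "time_s": times_s,
            "bleach": bleach,
            "reference": reference,
            "background": background,
        }
    ).to_csv(path, index=False)


def read_curve_csv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_s", "bleach", "reference", "background"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: curve CSV lacks columns {sorted(missing)}")
    return df
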