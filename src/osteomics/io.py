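"""Readers and writers for the pipeline's plain-text formats.

Wide intensity matrices are tab-separated with a ``gene`` column and
``CLASS_rep`` sample headers; missing values are blank or ``NA``. Cell
regions of interest travel as JSON sidecars next to 16-bit grayscale
TIFF/PNG images; annotation sets use the GMT convention
(term, description, members, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .belts import CellImage
from .enrichment import AnnotationSet
from .proteomics import DapgRecord, IntensityMatrix, parse_sample_label

NA_VALUES = ("", "NA", "NaN", "nan")


def read_intensity_tsv(path) -> IntensityMatrix:
    """Read a wide protein-group x sample TSV into an IntensityMatrix."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(NA_VALUES), keep_default_na=False
    )
    for col in df.columns:
        parse_sample_label(col)  # raises on malformed headers
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene rows in {path}: {dups}")
    return IntensityMatrix(df.astype(float))


def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_records_tsv(records, path) -> None:
    """Write per-protein results mirroring the supplementary-table layout:
    gene, -log p, significance, significant Tukey pairs, trend category."""
    rows = []
    for rec in records:
        pairs = [
            f"{a}>{b}" if call.higher == a else f"{b}>{a}"
            for (a, b), call in rec.pair_calls.items()
            if call.significant
        ]
        rows.append(
            {
                "gene": rec.gene,
                "anova_p": rec.anova_p,
                "neg_log_p": rec.neg_log_p,
                "significant": "+" if rec.significant else "",
                "significant_pairs": ";".join(pairs),
                "category": rec.category or "",
            }
        )
    pd.DataFrame(
        rows,
        columns=["gene", "anova_p", "neg_log_p", "significant", "significant_pairs", "category"],
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[AnnotationSet]:
    """Read GMT annotation sets: ``term<TAB>description<TAB>gene...``."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets.append(
            AnnotationSet(
                term_id=fields[0],
                name=fields[1],
                genes=frozenset(g for g in fields[2:] if g),
            )
        )
    return sets


def read_gene_list(path) -> list[str]:
    return [g for g in Path(path).read_text().split() if g]


# ---------------------------------------------------------------------------
# images and regions of interest
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Load a single-channel TIFF/PNG as a float array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel image (shape {arr.shape})")
    return arr.astype(float)


def write_image(pixels: np.ndarray, path) -> None:
    """Write a non-negative float image as 16-bit grayscale TIFF."""
    import tifffile

    arr = np.asarray(pixels, dtype=float)
    scale = arr.max()
    scaled = np.zeros_like(arr) if scale == 0 else arr / scale * 65535.0
    tifffile.imwrite(Path(path), np.round(scaled).astype(np.uint16))


def read_roi_json(path) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Read a ROI sidecar: polygon vertices and optional centrosome."""
    payload = json.loads(Path(path).read_text())
    polygon = np.asarray(payload["polygon"], dtype=float)
    centrosome = payload.get("centrosome")
    if centrosome is not None:
        centrosome = (int(centrosome[0]), int(centrosome[1]))
    return polygon, centrosome


def write_roi_json(path, polygon: np.ndarray, centrosome=None) -> None:
    payload = {"polygon": np.asarray(polygon, dtype=float).tolist()}
    if centrosome is not None:
        payload["centrosome"] = [int(centrosome[0]), int(centrosome[1])]
    Path(path).write_text(json.dumps(payload))


def load_cell_image(image_path, roi_path) -> CellImage:
    polygon, centrosome = read_roi_json(roi_path)
    return CellImage(pixels=read_image(image_path), polygon=polygon, centrosome=centrosome)
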