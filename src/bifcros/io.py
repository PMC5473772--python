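"""Readers/writers for the package's standard artifacts.

TIFF frames are single-channel 16-bit unsigned little-endian; tables are
UTF-8 comma-separated CSV with a header row and '.' decimals; structured
results are JSON with sorted keys.  Array sequences are written as FASTA and
as GenBank with every operator occurrence annotated as a feature (1-based
inclusive coordinates, as GenBank requires).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .arrays import HybridArray, OperatorMotif, find_motifs
from .segmentation import CellMeasurement

__all__ = [
    "write_image",
    "read_image",
    "write_label_mask",
    "write_pixel_table",
    "read_pixel_table",
    "write_array_fasta",
    "write_array_genbank",
    "write_json",
]


def write_image(path, pixels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(pixels, dtype="<u2"))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_label_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored in 16-bit")
    tifffile.imwrite(path, mask.astype("<u2"))


def write_pixel_table(path, measurements: list[CellMeasurement]) -> None:
    """Long-format per-cell pixel table: one row per (cell_id, pixel_value)."""
    frames = [
        pd.DataFrame({"cell_id": m.cell_id, "pixel_value": m.pixel_values})
        for m in measurements
    ]
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "pixel_value"]
    )
    table.to_csv(path, index=False)


def read_pixel_table(path) -> list[CellMeasurement]:
    table = pd.read_csv(path)
    out = []
    for cell_id, group in table.groupby("cell_id", sort=True):
        values = group["pixel_value"].to_numpy(dtype=float)
        out.append(
            CellMeasurement(
                cell_id=int(cell_id),
                area=values.size,
                pixel_values=values,
                mean_intensity=float(values.mean()),
            )
        )
    return out


def _array_record(array: HybridArray, name: str = "hybrid_array") -> SeqRecord:
    record = SeqRecord(
        Seq(array.sequence),
        id=name,
        description=(
            f"hybrid OL1/UAS operator array: {array.n_units} units, "
            f"{array.n_ol1} OL1, {array.n_uas} UAS, "
            f"{array.assembly_steps} assembly steps"
        ),
    )
    record.annotations["molecule_type"] = "DNA"
    motifs: list[OperatorMotif] = []
    if array.block is not None:
        motifs = [array.block.ol1, array.block.uas_motif]
    for motif in motifs:
        for start, end, strand in find_motifs(array.sequence, motif):
            record.features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=strand),
                    type="protein_bind",
                    qualifiers={"label": [motif.name]},
                )
            )
    return record


def write_array_fasta(path, array: HybridArray, name: str = "hybrid_array") -> None:
    SeqIO.write([_array_record(array, name)], str(path), "fasta")


def write_array_genbank(path, array: HybridArray, name: str = "hybrid_array") -> None:
    SeqIO.write([_array_record(array, name)], str(path), "genbank")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
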