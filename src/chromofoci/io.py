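"""Readers and writers for the package's on-disk formats.

Scenes travel as multi-page TIFF (one page per channel, float32), masks as
16-bit label TIFF, tables as UTF-8 comma-separated CSV with a mandatory
header, sequences as FASTA with the methylation mask as a BED-like 3-column
sidecar (0-based half-open intervals).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import GroundTruth, MethylatedSequence

__all__ = [
    "write_scene_tiff",
    "read_scene_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_ground_truth",
    "write_fasta",
    "read_fasta",
    "write_methylation_bed",
    "read_methylation_bed",
]


def write_scene_tiff(path, channels: dict[str, np.ndarray]) -> None:
    names = sorted(channels)
    stack = np.stack([channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(path, stack, metadata={"channel_names": names})


def read_scene_tiff(path) -> dict[str, np.ndarray]:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channel_names") or [f"channel{i}" for i in range(stack.shape[0])]
    return {name: stack[i].astype(float) for i, name in enumerate(names)}


def write_mask_tiff(path, mask: np.ndarray) -> None:
    if mask.dtype == bool:
        mask = mask.astype(np.uint16)
    if np.any(mask < 0) or np.any(mask > np.iinfo(np.uint16).max):
        raise ValueError("mask labels do not fit in uint16")
    tifffile.imwrite(path, mask.astype(np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_ground_truth(directory, truth: GroundTruth, prefix: str = "scene") -> None:
    directory = Path(directory)
    write_mask_tiff(directory / f"{prefix}_nuclei_mask.tif", truth.nucleus_label_mask)
    write_mask_tiff(directory / f"{prefix}_foci_mask.tif", truth.foci_mask)
    truth.per_nucleus_params.to_csv(directory / f"{prefix}_ground_truth.csv", index=False)


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_methylation_bed(path, ms: MethylatedSequence, name: str = "seq") -> None:
    rows = [(name, p, p + 1) for p in sorted(ms.methylated_cpg)]
    pd.DataFrame(rows, columns=["name", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_methylation_bed(path, seq: str, name: str | None = None) -> MethylatedSequence:
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=["name", "start", "end"])
    except pd.errors.EmptyDataError:
        return MethylatedSequence(seq=seq)
    if name is not None:
        bed = bed[bed["name"] == name]
    positions = set()
    for _, row in bed.iterrows():
        positions.update(range(int(row["start"]), int(row["end"])))
    return MethylatedSequence(seq=seq, methylated_cpg=frozenset(positions))
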