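"""Genomic containers and text-format IO for the consensus pipeline.

The pipeline's working representation of a nucleosome map is a *binary
sequence* along each chromosome: 1 marks a nucleosome-packaged base, 0 marks
linker DNA.  Position call sets (BED intervals or dyad coordinates) are
converted into this representation with :func:`binarize_calls`; derived
continuous signals (XOR means, binomial probabilities, occupancy ratios) live
in :class:`RealTrack` and round-trip through bedGraph.

Coordinates are 0-based, half-open everywhere.  All readers and writers are
gzip-transparent (a ``.gz`` suffix switches compression).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "NucleosomeCallSet",
    "BinaryTrack",
    "RealTrack",
    "read_annotation",
    "write_annotation",
    "read_calls",
    "write_calls",
    "binarize_calls",
    "read_track",
    "write_track",
]

ANNOTATION_COLUMNS = ("gene_id", "chrom", "strand", "tss", "tts", "tata", "gene_class")
GENE_CLASSES = ("activated", "repressed", "basal", "unknown")


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


class TrackFormatError(ValueError):
    """Raised on malformed annotation/BED/bedGraph input."""


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class GenomeAnnotation:
    """Gene anchors (TSS/TTS, strand, TATA label, promoter class).

    Parameters
    ----------
    genes
        DataFrame with columns ``gene_id, chrom, strand, tss, tts, tata,
        gene_class``; ``tata`` is boolean, ``gene_class`` one of
        ``activated/repressed/basal/unknown``.
    chrom_sizes
        Mapping chromosome name -> length in bp.
    """

    genes: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.genes.columns]
        if missing:
            raise TrackFormatError(f"annotation missing columns: {missing}")
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise TrackFormatError(f"duplicate gene_id: {dup!r}")
        bad_strand = set(g["strand"]) - {"+", "-"}
        if bad_strand:
            raise TrackFormatError(f"invalid strand values: {sorted(bad_strand)}")
        bad_class = set(g["gene_class"]) - set(GENE_CLASSES)
        if bad_class:
            raise TrackFormatError(f"invalid gene_class values: {sorted(bad_class)}")
        for _, row in g.iterrows():
            size = self.chrom_sizes.get(row["chrom"])
            if size is None:
                raise TrackFormatError(f"gene {row['gene_id']}: unknown chromosome {row['chrom']}")
            for col in ("tss", "tts"):
                if not (0 <= row[col] < size):
                    raise TrackFormatError(
                        f"gene {row['gene_id']}: {col}={row[col]} outside chromosome "
                        f"{row['chrom']} of size {size}"
                    )

    def __len__(self) -> int:
        return len(self.genes)


def read_annotation(path) -> GenomeAnnotation:
    """Read a gene annotation TSV (with a ``# chrom_sizes:`` header line)."""
    chrom_sizes: dict[str, int] = {}
    with _open_text(path, "r") as fh:
        lines = fh.readlines()
    body: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("# chrom_sizes:"):
            for item in line.split(":", 1)[1].split(","):
                item = item.strip()
                if not item:
                    continue
                try:
                    name, size = item.split("=")
                    chrom_sizes[name.strip()] = int(size)
                except ValueError as exc:
                    raise TrackFormatError(f"line {lineno}: bad chrom_sizes entry {item!r}") from exc
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body.append(line)
    if not body:
        raise TrackFormatError("annotation file has no data rows")
    try:
        df = pd.read_csv(io.StringIO("".join(body)), sep="\t", dtype={"gene_id": str, "chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrackFormatError(f"cannot parse annotation table: {exc}") from exc
    if "tata" in df.columns:
        df["tata"] = df["tata"].astype(int).astype(bool)
    df["strand"] = df["strand"].astype(str).str.strip()
    return GenomeAnnotation(df.reset_index(drop=True), chrom_sizes)


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    with _open_text(path, "w") as fh:
        sizes = ",".join(f"{c}={s}" for c, s in annotation.chrom_sizes.items())
        fh.write(f"# chrom_sizes: {sizes}\n")
        df = annotation.genes.copy()
        df["tata"] = df["tata"].astype(int)
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# call sets
# ---------------------------------------------------------------------------


@dataclass
class NucleosomeCallSet:
    """One platform's nucleosome position calls.

    ``calls`` has columns ``chrom, start, end, dyad`` (0-based half-open
    intervals; dyad = ``floor((start+end)/2)`` when read from BED).
    """

    name: str
    calls: pd.DataFrame
    condition: str = "normal"

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end", "dyad"):
            if col not in self.calls.columns:
                raise TrackFormatError(f"call set {self.name!r} missing column {col!r}")
        c = self.calls
        if len(c) and not (c["start"] < c["end"]).all():
            raise TrackFormatError(f"call set {self.name!r}: start >= end")
        if len(c) and not ((c["dyad"] >= c["start"]) & (c["dyad"] < c["end"])).all():
            raise TrackFormatError(f"call set {self.name!r}: dyad outside interval")

    def __len__(self) -> int:
        return len(self.calls)


def read_calls(path, name: str | None = None, condition: str = "normal") -> NucleosomeCallSet:
    """Read a BED3+ file into a call set; dyad = interval midpoint.

    Unsorted input is sorted by (chrom, start); overlapping calls are retained.
    """
    rows = []
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TrackFormatError(f"line {lineno}: expected >=3 BED columns, got {len(parts)}")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TrackFormatError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise TrackFormatError(f"line {lineno}: start >= end")
            rows.append((chrom, start, end, (start + end) // 2))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "dyad"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return NucleosomeCallSet(name or Path(path).stem, df, condition)


def write_calls(callset: NucleosomeCallSet, path) -> None:
    """Write a call set as 6-column BED (name=index, score=0, strand='.')."""
    with _open_text(path, "w") as fh:
        for i, row in enumerate(callset.calls.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tnuc{i}\t0\t.\n")


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


@dataclass
class BinaryTrack:
    """Per-chromosome 0/1 occupancy vectors; 1 = nucleosome-packaged base."""

    data: dict[str, np.ndarray]
    name: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for chrom, arr in self.data.items():
            arr = np.asarray(arr)
            uniq = np.setdiff1d(np.unique(arr), [0, 1])
            if uniq.size:
                raise ValueError(f"binary track {self.name!r}/{chrom}: non-binary values {uniq[:5]}")
            clean[chrom] = arr.astype(np.uint8)
        self.data = clean

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}


@dataclass
class RealTrack:
    """Per-chromosome real-valued signal (occupancy ratio, XOR mean, BDID probability)."""

    data: dict[str, np.ndarray]
    name: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"real track {self.name!r}/{chrom}: non-finite values")
            clean[chrom] = arr
        self.data = clean

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}


def binarize_calls(
    callset: NucleosomeCallSet,
    chrom_sizes: Mapping[str, int],
    footprint: int = 147,
    use_intervals: bool = False,
) -> BinaryTrack:
    """Convert position calls into the binary packaged/linker representation.

    In dyad mode (default) each call marks ``dyad - footprint//2`` up to
    ``dyad - footprint//2 + footprint`` (an even footprint is left-biased);
    with ``use_intervals=True`` the reported interval itself is used.
    Overlaps coalesce to 1; windows are truncated at chromosome edges.
    """
    if not use_intervals and footprint < 1:
        raise ValueError("footprint must be >= 1")
    data = {c: np.zeros(int(s), dtype=np.uint8) for c, s in chrom_sizes.items()}
    calls = callset.calls
    for chrom, sub in calls.groupby("chrom", sort=False):
        if chrom not in data:
            raise ValueError(f"call on unknown chromosome {chrom!r}")
        size = len(data[chrom])
        if use_intervals:
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
        else:
            half = footprint // 2
            starts = sub["dyad"].to_numpy() - half
            ends = starts + footprint
        starts = np.clip(starts, 0, size)
        ends = np.clip(ends, 0, size)
        diff = np.zeros(size + 1, dtype=np.int64)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
        data[chrom][np.cumsum(diff[:-1]) > 0] = 1
    return BinaryTrack(data, name=callset.name)


def write_track(track: RealTrack | BinaryTrack, path) -> None:
    """Write a track as bedGraph, run-length encoding constant stretches."""
    with _open_text(path, "w") as fh:
        for chrom in track.data:
            arr = np.asarray(track.data[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.17g}\n")


def read_track(path, chrom_sizes: Mapping[str, int], name: str | None = None) -> RealTrack:
    """Read a 4-column bedGraph into a dense RealTrack.

    Overlapping intervals and intervals past the chromosome end are rejected;
    uncovered positions are 0.
    """
    data = {c: np.zeros(int(s), dtype=float) for c, s in chrom_sizes.items()}
    covered = {c: np.zeros(int(s), dtype=bool) for c, s in chrom_sizes.items()}
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TrackFormatError(f"line {lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in data:
                raise TrackFormatError(f"line {lineno}: unknown chromosome {chrom!r}")
            if start >= end:
                raise TrackFormatError(f"line {lineno}: start >= end")
            if end > len(data[chrom]):
                raise TrackFormatError(
                    f"line {lineno}: interval end {end} past chromosome end {len(data[chrom])}"
                )
            if covered[chrom][start:end].any():
                raise TrackFormatError(f"line {lineno}: overlapping bedGraph intervals")
            covered[chrom][start:end] = True
            data[chrom][start:end] = value
    return RealTrack(data, name=name or Path(path).stem)
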