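"""TSS/TTS-anchored composite profiles, peak detection and spacing.

A track is cut into strand-oriented per-gene windows (negative offsets =
upstream), averaged into a composite profile, and the profile's local maxima
are reported as the *stable equilibrium points* — the expected nucleosome
centres.  Successive peak distances give the nucleosome repeat length; gaps
larger than a threshold (the NFR-spanning gap) are excluded from the mean
spacing and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks_io import BinaryTrack, GenomeAnnotation, RealTrack

__all__ = [
    "GeneMatrix",
    "CompositeProfile",
    "PeakSet",
    "align_to_anchor",
    "composite_profile",
    "detect_peaks",
    "peak_spacing",
]


@dataclass
class GeneMatrix:
    """Genes x offsets signal matrix, strand-oriented around an anchor."""

    values: np.ndarray
    offsets: np.ndarray
    gene_ids: list[str]
    anchor: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.offsets)):
            raise ValueError("GeneMatrix shape mismatch")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class CompositeProfile:
    """Mean signal vs offset from the anchor."""

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int
    anchor: str


@dataclass
class PeakSet:
    """Detected local maxima of a smoothed composite profile."""

    offsets: np.ndarray
    heights: np.ndarray
    smooth_window: int
    min_separation: int
    min_prominence: float

    def __len__(self) -> int:
        return len(self.offsets)


def align_to_anchor(
    track: BinaryTrack | RealTrack,
    annotation: GenomeAnnotation,
    anchor: str = "tss",
    flank: int = 800,
) -> GeneMatrix:
    """Cut per-gene [-flank, +flank] windows around the anchor.

    Minus-strand rows are reversed so that negative offsets are always
    upstream of transcription.  Genes whose window extends beyond the
    chromosome are dropped and counted in ``n_dropped``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    anchor = anchor.lower()
    if anchor not in ("tss", "tts"):
        raise ValueError("anchor must be 'tss' or 'tts'")
    rows, ids, dropped = [], [], 0
    for g in annotation.genes.itertuples(index=False):
        a = g.tss if anchor == "tss" else g.tts
        data = track.data.get(g.chrom)
        if data is None:
            dropped += 1
            continue
        start, end = a - flank, a + flank + 1
        if start < 0 or end > len(data):
            dropped += 1
            continue
        window = np.asarray(data[start:end], dtype=float)
        rows.append(window[::-1] if g.strand == "-" else window)
        ids.append(g.gene_id)
    if not rows:
        raise ValueError("no usable genes within chromosome bounds")
    return GeneMatrix(
        values=np.vstack(rows),
        offsets=np.arange(-flank, flank + 1),
        gene_ids=ids,
        anchor=anchor,
        n_dropped=dropped,
    )


def composite_profile(m: GeneMatrix) -> CompositeProfile:
    """Column means of a gene matrix."""
    if m.values.shape[0] < 1:
        raise ValueError("empty gene matrix")
    return CompositeProfile(
        offsets=m.offsets.copy(),
        values=m.values.mean(axis=0),
        n_genes=m.values.shape[0],
        anchor=m.anchor,
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="reflect")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    profile: CompositeProfile,
    smooth_window: int = 31,
    min_separation: int = 100,
    min_prominence: float | None = None,
    edge_margin: int | None = None,
) -> PeakSet:
    """Local maxima of the moving-average-smoothed profile.

    ``min_prominence`` defaults to 5% of the smoothed profile's range.
    Candidates are suppressed greedily within ``min_separation`` bp keeping
    the higher peak; exact height ties are broken toward smaller ``|offset|``.
    Maxima within ``edge_margin`` (default: one smoothing window) of the
    profile boundary sit on incompletely smoothed signal and are discarded.
    A constant profile yields an empty peak set.
    """
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    if edge_margin is None:
        edge_margin = smooth_window
    from scipy.signal import find_peaks

    y = _smooth(profile.values, smooth_window)
    rng_y = float(y.max() - y.min())
    if min_prominence is None:
        min_prominence = 0.05 * rng_y
    if rng_y == 0:
        return PeakSet(
            np.array([], dtype=int), np.array([]), smooth_window, min_separation, min_prominence
        )
    cand, _ = find_peaks(y, prominence=min_prominence if min_prominence > 0 else None)
    cand = cand[(cand >= edge_margin) & (cand < len(y) - edge_margin)]
    offsets = profile.offsets[cand]
    heights = y[cand]
    # greedy non-maximum suppression: height desc, ties toward the anchor
    order = sorted(range(len(cand)), key=lambda i: (-heights[i], abs(offsets[i])))
    kept: list[int] = []
    for i in order:
        if all(abs(offsets[i] - offsets[j]) >= min_separation for j in kept):
            kept.append(i)
    kept.sort(key=lambda i: offsets[i])
    return PeakSet(
        offsets=np.asarray(offsets[kept], dtype=int),
        heights=np.asarray(heights[kept], dtype=float),
        smooth_window=smooth_window,
        min_separation=min_separation,
        min_prominence=float(min_prominence),
    )


@dataclass
class SpacingResult:
    spacings: np.ndarray
    mean_spacing: float
    gaps: np.ndarray = field(default_factory=lambda: np.array([]))


def peak_spacing(peaks: PeakSet | np.ndarray, gap_threshold: int = 200) -> SpacingResult:
    """Successive peak distances and their mean, excluding NFR-spanning gaps.

    Differences larger than ``gap_threshold`` (default 200 bp, wider than one
    nucleosome repeat) are reported in ``gaps`` and excluded from
    ``mean_spacing``.
    """
    offsets = peaks.offsets if isinstance(peaks, PeakSet) else np.asarray(peaks)
    if len(offsets) < 2:
        raise ValueError("need at least two peaks")
    diffs = np.diff(np.sort(np.asarray(offsets, dtype=float)))
    kept = diffs[diffs <= gap_threshold]
    gaps = diffs[diffs > gap_threshold]
    mean = float(kept.mean()) if kept.size else float("nan")
    return SpacingResult(spacings=kept, mean_spacing=mean, gaps=gaps)
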