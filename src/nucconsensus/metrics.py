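"""Per-gene measurability and stable/dynamic positioning SNR.

*Measurability* of a gene is the average pairwise Pearson correlation of the
n binary datasets over the gene's TSS +/- 800 bp window — how reproducibly
independent experiments measure that gene's nucleosomes.

*Positioning SNR* compares the energy of the stable consensus signal S to the
energy of the dynamic consensus signal D, in decibels::

    SNR = 10 * log10(S / D),   S = mean(stable^2),  D = mean(dynamic^2)

computed either in a sliding window across the promoter (to profile
measurement accuracy along the gene) or as one number per gene.  A vanishing
dynamic (or stable) energy yields a +inf (or -inf) sentinel, serialized as an
empty cell in TSV output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import CompositeProfile, GeneMatrix
from .tracks_io import BinaryTrack, GenomeAnnotation

__all__ = [
    "gene_measurability",
    "measurability_table",
    "snr_curve",
    "gene_snr",
    "gene_snr_table",
    "SNRCurve",
    "write_metrics_tsv",
]


def _gene_windows(
    tracks, chrom: str, tss: int, flank: int
) -> np.ndarray | None:
    size = len(tracks[0].data[chrom])
    start, end = tss - flank, tss + flank + 1
    if start < 0 or end > size:
        return None
    return np.vstack([np.asarray(t.data[chrom][start:end], dtype=float) for t in tracks])


def gene_measurability(
    tracks: list[BinaryTrack], chrom: str, tss: int, flank: int = 800
) -> tuple[float, int]:
    """Mean pairwise Pearson r over the gene's [-flank, +flank] TSS window.

    Returns ``(measurability, n_pairs)``; zero-variance pairs are excluded
    and ``n_pairs`` decremented.  If every pair is undefined the measurability
    is NaN with ``n_pairs = 0``.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    x = _gene_windows(tracks, chrom, tss, flank)
    if x is None:
        raise ValueError("gene window outside chromosome")
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore"):
        full = np.corrcoef(x)
    rs = [
        full[i, j]
        for i, j in itertools.combinations(range(len(tracks)), 2)
        if sd[i] > 0 and sd[j] > 0
    ]
    if not rs:
        return float("nan"), 0
    return float(np.mean(rs)), len(rs)


def measurability_table(
    tracks: list[BinaryTrack], annotation: GenomeAnnotation, flank: int = 800
) -> pd.DataFrame:
    """Per-gene measurability for every gene whose window fits the chromosome."""
    rows = []
    for g in annotation.genes.itertuples(index=False):
        if g.chrom not in tracks[0].data:
            continue
        try:
            m, n_pairs = gene_measurability(tracks, g.chrom, g.tss, flank)
        except ValueError:
            continue
        rows.append((g.gene_id, m, n_pairs))
    return pd.DataFrame(rows, columns=["gene_id", "measurability", "n_pairs"]).set_index("gene_id")


@dataclass
class SNRCurve:
    """Sliding-window SNR in dB across an anchored window."""

    offsets: np.ndarray
    snr_db: np.ndarray  # +/- inf where one energy vanishes
    window: int
    stable_energy: np.ndarray
    dynamic_energy: np.ndarray


def _window_energy(values: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    sq = np.asarray(values, dtype=float) ** 2
    cs = np.concatenate(([0.0], np.cumsum(sq)))
    starts = np.arange(0, len(sq) - window + 1, step)
    return starts, (cs[starts + window] - cs[starts]) / window


def _as_signal(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, GeneMatrix):
        return x.offsets, x.values.mean(axis=0)
    if isinstance(x, CompositeProfile):
        return x.offsets, x.values
    x = np.asarray(x, dtype=float)
    return np.arange(len(x)), x


def _db(s: np.ndarray, d: np.ndarray) -> np.ndarray:
    out = np.empty_like(s, dtype=float)
    both = (s > 0) & (d > 0)
    with np.errstate(divide="ignore"):
        out[both] = 10.0 * np.log10(s[both] / d[both])
    out[(s > 0) & (d == 0)] = np.inf
    out[(s == 0) & (d > 0)] = -np.inf
    out[(s == 0) & (d == 0)] = np.nan
    return out


def snr_curve(stable, dynamic, window: int = 200, step: int = 1) -> SNRCurve:
    """Sliding-window SNR of the stable vs dynamic consensus signals.

    ``stable`` and ``dynamic`` may be composite profiles, gene matrices
    (averaged over genes) or plain aligned arrays; they must share offsets.
    Each window reports 10*log10(S/D) where S and D are the mean squared
    signals in the window.
    """
    off_s, s_sig = _as_signal(stable)
    off_d, d_sig = _as_signal(dynamic)
    if len(s_sig) != len(d_sig) or not np.array_equal(off_s, off_d):
        raise ValueError("stable and dynamic inputs must share the same offsets")
    if window < 2 or window > len(s_sig):
        raise ValueError("window must be in [2, signal length]")
    starts, s_e = _window_energy(s_sig, window, step)
    _, d_e = _window_energy(d_sig, window, step)
    centres = off_s[starts] + window // 2
    return SNRCurve(
        offsets=centres, snr_db=_db(s_e, d_e), window=window, stable_energy=s_e, dynamic_energy=d_e
    )


def gene_snr(stable_row: np.ndarray, dynamic_row: np.ndarray) -> float:
    """Single SNR (dB) over a gene's full aligned window."""
    s = np.asarray(stable_row, dtype=float)
    d = np.asarray(dynamic_row, dtype=float)
    if s.shape != d.shape:
        raise ValueError("stable and dynamic rows must have the same length")
    return float(_db(np.array([np.mean(s**2)]), np.array([np.mean(d**2)]))[0])


def gene_snr_table(stable: GeneMatrix, dynamic: GeneMatrix) -> pd.DataFrame:
    """Per-gene SNR for genes present in both matrices."""
    common = [g for g in stable.gene_ids if g in set(dynamic.gene_ids)]
    rows = [(g, gene_snr(stable.row(g), dynamic.row(g))) for g in common]
    return pd.DataFrame(rows, columns=["gene_id", "snr_db"]).set_index("gene_id")


def write_metrics_tsv(df: pd.DataFrame, path) -> None:
    """Write a metrics table; +/-inf sentinels become empty cells."""
    out = df.replace([np.inf, -np.inf], np.nan)
    out.to_csv(path, sep="\t", na_rep="")
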