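"""Consensus integration of binary nucleosome maps.

Given n restructured binary datasets (1 = packaged base), three consensus
extractions are provided:

* :func:`logical_and_stack` — the conjunction over all datasets; positions
  where every experiment sees a nucleosome.  This is the *stable* nucleosome
  track.
* :func:`xor_mean_stack` — the arithmetic mean of all C(n, 2) pairwise XOR
  tracks; positions where the experiments disagree.  This is the *dynamic*
  nucleosome track.  At a site where k of n datasets report a nucleosome the
  value is k(n-k)/C(n,2), since exactly k(n-k) of the pairs are discordant.
* :func:`bdid_decompose` — the binomial decomposition: treating the n
  datasets as i.i.d. samples, the per-site occupancy frequency p(i) yields
  the probability profiles P{X(i)=k} = C(n,k) p(i)^k (1-p(i))^(n-k) for
  k = 0..n.  k=0 tracks the nucleosome-free regions, intermediate k the
  dynamic class, k >= n-1 the stable class.

Cross-dataset agreement is quantified with Pearson correlation matrices per
genomic region (:func:`dataset_correlations`), and a pair of continuous
occupancy tracks can be split into common/independent components with a 2x2
PCA (:func:`decompose_occupancy_pair`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks_io import BinaryTrack, GenomeAnnotation, NucleosomeCallSet, RealTrack

__all__ = [
    "BDIDProfiles",
    "CorrelationReport",
    "logical_and_stack",
    "xor_mean_stack",
    "bdid_decompose",
    "dataset_correlations",
    "decompose_occupancy_pair",
    "stable_calls_from_track",
    "GENE_REGIONS",
]


def _check_stack(tracks: Sequence[BinaryTrack]) -> dict[str, int]:
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    sizes = tracks[0].chrom_sizes
    for t in tracks[1:]:
        if t.chrom_sizes != sizes:
            raise ValueError(
                f"track length mismatch: {t.name!r} has {t.chrom_sizes}, expected {sizes}"
            )
    return sizes


def logical_and_stack(tracks: Sequence[BinaryTrack], name: str = "stable_and") -> BinaryTrack:
    """Elementwise AND over the stack: the stable nucleosome track."""
    sizes = _check_stack(tracks)
    data = {}
    for chrom in sizes:
        acc = tracks[0].data[chrom].copy()
        for t in tracks[1:]:
            np.minimum(acc, t.data[chrom], out=acc)
        data[chrom] = acc
    return BinaryTrack(data, name=name)


def xor_pairs(n: int) -> list[tuple[int, int]]:
    """The C(n, 2) dataset pairs entering the XOR mean."""
    return list(itertools.combinations(range(n), 2))


def xor_mean_stack(tracks: Sequence[BinaryTrack], name: str = "dynamic_xor") -> RealTrack:
    """Mean over all pairwise XOR tracks: the dynamic nucleosome track.

    Computed through the closed form k(n-k)/C(n,2) with k the per-site count
    of ones, which equals the explicit enumeration over all pairs.
    """
    sizes = _check_stack(tracks)
    n = len(tracks)
    n_pairs = comb(n, 2)
    data = {}
    for chrom in sizes:
        k = np.zeros(sizes[chrom], dtype=np.int32)
        for t in tracks:
            k += t.data[chrom]
        data[chrom] = k * (n - k) / n_pairs
    return RealTrack(data, name=name)


@dataclass
class BDIDProfiles:
    """Binomial decomposition of an n-dataset stack.

    ``probabilities[k]`` is the RealTrack of P{X(i)=k}; ``p`` is the per-site
    occupancy frequency (values in {0, 1/n, ..., 1}).  Group labels follow
    the phase comparison of the curves: k=0 -> NFR, 1 <= k <= n-2 -> dynamic,
    k >= n-1 -> stable (the threshold is configurable downstream).
    """

    n: int
    p: RealTrack
    probabilities: dict[int, RealTrack]
    stable_k_min: int = field(default=0)

    def __post_init__(self) -> None:
        if self.stable_k_min == 0:
            self.stable_k_min = self.n - 1

    def group(self, k: int) -> str:
        if k == 0:
            return "nfr"
        return "stable" if k >= self.stable_k_min else "dynamic"

    def group_track(self, group: str) -> RealTrack:
        """Sum of the P{X=k} tracks belonging to one group."""
        ks = [k for k in range(self.n + 1) if self.group(k) == group]
        if not ks:
            raise ValueError(f"no k assigned to group {group!r}")
        data = {}
        for chrom in self.p.data:
            acc = np.zeros_like(self.p.data[chrom])
            for k in ks:
                acc += self.probabilities[k].data[chrom]
            data[chrom] = acc
        return RealTrack(data, name=f"bdid_{group}")


def bdid_decompose(tracks: Sequence[BinaryTrack], stable_k_min: int = 0) -> BDIDProfiles:
    """Binomial-distribution-induced decomposition of the stack.

    p(i) is the frequency of nucleosome appearance at site i over the n
    datasets; P{X(i)=k} = C(n,k) p(i)^k (1-p(i))^(n-k).  The n+1 probability
    tracks sum to 1 at every site, and P{X(i)=n} = p(i)^n.
    """
    sizes = _check_stack(tracks)
    n = len(tracks)
    p_data, prob_data = {}, {k: {} for k in range(n + 1)}
    for chrom in sizes:
        k_count = np.zeros(sizes[chrom], dtype=np.int32)
        for t in tracks:
            k_count += t.data[chrom]
        p = k_count / n
        p_data[chrom] = p
        q = 1.0 - p
        for k in range(n + 1):
            prob_data[k][chrom] = comb(n, k) * p**k * q ** (n - k)
    return BDIDProfiles(
        n=n,
        p=RealTrack(p_data, name="bdid_p"),
        probabilities={k: RealTrack(prob_data[k], name=f"bdid_k{k}") for k in range(n + 1)},
        stable_k_min=stable_k_min,
    )


# ---------------------------------------------------------------------------
# cross-dataset correlations
# ---------------------------------------------------------------------------

#: strand-oriented gene segments, each 400 bp, keyed by region name.
#: Entries are (anchor, start_offset, end_offset) with anchor 'tss', 'tts'
#: or 'mid' (gene midpoint).
GENE_REGIONS = {
    "promoter": ("tss", -400, 0),
    "TSS": ("tss", -200, 200),
    "5CDS": ("tss", 0, 400),
    "midCDS": ("mid", -200, 200),
    "3CDS": ("tts", -400, 0),
    "TTS": ("tts", -200, 200),
}


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix between tracks for one region."""

    region: str
    matrix: pd.DataFrame
    mean_offdiag: float
    n_defined_pairs: int


def _region_segments(
    annotation: GenomeAnnotation, region: str, chrom_sizes: Mapping[str, int]
) -> list[tuple[str, int, int, bool]]:
    """Per-gene (chrom, start, end, reverse) genomic segments for a region."""
    anchor, lo, hi = GENE_REGIONS[region]
    segs = []
    for row in annotation.genes.itertuples(index=False):
        minus = row.strand == "-"
        if anchor == "tss":
            a = row.tss
        elif anchor == "tts":
            a = row.tts
        else:
            a = (row.tss + row.tts) // 2
        if minus:
            start, end = a - hi + 1, a - lo + 1
        else:
            start, end = a + lo, a + hi
        if start < 0 or end > chrom_sizes[row.chrom]:
            continue
        segs.append((row.chrom, start, end, minus))
    return segs


def dataset_correlations(
    tracks: Sequence[BinaryTrack | RealTrack],
    annotation: GenomeAnnotation | None = None,
    regions: Sequence[str] = ("genome",),
) -> list[CorrelationReport]:
    """Pairwise Pearson correlations between tracks, per genomic region.

    ``regions`` may include ``genome`` (whole concatenated signal) and the
    400 bp strand-oriented gene segments in :data:`GENE_REGIONS`.
    Constant-signal pairs are undefined: reported as NaN and excluded from
    the off-diagonal mean.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    names = [t.name or f"track{i}" for i, t in enumerate(tracks)]
    sizes = tracks[0].chrom_sizes
    reports = []
    for region in regions:
        if region == "genome":
            mats = [
                np.concatenate([np.asarray(t.data[c], dtype=float) for c in sizes]) for t in tracks
            ]
        elif region in GENE_REGIONS:
            if annotation is None:
                raise ValueError(f"region {region!r} requires an annotation")
            segs = _region_segments(annotation, region, sizes)
            if not segs:
                raise ValueError(f"region {region!r}: no usable genes")
            mats = []
            for t in tracks:
                parts = []
                for chrom, s, e, minus in segs:
                    seg = np.asarray(t.data[chrom][s:e], dtype=float)
                    parts.append(seg[::-1] if minus else seg)
                mats.append(np.concatenate(parts))

        else:
            raise ValueError(f"unknown region {region!r}")
        x = np.vstack(mats)
        sd = x.std(axis=1)
        n = len(tracks)
        mat = np.full((n, n), np.nan)
        for i in range(n):
            if sd[i] > 0:
                mat[i, i] = 1.0
        with np.errstate(invalid="ignore"):
            full = np.corrcoef(x)
        for i, j in itertools.combinations(range(n), 2):
            if sd[i] > 0 and sd[j] > 0:
                mat[i, j] = mat[j, i] = full[i, j]
        off = np.array([mat[i, j] for i, j in itertools.combinations(range(n), 2)])
        defined = off[~np.isnan(off)]
        reports.append(
            CorrelationReport(
                region=region,
                matrix=pd.DataFrame(mat, index=names, columns=names),
                mean_offdiag=float(defined.mean()) if defined.size else float("nan"),
                n_defined_pairs=int(defined.size),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# common/independent decomposition of two occupancy tracks
# ---------------------------------------------------------------------------


def decompose_occupancy_pair(a: RealTrack, b: RealTrack) -> tuple[RealTrack, RealTrack]:
    """Split two occupancy tracks into common and independent components.

    Both tracks are standardized per chromosome; the 2x2 covariance matrix of
    the standardized pair is eigendecomposed and each position is projected
    onto the two axes.  The *common* component is the projection on the
    same-sign (averaging) eigenvector, the *independent* component the
    projection on the opposite-sign (differencing) one — so two identical
    tracks have a vanishing independent component and two sign-opposed
    tracks a vanishing common component, regardless of which axis carries
    the larger eigenvalue.
    """
    if a.chrom_sizes != b.chrom_sizes:
        raise ValueError("track length mismatch")
    common, indep = {}, {}
    for chrom in a.data:
        xa, xb = a.data[chrom], b.data[chrom]
        if xa.std() == 0 or xb.std() == 0:
            raise ValueError(f"zero-variance input on {chrom!r}")
        za = (xa - xa.mean()) / xa.std()
        zb = (xb - xb.mean()) / xb.std()
        cov = np.cov(np.vstack([za, zb]))
        evals, evecs = np.linalg.eigh(cov)
        # eigh returns ascending eigenvalues; identify the averaging axis by
        # the sign pattern of its components
        v0, v1 = evecs[:, 0], evecs[:, 1]
        if v1[0] * v1[1] >= 0:
            v_common, v_indep = v1, v0
        else:
            v_common, v_indep = v0, v1
        if v_common.sum() < 0:
            v_common = -v_common
        if v_indep[0] < 0:
            v_indep = -v_indep
        common[chrom] = v_common[0] * za + v_common[1] * zb
        indep[chrom] = v_indep[0] * za + v_indep[1] * zb
    return (
        RealTrack(common, name="occupancy_common"),
        RealTrack(indep, name="occupancy_independent"),
    )


# ---------------------------------------------------------------------------
# consensus stable calls
# ---------------------------------------------------------------------------


def stable_calls_from_track(
    track: BinaryTrack,
    min_run: int = 80,
    repeat_length: int = 166,
    name: str = "stable_consensus",
) -> NucleosomeCallSet:
    """Turn runs of 1s in a (stable) binary track into consensus calls.

    Runs shorter than ``min_run`` bp are discarded.  A run long enough to
    hold several nucleosomes (adjacent consensus footprints fused across a
    short linker) is split into ``round(length / repeat_length)`` calls with
    evenly spaced dyads; an ordinary single-nucleosome run keeps its midpoint
    dyad.  Used to assign per-gene +1 nucleosomes and to build the consensus
    dyad density.
    """
    rows = []
    for chrom, arr in track.data.items():
        padded = np.concatenate(([0], arr, [0]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        keep = (ends - starts) >= min_run
        for s, e in zip(starts[keep], ends[keep]):
            length = int(e - s)
            k = max(1, round(length / repeat_length))
            for i in range(k):
                sub_s = s + i * length / k
                sub_e = s + (i + 1) * length / k
                rows.append((chrom, int(sub_s), int(sub_e), int((sub_s + sub_e) // 2)))
    calls = pd.DataFrame(rows, columns=["chrom", "start", "end", "dyad"])
    calls = calls.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return NucleosomeCallSet(name, calls)


def dyad_density_track(
    callset: NucleosomeCallSet, chrom_sizes: Mapping[str, int], name: str | None = None
) -> RealTrack:
    """Unit impulse per call dyad: the raw dyad-position density.

    Composite profiles of this track localize nucleosome centres much more
    sharply than footprint-coverage composites, whose ~147 bp plateaus leave
    the position of the maximum poorly determined.
    """
    data = {c: np.zeros(int(s)) for c, s in chrom_sizes.items()}
    for chrom, sub in callset.calls.groupby("chrom", sort=False):
        np.add.at(data[chrom], sub["dyad"].to_numpy(), 1.0)
    return RealTrack(data, name=name or f"{callset.name}_dyads")
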