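"""Promoter nucleosome patterns vs gene regulatory properties.

Links the stable/dynamic consensus tracks to per-gene properties
(transcription rate, mRNA abundance, sensitivity to chromatin regulation,
H3 turnover, expression noise):

* k-means clustering of promoter stable-occupancy patterns in a ~1600 bp
  TSS window into k groups;
* sliding gene-window group-frequency curves along a sorted property
  (the classic "percentage of each group vs property" display);
* Welch t-tests for promoter occupancy-density differences between groups;
* local regulatory correlation (LRC) maps: Pearson r across genes between
  window-mean occupancy and a property, over a grid of window widths and
  centre positions;
* +1 nucleosome / TSS distance analysis and the TATA-containing vs
  TATA-free contrast with bootstrap error bars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .integration import stable_calls_from_track
from .profiles import GeneMatrix, align_to_anchor, composite_profile
from .tracks_io import BinaryTrack, GenomeAnnotation, NucleosomeCallSet, RealTrack

__all__ = [
    "occupancy_feature_matrix",
    "cluster_genes",
    "ClusterAssignment",
    "subset_window_size",
    "group_frequency_curves",
    "group_density_test",
    "lrc_map",
    "LRCMap",
    "assign_plus_one",
    "plus_one_distance_analysis",
    "tata_contrast",
    "TataContrast",
]


def occupancy_feature_matrix(
    track: BinaryTrack | RealTrack,
    annotation: GenomeAnnotation,
    window: int = 1600,
) -> GeneMatrix:
    """Per-gene strand-oriented signal in a ``window`` bp TSS-centred window.

    The window covers offsets ``[-window/2, window/2)`` so the matrix has
    exactly ``window`` columns; delegates to
    :func:`~nucconsensus.profiles.align_to_anchor`.
    """
    if window % 2 != 0:
        raise ValueError("window must be even")
    half = window // 2
    m = align_to_anchor(track, annotation, anchor="tss", flank=half)
    return GeneMatrix(
        values=m.values[:, :-1],
        offsets=m.offsets[:-1],
        gene_ids=m.gene_ids,
        anchor=m.anchor,
        n_dropped=m.n_dropped,
    )


@dataclass
class ClusterAssignment:
    """k-means assignment of genes to promoter-pattern groups (labels 1..k)."""

    labels: pd.Series  # gene_id -> group
    k: int
    inertia: float
    seed: int
    feature_window: str = ""


def cluster_genes(
    features: GeneMatrix, k: int = 4, restarts: int = 10, seed: int = 0
) -> ClusterAssignment:
    """Euclidean k-means on promoter occupancy patterns.

    Best of ``restarts`` random initializations by inertia, deterministic
    given ``seed``.  Groups are relabelled 1..k in decreasing order of mean
    occupancy over the +1 region (offsets [0, 150]) so group numbering is
    stable across runs: group 1 has the strongest +1-region occupancy, group
    k the weakest.
    """
    from sklearn.cluster import KMeans

    x = features.values
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] < k:
        raise ValueError(f"{x.shape[0]} genes < k={k}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError("fewer distinct rows than clusters")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(x)
    plus_one_cols = (features.offsets >= 0) & (features.offsets <= 150)
    region = x[:, plus_one_cols].mean(axis=1) if plus_one_cols.any() else x.mean(axis=1)
    means = [region[raw == c].mean() for c in range(k)]
    order = np.argsort(means)[::-1]  # strongest +1 occupancy -> group 1
    relabel = {int(c): i + 1 for i, c in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=features.gene_ids, name="group")
    return ClusterAssignment(
        labels=labels,
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
        feature_window=f"{features.anchor}[{features.offsets[0]},{features.offsets[-1]}]",
    )


def subset_window_size(n_genes: int, n_subsets: int = 23) -> int:
    """Size of the equal gene subsets (ceiling division), e.g. 4792/23 -> 209."""
    if n_genes < 1 or n_subsets < 1:
        raise ValueError("n_genes and n_subsets must be >= 1")
    return math.ceil(n_genes / n_subsets)


def group_frequency_curves(
    assignment: ClusterAssignment,
    prop: pd.Series,
    window_genes: int | None = None,
    n_subsets: int = 23,
) -> pd.DataFrame:
    """Per-group percentage in sliding gene windows sorted by a property.

    Genes are sorted by ``prop``; for every window of ``window_genes``
    consecutive genes (default ``ceil(N / n_subsets)``), the percentage of
    each group and the window's mean property are recorded.  Returns a long
    DataFrame (window, mean_property, group, percent, n).
    """
    common = assignment.labels.index.intersection(prop.dropna().index)
    if len(common) == 0:
        raise ValueError("no genes with both a cluster label and a property value")
    labels = assignment.labels.loc[common]
    values = prop.loc[common].astype(float)
    order = values.sort_values(kind="stable").index
    labels, values = labels.loc[order].to_numpy(), values.loc[order].to_numpy()
    w = window_genes if window_genes is not None else subset_window_size(len(order), n_subsets)
    if len(order) < w:
        raise ValueError(f"{len(order)} genes < window of {w}")
    groups = sorted(assignment.labels.unique())
    onehot = np.stack([(labels == g).astype(float) for g in groups])
    kernel = np.ones(w)
    counts = np.vstack([np.convolve(row, kernel, mode="valid") for row in onehot])
    mean_prop = np.convolve(values, kernel / w, mode="valid")
    rows = []
    for wi in range(counts.shape[1]):
        for gi, g in enumerate(groups):
            rows.append((wi, mean_prop[wi], g, 100.0 * counts[gi, wi] / w, w))
    return pd.DataFrame(rows, columns=["window", "mean_property", "group", "percent", "n"])


def group_density_test(
    assignment: ClusterAssignment, density: pd.Series
) -> pd.DataFrame:
    """Welch two-sample t-test of promoter occupancy density per group pair."""
    common = assignment.labels.index.intersection(density.dropna().index)
    labels = assignment.labels.loc[common]
    dens = density.loc[common].astype(float)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            a, b = dens[labels == gi], dens[labels == gj]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"group {gi} or {gj} has fewer than 2 genes")
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((gi, gj, float(a.mean()), float(b.mean()), float(t), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_a", "mean_b", "t", "p"])


@dataclass
class LRCMap:
    """Local regulatory correlation map over (window width, window centre)."""

    r: np.ndarray  # widths x centres, NaN where the window does not fit
    widths: np.ndarray
    centres: np.ndarray
    track_class: str
    property_name: str
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format (width, centre, r) with undefined cells dropped."""
        w, c = np.meshgrid(self.widths, self.centres, indexing="ij")
        df = pd.DataFrame(
            {"width": w.ravel(), "centre": c.ravel(), "r": self.r.ravel()}
        ).dropna()
        df["track_class"] = self.track_class
        df["property"] = self.property_name
        df["n"] = self.n_genes
        return df


def lrc_map(
    matrix: GeneMatrix,
    prop: pd.Series,
    widths: np.ndarray | range = range(100, 601, 10),
    position_step: int = 1,
    track_class: str = "",
) -> LRCMap:
    """Pearson r across genes between window-mean occupancy and a property.

    For every window width and every centre position (clipped so the window
    fits inside the matrix's offset range), the per-gene mean occupancy in
    the window is correlated with the property across genes.  Zero-variance
    windows give NaN cells.
    """
    prop = prop.dropna()
    common = [g for g in matrix.gene_ids if g in prop.index]
    if len(common) < 3:
        raise ValueError("need at least three genes with property values")
    rows = [matrix.gene_ids.index(g) for g in common]
    x = matrix.values[rows]
    y = prop.loc[common].to_numpy(dtype=float)
    yc = y - y.mean()
    sy = yc.std()
    if sy == 0:
        raise ValueError("property has zero variance")
    widths = np.asarray(list(widths), dtype=int)
    offsets = matrix.offsets
    centres = offsets[::position_step]
    cs = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    r = np.full((len(widths), len(centres)), np.nan)
    for wi, w in enumerate(widths):
        half_lo = w // 2
        half_hi = w - half_lo
        starts = centres - half_lo - offsets[0]
        valid = (starts >= 0) & (starts + w <= x.shape[1])
        sv = starts[valid]
        win = (cs[:, sv + w] - cs[:, sv]) / w  # genes x valid centres
        wc = win - win.mean(axis=0)
        sw = wc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (wc * yc[:, None]).mean(axis=0) / (sw * sy)
        rr[sw == 0] = np.nan
        r[wi, valid] = rr
    return LRCMap(
        r=r,
        widths=widths,
        centres=centres,
        track_class=track_class,
        property_name=str(prop.name or ""),
        n_genes=len(common),
    )


# ---------------------------------------------------------------------------
# +1 nucleosome analyses
# ---------------------------------------------------------------------------


def assign_plus_one(
    calls: NucleosomeCallSet,
    annotation: GenomeAnnotation,
    max_offset: int = 150,
) -> pd.DataFrame:
    """Assign each gene its +1 nucleosome from (stable) calls.

    The +1 nucleosome is the call whose dyad has the smallest non-negative
    strand-oriented offset from the TSS, within ``[0, max_offset]``.  The
    default cap of 150 bp (under one nucleosome repeat) keeps a missing +1
    from silently promoting the +2 call into the assignment.  Returns
    a frame indexed by gene_id with columns ``dyad`` (genomic),
    ``offset`` (strand-oriented TSS -> dyad) and ``distance``
    (signed TSS - dyad along the gene: -60 when the dyad sits 60 bp
    downstream of the TSS).  Genes without a +1 nucleosome are absent;
    their count is in ``df.attrs['n_unassigned']``.
    """
    rows = []
    unassigned = 0
    by_chrom = {c: sub for c, sub in calls.calls.groupby("chrom")}
    for g in annotation.genes.itertuples(index=False):
        sub = by_chrom.get(g.chrom)
        if sub is None:
            unassigned += 1
            continue
        dyads = sub["dyad"].to_numpy()
        offsets = (dyads - g.tss) if g.strand == "+" else (g.tss - dyads)
        ok = (offsets >= 0) & (offsets <= max_offset)
        if not ok.any():
            unassigned += 1
            continue
        i = np.flatnonzero(ok)[np.argmin(offsets[ok])]
        rows.append((g.gene_id, int(dyads[i]), int(offsets[i]), -int(offsets[i])))
    df = pd.DataFrame(rows, columns=["gene_id", "dyad", "offset", "distance"]).set_index("gene_id")
    df.attrs["n_unassigned"] = unassigned
    return df


def plus_one_distance_analysis(
    calls: NucleosomeCallSet,
    annotation: GenomeAnnotation,
    properties: pd.DataFrame,
    bin_width: int = 10,
    max_offset: int = 150,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene properties as a function of the +1 dyad / TSS distance.

    Returns ``(per_gene, binned)``: the per-gene +1 table joined with the
    properties, and per-distance-bin property means with percentile bootstrap
    intervals (genes resampled with replacement).
    """
    from .slidinganalysis import bootstrap_ci

    plus_one = assign_plus_one(calls, annotation, max_offset)
    per_gene = plus_one.join(properties, how="inner")
    bins = (per_gene["offset"] // bin_width) * bin_width
    rows = []
    rng = np.random.default_rng(seed)
    for (b, prop_name) in [(b, p) for b in sorted(bins.unique()) for p in properties.columns]:
        vals = per_gene.loc[bins == b, prop_name].dropna().to_numpy()
        if vals.size == 0:
            continue
        est, lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rows.append((int(b), prop_name, est, lo, hi, vals.size))
    binned = pd.DataFrame(
        rows, columns=["offset_bin", "property", "mean", "ci_low", "ci_high", "n"]
    )
    binned.attrs["n_unassigned"] = plus_one.attrs["n_unassigned"]
    return per_gene, binned


@dataclass
class TataContrast:
    """TATA-containing vs TATA-free +1 position and property contrast."""

    profile_tata: object
    profile_tatafree: object
    plus_one_offset_tata: float
    plus_one_offset_tatafree: float
    offset_difference: float  # tatafree - tata
    property_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_tata: int = 0
    n_tatafree: int = 0


def tata_contrast(
    annotation: GenomeAnnotation,
    stable_track: BinaryTrack,
    properties: pd.DataFrame | None = None,
    min_run: int = 80,
    max_offset: int = 150,
    flank: int = 800,
    n_boot: int = 1000,
    seed: int = 0,
) -> TataContrast:
    """Compare +1 nucleosome placement and properties by TATA class.

    The stable consensus track is reduced to consensus calls, each gene's +1
    dyad/TSS offset is measured, and the class means are contrasted.  Both
    classes also get a TSS-anchored composite stable profile and (optionally)
    property means with bootstrap standard errors.
    """
    from .slidinganalysis import bootstrap_ci

    genes = annotation.genes
    if not genes["tata"].any() or genes["tata"].all():
        raise ValueError("both TATA classes must be non-empty")
    calls = stable_calls_from_track(stable_track, min_run=min_run)
    plus_one = assign_plus_one(calls, annotation, max_offset)
    tata_ids = set(genes.loc[genes["tata"], "gene_id"])
    is_tata = plus_one.index.to_series().isin(tata_ids)
    off_t = plus_one.loc[is_tata, "offset"].to_numpy(dtype=float)
    off_f = plus_one.loc[~is_tata, "offset"].to_numpy(dtype=float)
    if off_t.size == 0 or off_f.size == 0:
        raise ValueError("a TATA class has no assignable +1 nucleosome")

    def class_profile(mask):
        ann = GenomeAnnotation(genes[mask].reset_index(drop=True), annotation.chrom_sizes)
        return composite_profile(align_to_anchor(stable_track, ann, "tss", flank))

    prop_rows = []
    if properties is not None:
        rng = np.random.default_rng(seed)
        for name in properties.columns:
            for label, ids in (("tata", tata_ids), ("tata_free", None)):
                sel = properties.index.isin(tata_ids)
                vals = properties.loc[sel if label == "tata" else ~sel, name].dropna().to_numpy()
                if vals.size == 0:
                    continue
                est, lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=int(rng.integers(2**31)))
                prop_rows.append((name, label, est, lo, hi, vals.size))
    return TataContrast(
        profile_tata=class_profile(genes["tata"]),
        profile_tatafree=class_profile(~genes["tata"]),
        plus_one_offset_tata=float(off_t.mean()),
        plus_one_offset_tatafree=float(off_f.mean()),
        offset_difference=float(off_f.mean() - off_t.mean()),
        property_means=pd.DataFrame(
            prop_rows, columns=["property", "tata_class", "mean", "ci_low", "ci_high", "n"]
        ),
        n_tata=int(off_t.size),
        n_tatafree=int(off_f.size),
    )
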