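"""Nucleosome sliding between conditions (normal vs heat shock).

Positioned nucleosomes are indexed ordinally around each TSS (-3..-1
upstream, +1..+5 downstream, searching one-by-one outward), matched across
two conditions by index, and their dyad displacements and distances to the
stable equilibrium points are summarized per promoter class.  A per-gene
convergent/divergent pattern label (moving toward/away from equilibrium) is
tested for enrichment against transcriptional activation with Fisher's exact
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tracks_io import GenomeAnnotation, NucleosomeCallSet

__all__ = [
    "IndexedDyads",
    "index_nucleosomes",
    "displacement_by_index",
    "dyad_kernel_density",
    "equilibrium_convergence",
    "ConvergenceReport",
    "pattern_enrichment_test",
    "bootstrap_ci",
    "DOWNSTREAM_INDICES",
    "UPSTREAM_INDICES",
]

DOWNSTREAM_INDICES = (1, 2, 3, 4, 5)
UPSTREAM_INDICES = (-1, -2, -3)


@dataclass
class IndexedDyads:
    """Per-gene, per-index strand-oriented dyad offsets for one condition.

    ``table`` is a wide DataFrame indexed by gene_id with one column per
    nucleosome index (ints -3..-1, 1..5); NaN marks a missing nucleosome.
    """

    table: pd.DataFrame
    condition: str = "normal"

    def offsets(self, index: int) -> pd.Series:
        return self.table[index].dropna()


def index_nucleosomes(
    calls: NucleosomeCallSet,
    annotation: GenomeAnnotation,
    max_upstream: int = 3,
    max_downstream: int = 5,
    search_window: tuple[int, int] = (-1000, 1600),
) -> IndexedDyads:
    """Number calls ordinally around each TSS.

    Strand-oriented dyad offsets >= 0 are numbered +1, +2, ... in increasing
    offset; offsets < 0 are numbered -1, -2, ... in decreasing offset
    (walking away from the TSS on both sides).  Indices beyond the -3..+5
    range, and calls outside ``search_window``, are discarded.
    """
    cols = list(range(-max_upstream, 0)) + list(range(1, max_downstream + 1))
    by_chrom = {c: sub["dyad"].to_numpy() for c, sub in calls.calls.groupby("chrom")}
    lo, hi = search_window
    rows = {}
    for g in annotation.genes.itertuples(index=False):
        dyads = by_chrom.get(g.chrom)
        row = {c: np.nan for c in cols}
        if dyads is not None:
            off = (dyads - g.tss) if g.strand == "+" else (g.tss - dyads)
            off = np.sort(off[(off >= lo) & (off <= hi)])
            down = off[off >= 0][:max_downstream]
            up = off[off < 0][::-1][:max_upstream]
            for i, o in enumerate(down, start=1):
                row[i] = float(o)
            for i, o in enumerate(up, start=1):
                row[-i] = float(o)
        rows[g.gene_id] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[cols]
    table.index.name = "gene_id"
    return IndexedDyads(table=table, condition=calls.condition)


def bootstrap_ci(
    values: np.ndarray,
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Seeded percentile bootstrap: (estimate, low, high).

    With a single value (or ``n_boot=1``) the interval degenerates onto the
    point estimate.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    est = float(statistic(values))
    rng = np.random.default_rng(seed)
    reps = np.array(
        [
            statistic(values[rng.integers(0, values.size, size=values.size)])
            for _ in range(n_boot)
        ]
    )
    alpha = (1.0 - level) / 2.0
    return est, float(np.quantile(reps, alpha)), float(np.quantile(reps, 1.0 - alpha))


def _class_masks(gene_ids: pd.Index, classes: pd.Series) -> dict[str, np.ndarray]:
    cls = classes.reindex(gene_ids)
    masks = {"all": np.ones(len(gene_ids), dtype=bool)}
    for label in ("activated", "repressed"):
        masks[label] = (cls == label).to_numpy()
    return masks


def displacement_by_index(
    before: IndexedDyads,
    after: IndexedDyads,
    classes: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean absolute dyad displacement per index and promoter class.

    Delta = after - before per (gene, index); genes missing the nucleosome in
    either condition are excluded per index.  Signed means are retained for
    inspection alongside the |Delta| summary; intervals are percentile
    bootstrap (degenerate, flagged, when only one gene contributes).
    """
    common = before.table.index.intersection(after.table.index)
    b, a = before.table.loc[common], after.table.loc[common]
    masks = _class_masks(common, classes)
    rng = np.random.default_rng(seed)
    rows = []
    for idx in b.columns:
        delta = (a[idx] - b[idx]).to_numpy()
        for label, mask in masks.items():
            d = delta[mask]
            d = d[~np.isnan(d)]
            if d.size == 0:
                continue
            est, lo, hi = bootstrap_ci(np.abs(d), n_boot=n_boot, seed=int(rng.integers(2**31)))
            rows.append(
                (
                    int(idx),
                    label,
                    est,
                    lo,
                    hi,
                    float(np.mean(d)),
                    int(d.size),
                    d.size < 2,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "index",
            "promoter_class",
            "mean_abs_displacement",
            "ci_low",
            "ci_high",
            "mean_signed_displacement",
            "n",
            "degenerate_ci",
        ],
    )


def dyad_kernel_density(
    dyads: np.ndarray,
    bandwidth: float = 15.0,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of dyad offsets for one nucleosome index.

    ``bandwidth`` is in bp (the kernel SD).  Returns (grid, density); the
    density integrates to 1 over a sufficiently wide evaluation range.
    """
    dyads = np.asarray(dyads, dtype=float)
    if dyads.size < 2:
        raise ValueError("need at least two observations")
    if grid is None:
        lo, hi = dyads.min() - 4 * bandwidth, dyads.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, max(512, int(hi - lo)))
    diff = (grid[:, None] - dyads[None, :]) / bandwidth
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (dyads.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, dens


@dataclass
class ConvergenceReport:
    """Distance-to-equilibrium comparison between two conditions."""

    per_index: pd.DataFrame  # index, promoter_class, mean_dist_before/after, pattern, n
    gene_patterns: pd.Series  # gene_id -> convergent|divergent|neutral
    equilibrium_offsets: tuple[float, ...] = field(default_factory=tuple)


def _nearest_equilibrium(offsets: np.ndarray, eq: np.ndarray) -> np.ndarray:
    return eq[np.argmin(np.abs(offsets[:, None] - eq[None, :]), axis=1)]


def equilibrium_convergence(
    before: IndexedDyads,
    after: IndexedDyads,
    equilibrium_offsets: Sequence[float],
    classes: pd.Series,
) -> ConvergenceReport:
    """Classify nucleosome movement relative to the stable equilibrium points.

    Each observed dyad is measured against its *nearest* equilibrium offset;
    per class and index the mean distances before vs after are compared
    (convergent if after < before, divergent if after > before).  The
    per-gene pattern is the majority over its observed indices, ``neutral``
    on an exact tie.
    """
    eq = np.asarray(sorted(equilibrium_offsets), dtype=float)
    if eq.size == 0:
        raise ValueError("need at least one equilibrium offset")
    common = before.table.index.intersection(after.table.index)
    b, a = before.table.loc[common], after.table.loc[common]
    masks = _class_masks(common, classes)
    rows = []
    votes = pd.DataFrame(0, index=common, columns=["conv", "div", "seen"])
    for idx in b.columns:
        bo, ao = b[idx].to_numpy(), a[idx].to_numpy()
        ok = ~(np.isnan(bo) | np.isnan(ao))
        if not ok.any():
            continue
        db = np.abs(bo[ok] - _nearest_equilibrium(bo[ok], eq))
        da = np.abs(ao[ok] - _nearest_equilibrium(ao[ok], eq))
        votes.loc[common[ok], "conv"] += (da < db).astype(int)
        votes.loc[common[ok], "div"] += (da > db).astype(int)
        votes.loc[common[ok], "seen"] += 1
        for label, mask in masks.items():
            sel = mask[ok]
            if not sel.any():
                continue
            mb, ma = float(db[sel].mean()), float(da[sel].mean())
            pattern = "convergent" if ma < mb else ("divergent" if ma > mb else "neutral")
            rows.append((int(idx), label, mb, ma, pattern, int(sel.sum())))
    observed = votes["seen"] > 0
    patterns = pd.Series(
        np.where(
            votes["conv"] > votes["div"],
            "convergent",
            np.where(votes["div"] > votes["conv"], "divergent", "neutral"),
        ),
        index=common,
        name="pattern",
    )[observed]
    return ConvergenceReport(
        per_index=pd.DataFrame(
            rows,
            columns=[
                "index",
                "promoter_class",
                "mean_dist_before",
                "mean_dist_after",
                "pattern",
                "n",
            ],
        ),
        gene_patterns=patterns,
        equilibrium_offsets=tuple(float(x) for x in eq),
    )


def pattern_enrichment_test(
    patterns: pd.Series, classes: pd.Series
) -> dict:
    """Association between sliding pattern and promoter activation class.

    Builds the convergent/divergent x activated/repressed contingency table
    (neutral patterns and basal genes excluded).  2x2 tables get Fisher's
    exact test and an odds ratio; larger tables a chi-square test.  Any zero
    margin is rejected.
    """
    df = pd.DataFrame({"pattern": patterns, "cls": classes.reindex(patterns.index)}).dropna()
    df = df[df["pattern"].isin(["convergent", "divergent"]) & df["cls"].isin(["activated", "repressed"])]
    table = pd.crosstab(df["pattern"], df["cls"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table is degenerate (a pattern or class is absent)")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    result = {"table": table}
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table.to_numpy())
        result.update(test="fisher_exact", p=float(p), odds_ratio=float(odds))
    else:  # pragma: no cover - only 2x2 arises from the two retained labels
        chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
        result.update(test="chi2", p=float(p), chi2=float(chi2), dof=int(dof))
    return result
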