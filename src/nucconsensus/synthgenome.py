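"""Synthetic yeast-like chromatin: ground truth, platform sampling, properties.

This module builds a planted nucleosome architecture so that every downstream
stage of the consensus pipeline (AND/XOR/BDID integration, composite profiles,
measurability/SNR, regulation and sliding analyses) can be exercised and
verified against known ground truth without external data.

The architecture emulates the features the real cross-platform datasets show:

* phased stable nucleosomes at fixed equilibrium offsets around each TSS
  (default offsets -559, -393, -228, +60, +225, +392, +559, +725 bp; ~165-166
  bp repeat) with small per-gene positional jitter;
* a nucleosome-free region (NFR) just upstream of the TSS that no stable
  nucleosome may enter;
* dynamic (intermittent, poorly positioned) nucleosomes at counterphase sites
  — the midpoints between adjacent stable equilibrium offsets — realized
  independently by each platform with large positional jitter and sub-unit
  presence probability, so that platforms disagree exactly there;
* a TATA-dependent +1 nucleosome offset (58 bp on TATA-containing promoters
  vs 64 bp on TATA-free ones);
* four promoter archetypes differing in which stable nucleosomes are present
  and in dynamic propensity (the planted ground truth for promoter-pattern
  clustering; the sparsest archetype lacks a stable +1);
* gene properties linearly coupled to dynamic occupancy (positively) and
  stable occupancy (negatively) in configured windows;
* a heat-shock condition in which activated genes' arrays expand away from
  the equilibrium points (up to ~350 bp at distal indices), repressed genes'
  nucleosomes converge onto them, and basal genes jitter symmetrically.

Every generator is deterministic given its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks_io import GenomeAnnotation, NucleosomeCallSet, RealTrack

__all__ = [
    "ArchitectureParams",
    "PlatformSpec",
    "ShiftParams",
    "TrueLayout",
    "make_annotation",
    "make_architecture",
    "sample_platform_callsets",
    "make_gene_properties",
    "make_heat_shock_layout",
    "make_occupancy_track",
    "DEFAULT_EQUILIBRIUM_OFFSETS",
    "DEFAULT_PLATFORMS",
    "CONDITION_PLATFORM",
]

DEFAULT_EQUILIBRIUM_OFFSETS = (-559, -393, -228, 60, 225, 392, 559, 725)

#: stable-presence mask per archetype over the +1..+4 core offsets
#: (True = nucleosome present; unlisted offsets always present).  The four
#: promoter archetypes are pairwise >= 2 bands apart: 1 = fully packaged
#: coding region; 2/3 = partially destabilised arrays; 4 = no stable
#: proximal nucleosomes at all (no stable +1, highest dynamic propensity).
_ARCHETYPE_MASKS = {
    1: {60: True, 225: True, 392: True, 559: True},
    2: {60: True, 225: True, 392: False, 559: False},
    3: {60: True, 225: False, 392: True, 559: False},
    4: {60: False, 225: False, 392: False, 559: True},
}
_ARCHETYPE_PROPENSITY = {1: 0.15, 2: 0.28, 3: 0.40, 4: 0.55}


class CapacityError(ValueError):
    """Genes cannot be placed on the chromosome without window overlap."""


@dataclass(frozen=True)
class ArchitectureParams:
    """Parameters of the planted nucleosome architecture.

    All offsets are strand-oriented bp relative to the TSS (negative =
    upstream).  ``nfr_span`` is the promoter nucleosome-free region no stable
    dyad may enter.  ``dynamic_effect_window`` is the region in which the
    per-gene dynamic propensity (archetype-driven) modulates dynamic presence;
    outside it, dynamic sites use the flat ``dynamic_presence_prob``.
    """

    n_genes: int = 2000
    chrom: str = "chrI"
    chrom_length: int | None = None
    gene_spacing: int = 3700
    margin: int = 2500
    nfr_span: tuple[int, int] = (-160, -10)
    equilibrium_offsets: tuple[int, ...] = DEFAULT_EQUILIBRIUM_OFFSETS
    extension_repeat: int = 166
    upstream_extent: int = 900
    body_gap: int = 150
    post_tts_offsets: tuple[int, ...] = (150, 316)
    stable_jitter_sd: float = 8.0
    dynamic_jitter_sd: float = 50.0
    dynamic_presence_prob: float = 0.5
    dynamic_effect_window: tuple[int, int] = (0, 640)
    footprint: int = 147
    tata_fraction: float = 0.2
    plus_one_offset_tata: int = 58
    plus_one_offset_tatafree: int = 64
    class_fractions: tuple[float, float, float] = (0.15, 0.15, 0.70)
    archetype_propensities: tuple[float, float, float, float] = (
        _ARCHETYPE_PROPENSITY[1],
        _ARCHETYPE_PROPENSITY[2],
        _ARCHETYPE_PROPENSITY[3],
        _ARCHETYPE_PROPENSITY[4],
    )
    propensity_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nfr_span[0] > self.nfr_span[1]:
            raise ValueError("nfr_span must be ordered (low, high)")
        if self.stable_jitter_sd < 0 or self.dynamic_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")
        for p in (self.dynamic_presence_prob, self.tata_fraction, *self.archetype_propensities):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")
        if list(self.equilibrium_offsets) != sorted(self.equilibrium_offsets):
            raise ValueError("equilibrium_offsets must be sorted ascending")


@dataclass(frozen=True)
class PlatformSpec:
    """Observation model of one measurement platform.

    ``positional_noise_sd`` blurs every reported dyad; ``detection_rate``
    thins true nucleosomes; ``false_call_rate`` adds spurious calls (per kb).
    ``include_dynamic=False`` emulates a positioned-nucleosome caller that
    reports only the well-positioned (stable) class.
    """

    name: str
    positional_noise_sd: float = 5.0
    detection_rate: float = 0.9
    false_call_rate: float = 0.02
    include_dynamic: bool = True
    condition: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in [0, 1]")
        if self.positional_noise_sd < 0 or self.false_call_rate < 0:
            raise ValueError("noise SD and false_call_rate must be >= 0")


#: platform roster loosely mirroring the six published studies' noise scales.
#: Detection of well-positioned nucleosomes is kept high (the published call
#: sets carry 40-70k calls, close to the full yeast nucleosome complement),
#: so the six-fold intersection retains most stable nucleosomes; platform
#: disagreement is dominated by positional noise and the dynamic class.
DEFAULT_PLATFORMS = (
    PlatformSpec("lee", positional_noise_sd=5.0, detection_rate=0.99, seed=101),
    PlatformSpec("albert", positional_noise_sd=8.0, detection_rate=0.97, seed=102),
    PlatformSpec("whitehouse", positional_noise_sd=10.0, detection_rate=0.96, seed=103),
    PlatformSpec("shivaswamy", positional_noise_sd=4.0, detection_rate=0.99, seed=104),
    PlatformSpec("mavrich", positional_noise_sd=4.0, detection_rate=0.99, seed=105),
    PlatformSpec("field", positional_noise_sd=5.0, detection_rate=0.98, seed=106),
)

#: high-fidelity positioned-nucleosome caller used for the two-condition
#: sliding analysis (ordinal index matching needs near-complete call sets)
CONDITION_PLATFORM = PlatformSpec(
    "condition",
    positional_noise_sd=2.0,
    detection_rate=1.0,
    false_call_rate=0.0,
    include_dynamic=False,
    seed=200,
)


@dataclass
class TrueLayout:
    """Planted ground truth: one row per (gene, nucleosome site).

    ``nucleosomes`` columns:

    ==================  =====================================================
    gene_id             anchor gene
    nuc_class           ``stable`` or ``dynamic``
    index               ordinal index (-3..-1, +1..+5) for stable sites; 0
                        for dynamic counterphase sites
    offset_eq           equilibrium (or counterphase-site) offset from TSS
    offset              realized strand-oriented offset (stable: jittered;
                        dynamic: equals the site, realized per platform)
    dyad                genomic dyad coordinate
    present             stable: archetype presence; dynamic: always True
    presence_prob       per-platform presence probability (1 for stable)
    ==================  =====================================================

    ``gene_info`` carries archetype, dynamic propensity and promoter class.
    """

    nucleosomes: pd.DataFrame
    gene_info: pd.DataFrame
    annotation: GenomeAnnotation
    params: ArchitectureParams
    condition: str = "normal"
    metadata: dict = field(default_factory=dict)

    def stable(self, present_only: bool = True) -> pd.DataFrame:
        sub = self.nucleosomes[self.nucleosomes["nuc_class"] == "stable"]
        return sub[sub["present"]] if present_only else sub

    def dynamic(self) -> pd.DataFrame:
        return self.nucleosomes[self.nucleosomes["nuc_class"] == "dynamic"]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def make_annotation(params: ArchitectureParams) -> GenomeAnnotation:
    """Place ``n_genes`` on one chromosome with disjoint TSS+/-800 windows.

    TSSs sit on a regular grid of pitch ``gene_spacing`` with a +/-200 bp
    uniform offset, so adjacent ``TSS +/- 800`` windows can never overlap as
    long as ``gene_spacing >= 2001`` (checked).  Strand is ~50/50, TATA labels
    are Bernoulli(``tata_fraction``), promoter classes follow
    ``class_fractions``.
    """
    p = params
    if p.gene_spacing < 2001:
        raise CapacityError("gene_spacing must be >= 2001 bp to keep TSS+/-800 windows disjoint")
    needed = p.margin * 2 + (p.n_genes - 1) * p.gene_spacing + 1
    chrom_length = p.chrom_length if p.chrom_length is not None else needed
    if chrom_length < needed:
        raise CapacityError(
            f"chrom_length {chrom_length} too small for {p.n_genes} genes "
            f"(need >= {needed} at spacing {p.gene_spacing})"
        )
    rng = np.random.default_rng(p.seed)
    grid = p.margin + np.arange(p.n_genes) * p.gene_spacing
    tss = grid + rng.integers(-200, 201, size=p.n_genes)
    strand = rng.choice(["+", "-"], size=p.n_genes)
    gene_len = rng.integers(1200, 1801, size=p.n_genes)
    tts = np.where(strand == "+", tss + gene_len, tss - gene_len)
    tata = rng.random(p.n_genes) < p.tata_fraction
    classes = rng.choice(
        ["activated", "repressed", "basal"], size=p.n_genes, p=list(p.class_fractions)
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(p.n_genes)],
            "chrom": p.chrom,
            "strand": strand,
            "tss": tss,
            "tts": np.clip(tts, 0, chrom_length - 1),
            "tata": tata,
            "gene_class": classes,
        }
    )
    return GenomeAnnotation(genes, {p.chrom: int(chrom_length)})


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------


def _gene_lattice(p: ArchitectureParams, gene_len: int, plus_one_offset: float) -> np.ndarray:
    """Equilibrium lattice of one gene: core offsets, upstream/body extensions
    continuing the repeat, a TTS nucleosome-free gap, and post-TTS sites."""
    core = [float(o) for o in p.equilibrium_offsets]
    plus_one = min(o for o in p.equilibrium_offsets if o >= 0)
    core[core.index(float(plus_one))] = float(plus_one_offset)
    lattice = list(core)
    o = min(core) - p.extension_repeat
    while o >= -p.upstream_extent:
        lattice.append(o)
        o -= p.extension_repeat
    o = max(core) + p.extension_repeat
    while o <= gene_len - p.body_gap:
        lattice.append(o)
        o += p.extension_repeat
    for post in p.post_tts_offsets:
        lattice.append(float(gene_len + post))
    return np.sort(np.asarray(lattice))


def _ordinal_indices(lattice: np.ndarray) -> np.ndarray:
    """Ordinal nucleosome indices: downstream offsets +1, +2, ... walking away
    from the TSS, upstream offsets -1, -2, ..."""
    idx = np.zeros(len(lattice), dtype=int)
    down = lattice >= 0
    idx[down] = np.arange(1, down.sum() + 1)
    idx[~down] = -np.arange((~down).sum(), 0, -1)
    return idx


def make_architecture(annotation: GenomeAnnotation, params: ArchitectureParams) -> TrueLayout:
    """Plant stable and dynamic (counterphase) nucleosomes for every gene."""
    p = params
    rng = np.random.default_rng(p.seed + 1)
    genes = annotation.genes
    n = len(genes)
    masked_offsets = set(_ARCHETYPE_MASKS[1])

    archetype = rng.integers(1, 5, size=n)
    propensity = np.clip(
        np.asarray(p.archetype_propensities)[archetype - 1]
        + rng.normal(0.0, p.propensity_jitter_sd, size=n),
        0.02,
        0.55,
    )
    gene_info = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "archetype": archetype,
            "dyn_propensity": propensity,
            "promoter_class": genes["gene_class"].to_numpy(),
        }
    )

    lo, hi = p.nfr_span
    lo_w, hi_w = p.dynamic_effect_window
    cols: dict[str, list] = {
        k: [] for k in ("gene_id", "nuc_class", "index", "offset_eq", "offset", "present", "presence_prob")
    }
    for gi, g in enumerate(genes.itertuples(index=False)):
        glen = abs(int(g.tts) - int(g.tss))
        p1 = p.plus_one_offset_tata if g.tata else p.plus_one_offset_tatafree
        lattice = _gene_lattice(p, glen, p1)
        indices = _ordinal_indices(lattice)
        m = len(lattice)
        jitter = rng.normal(0.0, p.stable_jitter_sd, size=m) if p.stable_jitter_sd > 0 else np.zeros(m)
        realized = lattice + jitter
        # keep stable dyads out of the planted promoter NFR
        inside = (realized > lo) & (realized < hi)
        realized[inside] = np.where(lattice[inside] <= lo, lo, hi)
        realized = np.sort(np.round(realized))
        mask = _ARCHETYPE_MASKS[archetype[gi]]
        present = np.array(
            [mask.get(int(o), True) if o in masked_offsets or int(o) in masked_offsets else True
             for o in lattice]
        )
        # archetype masks are keyed by the configured core offsets; the +1
        # entry applies to the TATA-adjusted +1 position as well
        plus_one = min(o for o in p.equilibrium_offsets if o >= 0)
        p1_pos = np.isclose(lattice, p1)
        present[p1_pos] = mask.get(plus_one, True)
        mids = (lattice[:-1] + lattice[1:]) / 2.0
        n_stable, n_dyn = m, len(mids)
        cols["gene_id"] += [g.gene_id] * (n_stable + n_dyn)
        cols["nuc_class"] += ["stable"] * n_stable + ["dynamic"] * n_dyn
        cols["index"] += list(indices) + [0] * n_dyn
        cols["offset_eq"] += list(lattice) + list(mids)
        cols["offset"] += list(realized) + list(np.round(mids))
        cols["present"] += list(present) + [True] * n_dyn
        dyn_prob = np.where(
            (mids >= lo_w) & (mids <= hi_w), propensity[gi], p.dynamic_presence_prob
        )
        cols["presence_prob"] += [1.0] * n_stable + list(dyn_prob)
    nucs = pd.DataFrame(cols)

    sign = np.where(genes["strand"].to_numpy() == "+", 1, -1)
    tss = genes["tss"].to_numpy()
    gid_order = {g: i for i, g in enumerate(genes["gene_id"])}
    gidx = nucs["gene_id"].map(gid_order).to_numpy()
    nucs["dyad"] = (tss[gidx] + sign[gidx] * nucs["offset"].to_numpy()).astype(int)
    nucs = nucs.sort_values(["gene_id", "offset"], kind="stable").reset_index(drop=True)

    # planted expectations for the composite-profile analyses: the lattice
    # positions shared by all genes inside the default +/-800 bp window, with
    # the +1 offset at its TATA-mixture mean
    exp_plus_one = (
        p.tata_fraction * p.plus_one_offset_tata + (1 - p.tata_fraction) * p.plus_one_offset_tatafree
    )
    plus_one = min(o for o in p.equilibrium_offsets if o >= 0)
    profile_lattice = sorted(
        {float(o) for o in p.equilibrium_offsets if o != plus_one}
        | {exp_plus_one}
        | {
            float(o)
            for o in np.arange(
                min(p.equilibrium_offsets) - p.extension_repeat,
                -p.upstream_extent - 1,
                -p.extension_repeat,
            )
        }
    )
    profile_lattice = [o for o in profile_lattice if -800 <= o <= 800]
    d = np.diff(profile_lattice)
    planted_mean_spacing = float(np.mean(d[d <= 200]))
    lat = np.asarray(profile_lattice)
    metadata = {
        "planted_offsets": tuple(float(o) for o in p.equilibrium_offsets),
        "planted_profile_offsets": tuple(profile_lattice),
        "planted_mean_spacing": planted_mean_spacing,
        "counterphase_sites": tuple((lat[:-1] + lat[1:]) / 2.0),
        "plus_one_offset": plus_one,
        "expected_plus_one": exp_plus_one,
    }
    return TrueLayout(nucs, gene_info, annotation, p, condition="normal", metadata=metadata)


# ---------------------------------------------------------------------------
# platform sampling
# ---------------------------------------------------------------------------


def sample_platform_callsets(
    layout: TrueLayout, specs: Sequence[PlatformSpec]
) -> list[NucleosomeCallSet]:
    """Draw one call set per platform spec from the planted layout.

    Stable nucleosomes are reported at their layout dyad plus platform noise,
    thinned by ``detection_rate``.  Dynamic nucleosomes are realized
    independently by each platform: present with ``presence_prob *
    detection_rate`` at the counterphase site plus N(0, dynamic_jitter_sd)
    plus platform noise — each platform is an independent sample of a cell
    population in which these nucleosomes are intermittent and poorly
    positioned.  Poisson false calls are added at ``false_call_rate`` per kb.

    With zero noise, full detection, no false calls and (for the dynamic
    class) zero dynamic jitter and unit presence probability, the sampled
    dyads equal the layout dyads exactly.
    """
    if not specs:
        raise ValueError("need at least one platform spec")
    p = layout.params
    chrom = p.chrom
    chrom_length = layout.annotation.chrom_sizes[chrom]
    half = p.footprint // 2
    out = []
    stable = layout.stable(present_only=True)
    dynamic = layout.dynamic()
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        dyads = []
        keep = rng.random(len(stable)) < spec.detection_rate
        d = stable["dyad"].to_numpy()[keep].astype(float)
        if spec.positional_noise_sd > 0:
            d = d + rng.normal(0.0, spec.positional_noise_sd, size=d.size)
        dyads.append(d)
        if spec.include_dynamic and len(dynamic):
            keep = rng.random(len(dynamic)) < dynamic["presence_prob"].to_numpy() * spec.detection_rate
            d = dynamic["dyad"].to_numpy()[keep].astype(float)
            if p.dynamic_jitter_sd > 0:
                d = d + rng.normal(0.0, p.dynamic_jitter_sd, size=d.size)
            if spec.positional_noise_sd > 0:
                d = d + rng.normal(0.0, spec.positional_noise_sd, size=d.size)
            dyads.append(d)
        if spec.false_call_rate > 0:
            n_false = rng.poisson(spec.false_call_rate * chrom_length / 1000.0)
            dyads.append(rng.uniform(half, chrom_length - half - 1, size=n_false))
        dyad = np.round(np.concatenate(dyads)).astype(int)
        dyad = np.clip(dyad, half, chrom_length - (p.footprint - half) - 1)
        calls = pd.DataFrame(
            {
                "chrom": chrom,
                "start": dyad - half,
                "end": dyad - half + p.footprint,
                "dyad": dyad,
            }
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        out.append(NucleosomeCallSet(spec.name, calls, condition=spec.condition))
    return out


# ---------------------------------------------------------------------------
# gene properties
# ---------------------------------------------------------------------------

DEFAULT_EFFECT_SIZES = {
    "transcription_rate": (1.0, -0.8),
    "mrna_abundance": (1.0, -0.8),
    "regulation_sensitivity": (0.8, -0.6),
    "h3_turnover": (0.8, -0.6),
    "expression_noise": (0.6, -0.4),
}


def make_gene_properties(
    layout: TrueLayout,
    effect_sizes: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    stable_window: tuple[int, int] = (-240, 560),
) -> pd.DataFrame:
    """Generate gene properties coupled to planted occupancy.

    Each property is ``beta_dyn * z(dynamic occupancy) + beta_stab *
    z(stable occupancy) + N(0, noise_sd)`` where dynamic occupancy is the
    gene's expected dynamic coverage inside ``dynamic_effect_window``
    (propensity x number of counterphase sites there) and stable occupancy is
    the footprint coverage fraction of present stable nucleosomes inside
    ``stable_window``.  By default ``beta_dyn > 0`` and ``beta_stab < 0``:
    dynamic occupancy tracks transcriptional activity, stable occupancy
    opposes it.

    The returned frame is indexed by gene_id; ``df.attrs['planted']`` records
    the exact planted Pearson correlation of each property with both
    occupancy covariates (computed from the realized covariates, the betas
    and the noise variance).
    """
    p = layout.params
    effects = dict(DEFAULT_EFFECT_SIZES if effect_sizes is None else effect_sizes)
    for betas in effects.values():
        if not all(math.isfinite(b) for b in betas):
            raise ValueError("effect sizes must be finite")
    rng = np.random.default_rng(seed)
    genes = layout.annotation.genes
    gid = genes["gene_id"].to_numpy()
    n = len(gid)

    lo_w, hi_w = p.dynamic_effect_window
    dyn = layout.dynamic()
    in_w = dyn[(dyn["offset_eq"] >= lo_w) & (dyn["offset_eq"] <= hi_w)]
    n_sites = in_w.groupby("gene_id").size().reindex(gid).fillna(0).to_numpy()
    x_dyn = layout.gene_info.set_index("gene_id")["dyn_propensity"].reindex(gid).to_numpy() * n_sites

    lo_s, hi_s = stable_window
    st = layout.stable(present_only=True)
    half = p.footprint // 2
    cover = np.zeros(n)
    width = hi_s - lo_s
    order = {g: i for i, g in enumerate(gid)}
    s_idx = st["gene_id"].map(order).to_numpy()
    s_lo = np.clip(st["offset"].to_numpy() - half, lo_s, hi_s)
    s_hi = np.clip(st["offset"].to_numpy() + half + 1, lo_s, hi_s)
    np.add.at(cover, s_idx, (s_hi - s_lo) / width)
    x_stab = cover

    def z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    zd, zs = z(x_dyn), z(x_stab)
    r_ds = float(np.corrcoef(zd, zs)[0, 1]) if n > 1 else 0.0
    data, planted = {}, {}
    for name, (bd, bs) in effects.items():
        y = bd * zd + bs * zs
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=n)
        data[name] = y
        var_y = bd**2 + bs**2 + 2 * bd * bs * r_ds + noise_sd**2
        sd_y = math.sqrt(var_y) if var_y > 0 else float("nan")
        planted[name] = {
            "beta_dyn": bd,
            "beta_stab": bs,
            "r_dyn": (bd + bs * r_ds) / sd_y if sd_y > 0 else float("nan"),
            "r_stab": (bs + bd * r_ds) / sd_y if sd_y > 0 else float("nan"),
        }
    df = pd.DataFrame(data, index=pd.Index(gid, name="gene_id"))
    df.attrs["planted"] = planted
    df.attrs["dynamic_effect_window"] = (lo_w, hi_w)
    df.attrs["stable_window"] = stable_window
    df.attrs["x_dyn"] = x_dyn
    df.attrs["x_stab"] = x_stab
    return df


# ---------------------------------------------------------------------------
# heat shock
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftParams:
    """Heat-shock displacement model.

    Activated genes' stable nucleosomes slide *away* from their equilibrium
    points — upstream indices further upstream, downstream indices further
    downstream — with per-index mean magnitudes growing with distance from
    the TSS up to ``cap`` (default magnitudes reach ~350 bp at the +5
    nucleosome).  Repressed genes' nucleosomes move *toward* equilibrium
    (residual offset scaled by ``repressed_shrink``); basal genes get small
    symmetric jitter.
    """

    magnitudes: dict[int, float] = field(
        default_factory=lambda: {1: 20, 2: 60, 3: 120, 4: 220, 5: 350, -1: 20, -2: 60, -3: 120}
    )
    cap: float = 350.0
    magnitude_rel_spread: float = 0.15
    repressed_shrink: float = 0.1
    basal_jitter_sd: float = 3.0

    def magnitude(self, index: int) -> float:
        # indices outside the measured -3..+5 range (deep gene body, far
        # upstream) are left in place: remodeling concentrates near promoters
        mag = self.magnitudes.get(index, 0.0)
        return float(min(mag, self.cap))


def make_heat_shock_layout(
    layout: TrueLayout, shift_params: ShiftParams | None = None, seed: int = 0
) -> TrueLayout:
    """Apply activation-dependent dyad shifts; returns the heat-shock layout."""
    sp = shift_params or ShiftParams()
    if layout.gene_info["promoter_class"].isin(["unknown"]).all():
        raise ValueError("promoter classes must be assigned before heat shock")
    rng = np.random.default_rng(seed)
    nucs = layout.nucleosomes.copy()
    cls = layout.gene_info.set_index("gene_id")["promoter_class"]
    gene_cls = nucs["gene_id"].map(cls).to_numpy()
    stable = (nucs["nuc_class"] == "stable").to_numpy()
    idx = nucs["index"].to_numpy()
    offset = nucs["offset"].to_numpy().astype(float)
    eq = nucs["offset_eq"].to_numpy().astype(float)
    new = offset.copy()

    act = stable & (gene_cls == "activated")
    if act.any():
        mags = np.array([sp.magnitude(i) for i in idx[act]])
        scale = 1.0 + rng.uniform(-sp.magnitude_rel_spread, sp.magnitude_rel_spread, size=act.sum())
        new[act] = offset[act] + np.sign(idx[act]) * mags * scale

    rep = stable & (gene_cls == "repressed")
    if rep.any():
        new[rep] = eq[rep] + (offset[rep] - eq[rep]) * sp.repressed_shrink

    bas = stable & (gene_cls == "basal")
    if bas.any() and sp.basal_jitter_sd > 0:
        new[bas] = offset[bas] + rng.normal(0.0, sp.basal_jitter_sd, size=bas.sum())

    # nucleosomes cannot slide through each other: a large shift is blocked
    # by (stacks against) the next static nucleosome along the gene
    nucs["offset"] = np.round(new)
    stable_rows = nucs["nuc_class"] == "stable"
    sub = nucs.loc[stable_rows]
    nucs.loc[stable_rows, "offset"] = sub.groupby("gene_id", sort=False)["offset"].transform(
        lambda s: np.sort(s.to_numpy())
    )
    genes = layout.annotation.genes
    sign = {g: (1 if s == "+" else -1) for g, s in zip(genes["gene_id"], genes["strand"])}
    tss = {g: t for g, t in zip(genes["gene_id"], genes["tss"])}
    nucs["dyad"] = (
        nucs["gene_id"].map(tss).to_numpy()
        + nucs["gene_id"].map(sign).to_numpy() * nucs["offset"].to_numpy()
    ).astype(int)
    meta = dict(layout.metadata)
    meta["planted_shift_magnitudes"] = {k: sp.magnitude(k) for k in sorted(sp.magnitudes)}
    meta["shift_params"] = sp
    return TrueLayout(
        nucs, layout.gene_info, layout.annotation, layout.params, condition="heat_shock", metadata=meta
    )


# ---------------------------------------------------------------------------
# occupancy track
# ---------------------------------------------------------------------------


def make_occupancy_track(
    callset: NucleosomeCallSet,
    chrom_sizes: dict[str, int],
    footprint: int = 147,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RealTrack:
    """Sum of footprint indicators per position plus optional Normal noise.

    Unlike :func:`~nucconsensus.tracks_io.binarize_calls`, overlapping
    footprints stack (two calls 80 bp apart give height 2 in the overlap),
    emulating a continuous occupancy-ratio signal.
    """
    if footprint < 1:
        raise ValueError("footprint must be >= 1")
    rng = np.random.default_rng(seed)
    half = footprint // 2
    data = {}
    for chrom, size in chrom_sizes.items():
        size = int(size)
        diff = np.zeros(size + 1)
        sub = callset.calls[callset.calls["chrom"] == chrom]
        starts = np.clip(sub["dyad"].to_numpy(dtype=np.int64) - half, 0, size)
        ends = np.clip(starts + footprint, 0, size)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        track = np.cumsum(diff[:-1])
        if noise_sd > 0:
            track = track + rng.normal(0.0, noise_sd, size=size)
        data[chrom] = track
    return RealTrack(data, name=f"{callset.name}_occupancy")
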