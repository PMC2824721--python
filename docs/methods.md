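# Methods

## The consensus model

Each input dataset is a set of nucleosome position calls on a shared genome.
All analyses run on the *binary restructuring* of a call set: a per-chromosome
0/1 vector in which 1 marks nucleosome-packaged DNA (a 147 bp footprint around
each call's dyad by default, or the reported interval) and 0 marks linker.
Coordinates are 0-based half-open; an even footprint is placed left-biased
around the dyad.

Given *n* binary datasets, three consensus extractions are computed per site
*i*, writing *k(i)* for the number of datasets calling the site packaged and
*p(i) = k(i)/n*:

* **stable** (logical AND): 1 iff *k(i) = n*;
* **dynamic** (mean pairwise XOR): *k(i)(n−k(i))/C(n,2)* — the fraction of the
  C(n,2) dataset pairs that disagree; it vanishes exactly where the datasets
  are unanimous;
* **BDID**: the binomial probabilities *P{X(i)=k} = C(n,k) p(i)^k (1−p(i))^{n−k}*,
  *k = 0…n*, which sum to 1 at every site. The curves partition into an NFR
  group (*k = 0*), a dynamic group (*1 ≤ k ≤ n−2*) and a stable group
  (*k ≥ n−1*); the stable threshold is configurable.

Treating the datasets as i.i.d. samples of a cell population is the model's
central assumption; it is exact for the synthetic generator and only an
approximation for real cross-platform data (platform biases are correlated).

Two continuous occupancy tracks can additionally be split into common and
independent components by standardizing both, eigendecomposing their 2×2
covariance and projecting on the two axes. The projection on the same-sign
(averaging) eigenvector is reported as the common component and the
opposite-sign (differencing) one as independent, irrespective of eigenvalue
order — so identical tracks have a null independent component and sign-opposed
tracks a null common component.

## Anchored profiles and equilibrium points

Tracks are cut into strand-oriented per-gene windows (default ±800 bp) around
the TSS or TTS, genes truncated by chromosome ends being dropped and counted,
and averaged into composite profiles. Peaks of the smoothed stable composite
are the *stable equilibrium points*; successive distances ≤ 200 bp give the
nucleosome repeat (larger gaps — the NFR — are reported separately).

Peak localization uses the **consensus dyad density**, not the raw coverage
composite: runs of 1s in the AND track at least 80 bp long become consensus
calls (runs long enough for several nucleosomes are split at the 166 bp repeat
into evenly spaced dyads), and the composite of the dyad impulses is smoothed
(31 bp) and scanned for local maxima with 100 bp minimum separation and a
prominence floor of 5% of the profile range. The coverage composite of a
147 bp footprint is a flat-topped plateau whose maximum is poorly determined —
in measurements its argmax wandered ~30 bp under neighbour overlap — whereas
dyad-density peaks recover planted positions within ±3 bp. Maxima within one
smoothing window of the window boundary are discarded as unreliable. Exact
height ties break toward the smaller |offset|.

## Measurability and SNR

Per gene, *measurability* is the mean Pearson correlation over all C(n,2)
dataset pairs in the ±800 bp TSS window; zero-variance pairs are excluded and
the pair count reported. Positioning *SNR* is 10·log₁₀(S/D) in dB with
"energy" the mean squared signal — S from the stable track, D from the
dynamic track — either per gene over the full window or in a 200 bp sliding
window across the promoter. S = D gives 0 dB and a tenfold energy ratio
10 dB; a vanishing D (or S) yields a +∞ (−∞) sentinel, serialized as an empty
TSV cell. SNR is invariant under common rescaling and strictly increasing in
stable energy.

## Regulation analyses

* **Clustering**: Euclidean k-means (best of 10 seeded restarts) on the
  per-gene stable-track occupancy in a 1,600 bp TSS window, k = 4. Groups are
  relabelled in decreasing order of mean occupancy over offsets [0, 150] so
  numbering is reproducible.
* **Group-frequency curves**: genes sorted by a property; in each sliding
  window of ⌈N/23⌉ consecutive genes (209 for 4,792 genes) the per-group
  percentage is plotted against the window's mean property.
* **Density contrast**: Welch two-sample t-tests of promoter occupancy
  density between every group pair.
* **LRC maps**: for window widths 100–600 bp (10 bp width step by default; a
  1 bp step over both axes is supported but slow) and every centre position
  in ±800 bp, the Pearson correlation across genes between window-mean
  occupancy and the property. Negating a property negates the map exactly;
  zero-variance windows are undefined cells.
* **+1 nucleosome**: the consensus stable call whose dyad has the smallest
  non-negative strand-oriented TSS offset within [0, 150]. The cap of one
  half-repeat is deliberate: with a wider window a missing +1 silently
  promotes the +2 call (~225 bp) into the slot and biases the class means.
  Reported distance follows the TSS − dyad sign convention (−60 for a dyad
  60 bp downstream); with a 147 bp footprint that places the TSS
  ⌊147/2⌋ − 60 = 13 bp inside the nucleosome's upstream border. The TATA
  contrast compares class-wise composite profiles, +1 offsets and property
  means with seeded percentile-bootstrap intervals.

## Sliding analysis

Calls are indexed ordinally around each TSS (+1, +2, … downstream; −1, −2, …
upstream; indices beyond −3/+5 discarded; search window −1,000…+1,600 bp) and
matched across conditions by index. Per index and promoter class the mean
|Δdyad| is reported with bootstrap intervals, and each dyad's distance to its
*nearest* stable equilibrium point is compared between conditions: convergent
if it shrinks, divergent if it grows; a gene's pattern is the majority over
its indices (neutral on a tie), and swapping the conditions exactly exchanges
the two labels. Pattern-vs-activation enrichment uses Fisher's exact test on
the convergent/divergent × activated/repressed table (χ² for larger tables);
zero margins are rejected. Ordinal matching mirrors a one-by-one search
outward from the TSS and is the analysis' weakest assumption: one missing
call shifts every later index by one, producing ~165 bp displacement
artifacts, which is why the default scenario samples the condition pair at
full detection with positioned calls only.

## The synthetic generator

The generator emulates the study conditions of a six-platform yeast
experiment; its defaults are the package's fixed reference conditions.

* **Genes**: 2,000 by default on one chromosome (multi-gene slots of 3,700 bp
  keep each gene's ±800 bp window, its array and its heat-shock excursions
  private), ~50% per strand, lengths 1,200–1,800 bp, TATA labels at 20%,
  promoter classes 15% activated / 15% repressed / 70% basal.
* **Stable lattice**: equilibrium offsets −559, −393, −228, +60, +225, +392,
  +559, +725 bp from the TSS (config, not constants), extended at the 166 bp
  repeat upstream to −900 bp and through the gene body, with a
  nucleosome-free gap at the TTS and two post-TTS sites. The +1 offset is
  58 bp on TATA-containing and 64 bp on TATA-free promoters. Per-gene
  positional jitter is Normal(0, 8 bp); no stable dyad may sit inside the
  promoter NFR (−160…−10 bp). The 8 bp (stable) vs 50 bp (dynamic) spread is
  a tunable default, not a claim about real chromatin.
* **Promoter archetypes**: four classes differing in which of the +1…+4 core
  nucleosomes are present (pairwise ≥ 2 bands apart; archetype 4 has no
  stable +1) with dynamic propensities 0.15/0.28/0.40/0.55 (±0.05).
* **Dynamic nucleosomes** occupy the counterphase sites — midpoints between
  adjacent lattice positions, including the fragile promoter-NFR site — and
  are *realized independently by each platform*: present with the site's
  probability times the platform detection rate, at the site plus
  Normal(0, 50 bp) jitter. A realization shared across platforms could never
  produce cross-platform disagreement, which is the phenomenon the class
  models; the per-platform construction reduces to the deterministic layout
  in the zero-noise limit (unit presence, zero jitter). Per-gene propensity
  modulates only sites inside the effect window 0…+650 bp, so the planted
  occupancy–property correlation is localized there.
* **Platforms**: six specs with positional noise 4–10 bp, detection
  0.96–0.99 and ~0.02 false calls/kb. Detection is kept near-complete so the
  six-fold intersection retains most well-positioned nucleosomes — the
  published call sets are of near-full-complement size, and the planted
  archetypes are separable only if their bands survive the AND. The
  two-condition pair for the sliding analysis is sampled at full detection,
  2 bp noise, positioned (stable) calls only.
* **Properties**: five gene properties, each
  β_dyn·z(dynamic occupancy) + β_stab·z(stable coverage) + Normal noise with
  β_dyn > 0 and β_stab < 0; exact planted correlations are recorded in the
  output metadata.
* **Heat shock**: activated genes' arrays expand away from their equilibrium
  points with per-index mean magnitudes 20/60/120/220/350 bp (±1…±3, +4, +5;
  capped at 350 bp; ±15% per-gene spread); repressed genes' dyads move to
  10% of their residual offset; basal genes get 3 bp symmetric jitter.
  Nucleosomes cannot slide through one another: per gene the shifted offsets
  are re-sorted, so a large shift stacks against the next static nucleosome.
  Realized sliding distances at high indices are therefore smaller than the
  nominal magnitudes; recovery tests compare against a truth replay, not the
  nominal values.

What the generator does **not** emulate: DNA sequence and MNase digestion
(no sequence-dependent bias), correlated platform errors, chromosome-scale
heterogeneity, fuzzy multi-modal nucleosomes beyond the single-site jitter
model, and partial/continuous occupancy. Passing recovery tests therefore
demonstrates that the pipeline measures what was planted under i.i.d.
platform noise — not that real cross-platform data satisfy those assumptions.

## Numerical and design choices

* Binarization unions overlapping footprints; tracks round-trip exactly
  through run-length-encoded bedGraph.
* Undefined correlations (zero variance) are excluded from means, never
  zero-filled.
* Composite-profile smoothing 31 bp, peak separation 100 bp, prominence 5% of
  range, NFR gap threshold 200 bp, LRC width step 10 bp, +1 window 150 bp,
  kernel-density bandwidth 15 bp, bootstrap 1,000 resamples at 95% — all
  config-exposed defaults.
* Every random operation takes an explicit seed; the CLI derives per-stage
  seeds from one global seed and writes a checksummed manifest.
* Default problem sizes (2,000 genes for analyses, 500 for the README
  example) were chosen so the planted effects are estimated with comfortable
  margins while a full run stays in the seconds range.

## Known limitations

Ordinal index matching breaks down under call dropout (see above). The AND
consensus is sensitive to the weakest dataset: one platform with poor
detection erases the stable track. The XOR composite inherits footprint-edge
disagreement, so its counterphase peaks are a superposition of genuine
dynamic occupancy and stable-edge noise. BDID treats platforms as exchangeable
and i.i.d., which real platforms are not. The per-gene SNR uses per-gene
signal rows; whether a composite-based variant is preferable for noisy real
data is left to the user (both are exposed).
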