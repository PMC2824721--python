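# nucconsensus

Consensus analysis of cross-platform nucleosome positioning maps.

High-resolution nucleosome maps of the *S. cerevisiae* genome measured on
different platforms (tiling arrays, early sequencing) disagree substantially —
not only because of measurement noise, but because many nucleosomes are
genuinely dynamic in vivo. `nucconsensus` integrates several independently
measured position call sets into consensus tracks that separate the two
behaviours, and then relates each class to transcription:

* **Stable track** — each call set is restructured into a binary sequence
  (1 = nucleosome-packaged base, 0 = linker) and the *n* datasets are combined
  with a logical AND: positions every experiment agrees are packaged.
* **Dynamic track** — the arithmetic mean of all C(n, 2) pairwise XOR tracks;
  at a site where *k* of *n* datasets call a nucleosome this is
  *k(n−k)/C(n,2)*, the fraction of discordant dataset pairs.
* **BDID** (binomial-distribution-induced decomposition) — treating the *n*
  datasets as i.i.d. samples with per-site occupancy frequency *p(i)*, the
  probability profiles *P{X(i)=k} = C(n,k) p(i)^k (1−p(i))^(n−k)* for
  *k = 0…n*; *k = 0* maps nucleosome-free regions (NFRs), intermediate *k*
  the dynamic class, *k ≥ n−1* the stable class.

Downstream analyses anchored at the TSS/TTS of annotated genes: composite
profiles and their peaks (the *stable equilibrium points*), the ~165–166 bp
nucleosome repeat; per-gene *measurability* (mean pairwise Pearson *r* of the
datasets in a ±800 bp TSS window) and positioning *SNR* (10·log₁₀(S/D) dB,
where S and D are the mean squared stable and dynamic signals); k-means
clustering of promoter occupancy patterns; local regulatory correlation (LRC)
maps between windowed occupancy and gene properties; the +1-nucleosome/TSS
distance and its TATA dependence; and convergent/divergent nucleosome sliding
between a normal and a heat-shock condition, measured against the stable
equilibrium points.

Because the original six published yeast datasets are not bundled, the package
ships a first-class synthetic generator (`nucconsensus.synthgenome`) that
plants a known nucleosome architecture — phased stable arrays, promoter and
TTS NFRs, intermittent counterphase dynamic nucleosomes, TATA-dependent +1
offsets, promoter archetypes, property couplings and activation-dependent
heat-shock dyad shifts — and samples platform-like call sets from it, so every
stage is testable against ground truth.

## Worked example

```python
from nucconsensus.pipeline import simulate_scenario, integrate_scenario, sliding_report
from nucconsensus.profiles import peak_spacing
from nucconsensus.regulation import tata_contrast

scn = simulate_scenario(n_genes=500, seed=0)   # six platforms + heat shock
ana = integrate_scenario(scn)                  # binarize, AND/XOR/BDID, profiles

print("stable equilibrium points:", list(ana.stable_peaks.offsets))
sp = peak_spacing(ana.stable_peaks, gap_threshold=200)
print("mean repeat length: %.1f bp" % sp.mean_spacing)

tc = tata_contrast(scn.annotation, ana.stable_track, n_boot=100, seed=0)
print("+1 dyad-TSS: TATA %.1f bp, TATA-free %.1f bp" %
      (tc.plus_one_offset_tata, tc.plus_one_offset_tatafree))

_, _, disp, conv, enrich = sliding_report(scn, n_boot=200)
print("heat-shock enrichment p = %.2e" % enrich["p"])
```

prints

```
stable equilibrium points: [-724, -557, -392, -232, 64, 225, 389, 558, 725]
mean repeat length: 164.7 bp
+1 dyad-TSS: TATA 57.3 bp, TATA-free 64.1 bp
heat-shock enrichment p = 1.15e-40
```

The detected stable peaks recover the planted equilibrium lattice (…, −559,
−393, −228, +60, +225, +392, +559, +725 bp from the TSS) within a few bp; the
−232 → +64 gap is the promoter NFR. The +1 nucleosome sits ~58 bp downstream
of the TSS on TATA-containing promoters and ~64 bp on TATA-free ones (a ~6 bp
difference), and after heat shock, genes whose nucleosomes diverge from their
equilibrium points are overwhelmingly the transcriptionally activated ones.

## Command line

```bash
nucconsensus all --config config.yaml --out results/ [--seed N]
```

Subcommands `simulate`, `integrate`, `profile`, `metrics`, `regulation`,
`sliding` and `all` run the stages in dependency order; every stage reads its
inputs from and writes TSV/BED/bedGraph artifacts (plus a checksummed
`manifest.json`) to the output directory, so runs are reproducible and stages
can be re-run individually. The YAML config has one optional block per stage.

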