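"""End-to-end synthetic scenario: simulate, integrate, profile, analyse.

Bundles the default study conditions — six normal-condition platform call
sets sampled from one planted architecture, a matched high-fidelity
normal/heat-shock call-set pair, and the planted gene properties — and runs
the full consensus pipeline over them.  This is the object the CLI, the
recovery tests and the acceptance script all drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import integration, profiles, slidinganalysis as sliding
from .synthgenome import (
    CONDITION_PLATFORM,
    DEFAULT_PLATFORMS,
    ArchitectureParams,
    ShiftParams,
    TrueLayout,
    make_annotation,
    make_architecture,
    make_gene_properties,
    make_heat_shock_layout,
    sample_platform_callsets,
)
from .tracks_io import BinaryTrack, GenomeAnnotation, NucleosomeCallSet, RealTrack, binarize_calls

__all__ = ["SyntheticScenario", "simulate_scenario", "integrate_scenario", "ScenarioAnalysis"]


@dataclass
class SyntheticScenario:
    """Simulated inputs for one run of the consensus pipeline."""

    params: ArchitectureParams
    annotation: GenomeAnnotation
    layout: TrueLayout
    layout_hs: TrueLayout
    callsets: list[NucleosomeCallSet]
    calls_normal: NucleosomeCallSet
    calls_heat_shock: NucleosomeCallSet
    properties: pd.DataFrame
    seed: int = 0


def simulate_scenario(
    n_genes: int = 2000,
    seed: int = 0,
    params: ArchitectureParams | None = None,
    shift_params: ShiftParams | None = None,
    property_noise_sd: float = 1.0,
) -> SyntheticScenario:
    """Generate the default study conditions, all seeds derived from ``seed``."""
    base = params or ArchitectureParams()
    base = replace(base, n_genes=n_genes, seed=seed)
    annotation = make_annotation(base)
    layout = make_architecture(annotation, base)
    layout_hs = make_heat_shock_layout(layout, shift_params, seed=seed + 11)
    platform_specs = [replace(s, seed=seed * 1000 + s.seed) for s in DEFAULT_PLATFORMS]
    callsets = sample_platform_callsets(layout, platform_specs)
    cond_n = replace(CONDITION_PLATFORM, name="condition_normal", seed=seed * 1000 + 201)
    cond_h = replace(
        CONDITION_PLATFORM, name="condition_heat_shock", condition="heat_shock",
        seed=seed * 1000 + 202,
    )
    calls_normal = sample_platform_callsets(layout, [cond_n])[0]
    calls_heat_shock = sample_platform_callsets(layout_hs, [cond_h])[0]
    properties = make_gene_properties(layout, noise_sd=property_noise_sd, seed=seed + 17)
    return SyntheticScenario(
        params=base,
        annotation=annotation,
        layout=layout,
        layout_hs=layout_hs,
        callsets=callsets,
        calls_normal=calls_normal,
        calls_heat_shock=calls_heat_shock,
        properties=properties,
        seed=seed,
    )


@dataclass
class ScenarioAnalysis:
    """Derived consensus tracks and headline analyses for one scenario."""

    scenario: SyntheticScenario
    binary_tracks: list[BinaryTrack]
    stable_track: BinaryTrack
    dynamic_track: RealTrack
    bdid: integration.BDIDProfiles
    stable_profile: profiles.CompositeProfile = None
    dynamic_profile: profiles.CompositeProfile = None
    stable_dyad_profile: profiles.CompositeProfile = None
    stable_peaks: profiles.PeakSet = None
    dynamic_peaks: profiles.PeakSet = None
    stable_matrix: profiles.GeneMatrix = None
    dynamic_matrix: profiles.GeneMatrix = None
    extras: dict = field(default_factory=dict)


def integrate_scenario(scn: SyntheticScenario, flank: int = 800) -> ScenarioAnalysis:
    """Binarize the platform call sets and build all consensus tracks/profiles."""
    sizes = scn.annotation.chrom_sizes
    tracks = [
        binarize_calls(cs, sizes, footprint=scn.params.footprint) for cs in scn.callsets
    ]
    stable = integration.logical_and_stack(tracks)
    dynamic = integration.xor_mean_stack(tracks)
    bdid = integration.bdid_decompose(tracks)
    ana = ScenarioAnalysis(
        scenario=scn,
        binary_tracks=tracks,
        stable_track=stable,
        dynamic_track=dynamic,
        bdid=bdid,
    )
    ana.stable_matrix = profiles.align_to_anchor(stable, scn.annotation, "tss", flank)
    ana.dynamic_matrix = profiles.align_to_anchor(dynamic, scn.annotation, "tss", flank)
    ana.stable_profile = profiles.composite_profile(ana.stable_matrix)
    ana.dynamic_profile = profiles.composite_profile(ana.dynamic_matrix)
    # stable equilibrium points are localized on the consensus dyad density:
    # the AND coverage composite has ~147 bp flat-topped plateaus whose
    # maxima are poorly determined, while consensus-call dyads peak sharply
    consensus = integration.stable_calls_from_track(stable)
    density = integration.dyad_density_track(consensus, scn.annotation.chrom_sizes)
    ana.stable_dyad_profile = profiles.composite_profile(
        profiles.align_to_anchor(density, scn.annotation, "tss", flank)
    )
    ana.stable_peaks = profiles.detect_peaks(ana.stable_dyad_profile)
    ana.dynamic_peaks = profiles.detect_peaks(ana.dynamic_profile)
    ana.extras["stable_consensus_calls"] = consensus
    return ana


def sliding_report(scn: SyntheticScenario, n_boot: int = 500):
    """Run the full two-condition sliding analysis on a scenario."""
    before = sliding.index_nucleosomes(scn.calls_normal, scn.annotation)
    after = sliding.index_nucleosomes(scn.calls_heat_shock, scn.annotation)
    classes = scn.annotation.genes.set_index("gene_id")["gene_class"]
    disp = sliding.displacement_by_index(before, after, classes, n_boot=n_boot, seed=scn.seed + 23)
    eq = scn.layout.metadata["planted_offsets"]
    conv = sliding.equilibrium_convergence(before, after, eq, classes)
    enrich = sliding.pattern_enrichment_test(conv.gene_patterns, classes)
    return before, after, disp, conv, enrich
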