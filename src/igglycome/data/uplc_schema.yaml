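# Default total-IgG HILIC-UPLC schema: 24 chromatographic glycan peaks.
#
# Each peak is annotated with the structural features of its dominant
# (most abundant) 2-AB labelled glycan structure, following the
# conventional IgG glycome peak assignment: number of antennary
# galactoses, sialic acids, bisecting GlcNAc and core fucose.  Derived
# traits are computed from these annotations, so the exact trait formulas
# can be changed by editing this file, without touching code.
#
# `weight` is the baseline relative abundance used by the synthetic-data
# generator (normalized within each galactosylation class at run time); it
# plays no role in trait derivation.
peaks:
  - {label: GP1,  structure: "FA1",      galactoses: 0, sialic_acids: 0, bisecting: false, core_fucose: true,  weight: 0.2}
  - {label: GP2,  structure: "A2",       galactoses: 0, sialic_acids: 0, bisecting: false, core_fucose: false, weight: 0.5}
  - {label: GP3,  structure: "A2B",      galactoses: 0, sialic_acids: 0, bisecting: true,  core_fucose: false, weight: 0.3}
  - {label: GP4,  structure: "FA2",      galactoses: 0, sialic_acids: 0, bisecting: false, core_fucose: true,  weight: 19.0}
  - {label: GP5,  structure: "FA2B",     galactoses: 0, sialic_acids: 0, bisecting: true,  core_fucose: true,  weight: 5.0}
  - {label: GP6,  structure: "M5",       galactoses: 0, sialic_acids: 0, bisecting: false, core_fucose: false, weight: 0.3}
  - {label: GP7,  structure: "A2[6]G1",  galactoses: 1, sialic_acids: 0, bisecting: false, core_fucose: false, weight: 0.5}
  - {label: GP8,  structure: "A2[3]G1",  galactoses: 1, sialic_acids: 0, bisecting: false, core_fucose: false, weight: 0.3}
  - {label: GP9,  structure: "FA2[6]G1", galactoses: 1, sialic_acids: 0, bisecting: false, core_fucose: true,  weight: 17.0}
  - {label: GP10, structure: "FA2[3]G1", galactoses: 1, sialic_acids: 0, bisecting: false, core_fucose: true,  weight: 7.0}
  - {label: GP11, structure: "FA2[6]BG1", galactoses: 1, sialic_acids: 0, bisecting: true, core_fucose: true,  weight: 5.0}
  - {label: GP12, structure: "A2G2",     galactoses: 2, sialic_acids: 0, bisecting: false, core_fucose: false, weight: 0.8}
  - {label: GP13, structure: "A2BG2",    galactoses: 2, sialic_acids: 0, bisecting: true,  core_fucose: false, weight: 0.4}
  - {label: GP14, structure: "FA2G2",    galactoses: 2, sialic_acids: 0, bisecting: false, core_fucose: true,  weight: 14.0}
  - {label: GP15, structure: "FA2BG2",   galactoses: 2, sialic_acids: 0, bisecting: true,  core_fucose: true,  weight: 2.5}
  - {label: GP16, structure: "FA2G1S1",  galactoses: 1, sialic_acids: 1, bisecting: false, core_fucose: true,  weight: 2.5}
  - {label: GP17, structure: "A2G2S1",   galactoses: 2, sialic_acids: 1, bisecting: false, core_fucose: false, weight: 1.0}
  - {label: GP18, structure: "FA2G2S1",  galactoses: 2, sialic_acids: 1, bisecting: false, core_fucose: true,  weight: 12.0}
  - {label: GP19, structure: "FA2BG2S1", galactoses: 2, sialic_acids: 1, bisecting: true,  core_fucose: true,  weight: 2.0}
  - {label: GP20, structure: "A2G2S2",   galactoses: 2, sialic_acids: 2, bisecting: false, core_fucose: false, weight: 0.8}
  - {label: GP21, structure: "FA2BG1S1", galactoses: 1, sialic_acids: 1, bisecting: true,  core_fucose: true,  weight: 1.0}
  - {label: GP22, structure: "A2BG2S2",  galactoses: 2, sialic_acids: 2, bisecting: true,  core_fucose: false, weight: 0.3}
  - {label: GP23, structure: "FA2G2S2",  galactoses: 2, sialic_acids: 2, bisecting: false, core_fucose: true,  weight: 5.0}
  - {label: GP24, structure: "FA2BG2S2", galactoses: 2, sialic_acids: 2, bisecting: true,  core_fucose: true,  weight: 1.5}
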