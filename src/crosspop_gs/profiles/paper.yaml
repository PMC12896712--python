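# Full-scale profile mirroring the published simulation design
# (three populations, 1095 historical generations, 50k markers,
# 725 QTL).  Long-running (hours) and not exercised by the test suite.
genome:
  n_chromosomes: 29
  total_length_cm: 2715.85
  n_markers: 50000
  n_qtl: 725
trait:
  h2: 0.42
  phenotypic_variance: 1.0
  gamma_shape: 0.4
  fixed_effect_mean: 0.0
common:                    # shared ancestral base the three breeds diverge from
  hp_phases: [[500, 400, 400]]
  mutation_rate: 2.5e-5
populations:
  A:
    # 200 for 1000 generations, expansion to 1000 over 95, then the
    # random-mating expansion cohort feeding the selected nucleus
    hp_phases: [[500, 200, 200], [95, 200, 1000], [10, 4100, 4100]]
    recent: {n_sires: 50, n_dams: 2000, n_generations: 10,
             sire_replacement: 0.6, dam_replacement: 0.3, offspring_per_dam: 1}
    mutation_rate: 2.5e-5
    missing_phenotype_rate: 0.05
  B:
    hp_phases: [[500, 500, 200], [95, 200, 1000], [10, 4300, 4300]]
    recent: {n_sires: 55, n_dams: 2100, n_generations: 10,
             sire_replacement: 0.5, dam_replacement: 0.3, offspring_per_dam: 1}
    mutation_rate: 2.5e-5
    missing_phenotype_rate: 0.05
  C:
    # ends in a contraction (terminal bottleneck), the source of PopC's
    # slow LD decay and its higher differentiation from PopA
    hp_phases: [[500, 1000, 1000], [95, 1000, 200], [10, 4500, 4500]]
    recent: {n_sires: 50, n_dams: 2200, n_generations: 10,
             sire_replacement: 0.5, dam_replacement: 0.2, offspring_per_dam: 1}
    mutation_rate: 2.5e-5
    missing_phenotype_rate: 0.05
analysis:
  fst_threshold: 0.1
  fst_estimator: wc
  fractions: [0.10, 0.15, 0.20]
  aggregate: centroid
  signal_mode: selected
  models: [gblup, ssgblup, wgblup]
  variance_components: true_simulated
  grm_blend: 0.05
  window_halfwidth: 20
replicates: 5
master_seed: 1
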