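# Desk-scale profile: the full three-population design at ~1/10 census
# size with shortened historical phases; runs in minutes.
genome:
  n_chromosomes: 5
  total_length_cm: 500.0
  n_markers: 4000
  n_qtl: 725
trait:
  h2: 0.42
  phenotypic_variance: 1.0
  gamma_shape: 0.4
  fixed_effect_mean: 0.0
common:                    # shared ancestral base the three populations branch from
  hp_phases: [[80, 200, 200]]
  mutation_rate: 2.5e-5
populations:
  A:                       # stable then expanding: fastest LD decay
    hp_phases: [[15, 150, 150], [5, 150, 500]]
    recent: {n_sires: 50, n_dams: 200, n_generations: 10,
             sire_replacement: 0.6, dam_replacement: 0.3, offspring_per_dam: 1}
    mutation_rate: 2.5e-5
    missing_phenotype_rate: 0.05
  B:                       # contracting then expanding
    hp_phases: [[15, 150, 50], [5, 50, 500]]
    recent: {n_sires: 55, n_dams: 210, n_generations: 10,
             sire_replacement: 0.5, dam_replacement: 0.3, offspring_per_dam: 1}
    mutation_rate: 2.5e-5
    missing_phenotype_rate: 0.05
  C:                       # large, then a strong terminal bottleneck: slowest LD decay
    hp_phases: [[10, 200, 200], [10, 200, 12], [2, 12, 500]]
    recent: {n_sires: 50, n_dams: 220, n_generations: 10,
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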