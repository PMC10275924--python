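# Default parameterization of the mass-rearing facility model.
#
# Anchored values come from the measured sorting performance and equipment
# quotes of the programme this model serves (marked "anchor"); everything
# else is a field-typical value for Aedes mass rearing under European cost
# conditions (marked "assumed"), chosen once and documented in
# docs/methods.md.  Costs are in euros; outputs are converted to US dollars
# at the configured rate (percent comparisons between systems are
# rate-invariant).

biology:
  eggs_per_female_per_week: 60        # assumed: ~100-egg batches, <1 gonotrophic cycle/week in cages
  hatch_rate: 0.85                    # assumed: typical for well-conditioned Aedes eggs
  survival_l1_to_pupa: 0.85           # assumed: L1 -> pupa under mass-rearing diet
  survival_pupa_to_adult: 0.95        # assumed: pupal emergence
  sex_ratio: 0.5                      # anchor: 50:50 male fraction at L1
  duration_egg_days: 7                # assumed: collection + conditioning before hatch
  duration_l1_days: 1                 # assumed: L1 stage residence
  duration_l2_l4_days: 5              # assumed: L2-L4 rearing to pupation
  duration_pupa_days: 2               # assumed: pupal stage residence
  duration_prerelease_days: 1         # assumed: adult holding before release
  adult_colony_lifespan_weeks: 4      # assumed: colony female replacement interval
  larvae_per_tray: 4000               # assumed: standard mass-rearing tray load
  trays_per_m2: 25                    # assumed: stacked rack footprint
  adults_per_cage: 10000              # assumed: mass-rearing cage load
  cages_per_m2: 1.0                   # assumed: cage footprint incl. access
  area_overhead_factor: 1.5           # assumed: corridors, labs, quality control

costs:
  eur_to_usd: 1.05                    # assumed: configurable conversion rate
  construction_cost_per_m2: 1000.0    # assumed: insectary-grade construction, EUR
  building_lifespan_years: 20         # anchor: building amortization horizon
  operating_weeks_per_year: 52        # anchor: weekly releases all year
  diet_cost_per_larva: 0.0002         # assumed: larval diet, full L1->pupa rearing
  l1_diet_fraction: 0.05              # assumed: diet share consumed by L1-only larvae
  adult_food_cost_per_adult_week: 0.0002  # assumed: sugar + blood feeding
  consumable_cost_per_released_male: 0.0002  # assumed: packaging, handling
  equipment:
    copas:                            # anchor: refurbished large-particle sorter quote
      unit_cost: 40000.0
      lifespan_years: 10
      weekly_capacity: 8640000.0      # anchor: 60 larvae/s x 40 h/week
    pupal_sorter_auto:                # anchor: automated pupal sorter quote
      unit_cost: 40000.0
      lifespan_years: 10
      weekly_capacity: 2000000.0      # assumed: pupae/week throughput
    glass_plate_station:              # assumed: manual glass-plate sorting station
      unit_cost: 500.0
      lifespan_years: 5
      weekly_capacity: 500000.0       # assumed: pupae/week per staffed station
    larval_rack:
      unit_cost: 2000.0
      lifespan_years: 10
      standing_capacity: 200000.0     # assumed: 50 trays x 4000 larvae
    adult_cage:
      unit_cost: 200.0
      lifespan_years: 5
      standing_capacity: 10000.0
  staff:
    larvae_reared_per_person_week: 5000000.0   # assumed
    adults_kept_per_person_week: 1000000.0     # assumed
    pupae_hand_sorted_per_person_week: 250000.0  # assumed: manual glass-plate rate
    males_released_per_person_week: 5000000.0  # assumed
    operators_per_sorter_unit: 0.5             # assumed: one operator per two machines

systems:
  size_manual:                        # manual glass-plate sorting of pupae
    sorting_stage: pupa
    male_recovery: 0.30               # anchor: ~30% male recovery for pupal size sorting
    female_contamination: 0.01        # assumed: glass-plate contamination order
    sorter: glass_plate_station
    manual_sort: true
    n_filter_colonies: 0
    n_rearing_colonies: 1
  size_auto:                          # robotic glass-plate sorting of pupae
    sorting_stage: pupa
    male_recovery: 0.30               # assumed: same biology as manual, automated handling
    female_contamination: 0.003
    sorter: pupal_sorter_auto
    manual_sort: false
    n_filter_colonies: 0
    n_rearing_colonies: 1
  gss:                                # single sexing strain, COPAS sort of L1
    sorting_stage: l1
    male_recovery: 0.696              # anchor: measured COPAS recovery at 60 larvae/s
    female_contamination: 0.0001      # anchor: recombination-limited contamination floor
    sorter: copas
    manual_sort: false
    n_filter_colonies: 1
    n_rearing_colonies: 1
    filter_copas_recovery: 0.696      # anchor: same sorter pass in filter colonies
    filter_pupal_recovery: 0.9        # assumed: pupal-stage re-check retention
  gss_cs:                             # two strains crossed for non-transgenic males
    sorting_stage: l1
    male_recovery: 0.696
    female_contamination: 0.001       # anchor: crossing-scheme contamination = recombination rate
    sorter: copas
    manual_sort: false
    n_filter_colonies: 2
    n_rearing_colonies: 2
    filter_copas_recovery: 0.696
    filter_pupal_recovery: 0.9
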