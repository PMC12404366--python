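# Pineapple comprehensive-quality index system: four first-level criteria,
# fifteen second-level indicators, the expert pairwise-comparison (judgment)
# matrices for each level, and the published entropy values of the 23-sample
# pineapple study for cross-checking the objective-weight identity.
#
# Orientation conventions: freshness is scored so that higher is better
# (shiny, full flesh scores 8-10); peculiar taste is scored so that LOWER is
# better (rich fragrance, no off-flavour scores 0-2), hence cost; mechanical
# damage ratio is cost; the sugar-acid ratio is an interval indicator with a
# well-balanced sensory range of [8, 20].
name: pineapple

groups:
  - id: eating
    label: eating quality
  - id: processing
    label: processing quality
  - id: nutrition
    label: nutritional quality
  - id: commodity
    label: commodity quality

indicators:
  - id: freshness
    label: fresh degree
    group: eating
    orientation: benefit
    units: sensory score (0-10)
  - id: peculiar_taste
    label: peculiar taste
    group: eating
    orientation: cost
    units: sensory score (0-10)
  - id: peel_color_l
    label: peel color L
    group: eating
    orientation: benefit
    units: CIELAB L*
  - id: sugar_acid_ratio
    label: acid-sugar ratio
    group: eating
    orientation: interval
    interval_bounds: [8, 20]
    units: dimensionless
  - id: titratable_acid
    label: titratable acid
    group: processing
    orientation: cost
    units: g/100 g
  - id: juice_yield
    label: rate of juice extracting
    group: processing
    orientation: benefit
    units: "%"
  - id: moisture
    label: moisture
    group: processing
    orientation: benefit
    units: g/100 g
  - id: polyphenol
    label: polyphenol
    group: nutrition
    orientation: benefit
    units: mg GAE/100 g
  - id: flavone
    label: flavone
    group: nutrition
    orientation: benefit
    units: mg/100 g
  - id: total_sugar
    label: total sugar
    group: nutrition
    orientation: benefit
    units: g/100 g
  - id: vitamin_c
    label: vitamin C
    group: nutrition
    orientation: benefit
    units: mg/100 g
  - id: soluble_solids
    label: soluble solid
    group: nutrition
    orientation: benefit
    units: "%"
  - id: physical_injury
    label: physical injury
    group: commodity
    orientation: cost
    units: mechanical-damage fruit ratio
  - id: fruit_weight
    label: single fruit weight
    group: commodity
    orientation: benefit
    units: g
  - id: edible_rate
    label: edible rate
    group: commodity
    orientation: benefit
    units: "%"

# Reciprocal 1-9 scale pairwise-comparison matrices. Fraction literals parse
# exactly. first_level compares the four groups; each remaining matrix
# compares the indicators within one group, rows/columns in `labels` order.
judgment_matrices:
  first_level:
    labels: [eating, processing, nutrition, commodity]
    rows:
      - [1, 9, 5, 3]
      - [1/9, 1, 1/3, 1/7]
      - [1/5, 3, 1, 1/4]
      - [1/3, 7, 4, 1]
  eating:
    labels: [freshness, peculiar_taste, peel_color_l, sugar_acid_ratio]
    rows:
      - [1, 1/5, 3, 2]
      - [5, 1, 8, 6]
      - [1/3, 1/8, 1, 1/2]
      - [1/2, 1/6, 2, 1]
  processing:
    labels: [titratable_acid, juice_yield, moisture]
    rows:
      - [1, 1/4, 1/2]
      - [4, 1, 3]
      - [2, 1/3, 1]
  nutrition:
    labels: [polyphenol, flavone, total_sugar, vitamin_c, soluble_solids]
    rows:
      - [1, 4, 4, 1/4, 3]
      - [1/4, 1, 1, 1/6, 1/2]
      - [1/4, 1, 1, 1/6, 1/2]
      - [4, 6, 6, 1, 5]
      - [1/3, 2, 2, 1/5, 1]
  commodity:
    labels: [physical_injury, fruit_weight, edible_rate]
    rows:
      - [1, 3, 5]
      - [1/3, 1, 2]
      - [1/5, 1/2, 1]

# Shannon entropies H_j published for the 23-sample pineapple study (n = 23,
# oriented min-max matrix). Used to cross-check the objective-weight identity
# beta_j = (1 - H_j) / sum_k (1 - H_k) independently of the raw samples.
published_entropy:
  freshness: 0.9967
  peculiar_taste: 0.9551
  peel_color_l: 0.9941
  sugar_acid_ratio: 0.9593
  titratable_acid: 0.9961
  juice_yield: 0.9992
  moisture: 0.9998
  polyphenol: 0.9891
  flavone: 0.9967
  total_sugar: 0.9946
  vitamin_c: 0.9822
  soluble_solids: 0.996
  physical_injury: 0.9228
  fruit_weight: 0.9756
  edible_rate: 0.9994
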