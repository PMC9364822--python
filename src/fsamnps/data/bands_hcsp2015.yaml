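# FSAm-NPS point-allocation grids (2015 HCSP modification of the UK FSA
# nutrient profiling system, the algorithm underlying the Nutri-Score label).
#
# Each component maps to an ordered list of [threshold, points] pairs: a food
# earns the points of the highest threshold its per-100 g/ml content STRICTLY
# exceeds (value > threshold), else 0.  "A" components (energy, sugars,
# saturated fat, sodium) are capped at 10 points each; "C" components (fiber,
# protein, fruit/vegetable/legume/nut/oil percentage) at 5 (10 for beverage
# fvln).
version: hcsp-2015
protein_cap_threshold: 11   # A-subtotal at/above which protein points are
                            # conditionally discarded (unless fvln is maximal
                            # or the food is cheese)
general:
  energy:   # kJ per 100 g
    [[335, 1], [670, 2], [1005, 3], [1340, 4], [1675, 5],
     [2010, 6], [2345, 7], [2680, 8], [3015, 9], [3350, 10]]
  sugars:   # g per 100 g
    [[4.5, 1], [9, 2], [13.5, 3], [18, 4], [22.5, 5],
     [27, 6], [31, 7], [36, 8], [40, 9], [45, 10]]
  satfat:   # g per 100 g
    [[1, 1], [2, 2], [3, 3], [4, 4], [5, 5],
     [6, 6], [7, 7], [8, 8], [9, 9], [10, 10]]
  sodium:   # mg per 100 g
    [[90, 1], [180, 2], [270, 3], [360, 4], [450, 5],
     [540, 6], [630, 7], [720, 8], [810, 9], [900, 10]]
  fiber:    # g per 100 g (AOAC)
    [[0.7, 1], [1.4, 2], [2.1, 3], [2.8, 4], [3.5, 5]]
  protein:  # g per 100 g
    [[1.6, 1], [3.2, 2], [4.8, 3], [6.4, 4], [8, 5]]
  fvln:     # % fruits, vegetables, legumes, nuts, rapeseed/walnut/olive oil
    [[40, 1], [60, 2], [80, 5]]
beverage:   # overrides for drinks other than milk; unlisted components fall
            # back to the general grid
  energy:   # kJ per 100 ml
    [[0, 1], [30, 2], [60, 3], [90, 4], [120, 5],
     [150, 6], [180, 7], [210, 8], [240, 9], [270, 10]]
  sugars:   # g per 100 ml
    [[0, 1], [1.5, 2], [3, 3], [4.5, 4], [6, 5],
     [7.5, 6], [9, 7], [10.5, 8], [12, 9], [13.5, 10]]
  fvln:
    [[40, 2], [60, 4], [80, 10]]
added_fat:  # saturated fat scored as 100 * satfat / total fat (%)
  satfat_ratio:
    [[10, 1], [16, 2], [22, 3], [28, 4], [34, 5],
     [40, 6], [46, 7], [52, 8], [58, 9], [64, 10]]
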