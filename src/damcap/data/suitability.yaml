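# Landcover -> forage suitability (0-5) for the four input sources.
# 0 no vegetation, 1 unsuitable, 2 barely suitable, 3 moderately suitable,
# 4 suitable, 5 preferred (deciduous/willow woodland).
# The shipped classes cover the headline table of each national dataset
# analogue; extend these maps for additional classes in your own data.
# Percent-cover bands are (low, high, value]; printed gaps between bands
# (e.g. 3-4%) are closed so every percentage maps to a value.
sources:
  os_vector:
    classes:
      Boulders: 0
      Sand: 0
      Shingle: 0
      Building: 0
      Water: 0
      Heathland: 1
      Unimproved grass: 1
      Marsh: 1
      Reeds: 2
      Shrub and heathland: 2
      Coniferous woodland: 3
      Shrub and marsh: 3
      Shrub and unimproved: 3
      Broadleaf woodland: 5
      Shrub: 5
      Mixed woodland: 5
      Orchard: 5
  lcm_raster:
    classes:
      "0": 0    # water / rock / saltmarsh / (sub)urban  (coded rasters)
      "1": 1    # acid, calcareous or improved grassland, heather, bog
      "2": 2    # arable and horticulture, neutral grassland
      "3": 3    # coniferous woodland
      "5": 5    # broadleaf woodland
  lcm_vector:
    classes:
      Water: 0
      Rock: 0
      Saltmarsh: 0
      Suburban: 0
      Urban: 0
      Acid grassland: 1
      Calcareous grassland: 1
      Heather: 1
      Improved grassland: 1
      Bog: 1
      Arable and horticulture: 2
      Neutral grassland: 2
      Coniferous woodland: 3
      Broadleaf woodland: 5
  tcd_raster:
    bands:
      - [0, 1, 0]
      - [1, 3, 1]
      - [3, 10, 2]
      - [10, 50, 3]
      - [50, 100, 4]
  wlff_vector:
    classes:
      Woody linear feature: 4
    default: 4
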