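"""Integer land-cover codes shared by the generator, resistance and
assessment modules (CLCD-style classes plus an explicit open-sea code)."""

CROPLAND = 1
FOREST = 2
GRASSLAND = 3
WATER = 4
WETLAND = 5
URBAN = 6
BARE = 7
SEA = 9

LANDCOVER_NAMES = {
    CROPLAND: "cropland",
    FOREST: "forest",
    GRASSLAND: "grassland",
    WATER: "water",
    WETLAND: "wetland",
    URBAN: "urban",
    BARE: "bare",
    SEA: "sea",
}
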