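# Example raw-ecosystem-name -> category mapping.
#
# Sparse raw types are folded into a larger, hydrologically similar
# category (e.g. fjords into the continental shelf).  This file is an
# illustrative guess covering all seven categories; real analyses
# should supply the mapping used when the dataset was compiled.
lake: lake
freshwater lake: lake
pond: lake
reservoir: reservoir
impoundment: reservoir
farm pond: reservoir
inland_wetland: inland_wetland
inland wetland: inland_wetland
freshwater marsh: inland_wetland
coastal_wetland: coastal_wetland
coastal wetland: coastal_wetland
salt marsh: coastal_wetland
tidal marsh: coastal_wetland
seagrass meadow: coastal_wetland
lagoon: lagoon
coastal lagoon: lagoon
mangrove: mangrove
mangrove forest: mangrove
continental_shelf: continental_shelf
continental shelf: continental_shelf
shelf sea: continental_shelf
inland sea: continental_shelf
fjord: continental_shelf
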