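# Nine phylogenetically independent cross-system contrasts on the packaged
# mammal tree.  Each entry pairs one X1X2Y cluster unit with one XY1Y2 cluster
# unit; the tree paths connecting the nine pairs share no edges.  Pair order
# follows the tree from the rodent clade outward.
pairs:
  - {x1x2y: Mus_X1X2Y, xy1y2: Mus_XY1Y2}
  - {x1x2y: Vandeleuria_X1X2Y, xy1y2: Taterillus_XY1Y2}
  - {x1x2y: Deltamys_X1X2Y, xy1y2: Sorex_XY1Y2}
  - {x1x2y: Choeroniscus_X1X2Y, xy1y2: Carolia+Carollia_XY1Y2}
  - {x1x2y: Mesophylla_X1X2Y, xy1y2: Artibeus_XY1Y2}
  - {x1x2y: Tragelaphus_X1X2Y, xy1y2: Gazella_XY1Y2}
  - {x1x2y: Herpestes_X1X2Y, xy1y2: Muntiacus_XY1Y2}
  - {x1x2y: Choloepus_X1X2Y, xy1y2: Potorous_XY1Y2}
  - {x1x2y: Lagorchestes_X1X2Y, xy1y2: Wallabia_XY1Y2}
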