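# Reference high-quality-index (HQI) accession lists.
#
# HQI-8 lists the published medoids of the eight AAindex1 clusters
# (electric properties, hydrophobicity, alpha/turn propensities,
# physico-chemical properties, residue propensity, composition,
# beta propensity, intrinsic propensities).
#
# The HQI-24 and HQI-40 member lists were published only as supplementary
# material and are not redistributed here; reproduce them with
# ptmstar.indices.select_hqi (tiers 3 and 5) on a clustered collection.
HQI-8:
  - BLAM930101
  - BIOV880101
  - MAXF760101
  - TSAJ990101
  - NAKH920108
  - CEDJ970104
  - LIFS790101
  - MIYS990104
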