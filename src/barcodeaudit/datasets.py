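"""Published summary tables from a continental-scale barcode library audit.

These are the printed group summaries from a comprehensive COI barcode
survey of the Canadian owlet-moth (Noctuoidea) fauna — roughly 1,541
species and 30,000 sequences.  The raw sequence data live in public
repositories and are not bundled here; the tables below are the published
*aggregates* (per-species nearest-neighbour distances of the introduced
species, the host-plant median-test contingency, and the ANOVA sums of
squares), retained so the statistical toolkit can be exercised against
real numbers without any download.
"""

from __future__ import annotations

#: Nearest-neighbour K2P distances (percent) of the 22 introduced noctuoid
#: species with barcode coverage, one value per species.
INTRODUCED_SPECIES_NN = {
    "Agrochola lota": 6.40,
    "Amphipyra tragopoginis": 6.28,
    "Apamea unanimis": 4.07,
    "Calophasia lunula": 6.51,
    "Caradrina morpheus": 4.14,
    "Cerapteryx graminis": 4.22,
    "Chrysodeixis chalcites": 5.39,
    "Cucullia umbratica": 4.68,
    "Garella nilotica": 7.85,
    "Hydraecia micacea": 1.72,
    "Lateroligia ophiogramma": 4.67,
    "Leucoma salicis": 12.07,
    "Lymantria dispar": 10.08,
    "Noctua comes": 5.23,
    "Noctua pronuba": 4.54,
    "Oligia strigilis": 4.82,
    "Rhizedra lutosa": 6.21,
    "Spodoptera exigua": 5.72,
    "Tathorhynchus exsiccata": 6.86,
    "Trichoplusia ni": 6.22,
    "Tyria jacobaeae": 7.73,
    "Xestia xanthographa": 4.13,
}

#: Mood's-median-test contingency for NN distance by larval host-plant
#: category (1,196 species): (n above pooled median, n at or below).
HOST_PLANT_MEDIAN_CONTINGENCY = {
    "grass_herb": (271, 185),
    "tree_shrub": (230, 226),
    "detritus_fungi_lichen": (51, 22),
    "generalist": (46, 165),
}

#: Printed ANOVA sums of squares / df for NN distance by host-plant
#: category: the full unequal-n design and the balanced 73-per-group
#: subsample.
HOST_PLANT_ANOVA_SUMS = {
    "unequal": {"ss_between": 362.48, "df_between": 3,
                "ss_within": 5613.26, "df_within": 1192},
    "balanced": {"ss_between": 99.15, "df_between": 3,
                 "ss_within": 1310.91, "df_within": 288},
}

#: Printed per-group counts and sums of NN distance (percent) by host-plant
#: category, full design: (count, sum).
HOST_PLANT_GROUP_SUMS = {
    "grass_herb": (456, 1608.29),
    "tree_shrub": (456, 1518.13),
    "detritus_fungi_lichen": (73, 291.51),
    "generalist": (211, 440.53),
}

#: Library-wide species/sharing counts at the national scale.
NATIONAL_COUNTS = {"n_species": 1541, "n_sharing": 158}

#: Regional counts: (diagnosable species, barcoded species).
REGIONAL_COUNTS = {
    "New Brunswick/Nova Scotia": (369, 387),
    "Ontario": (592, 617),
    "British Columbia": (637, 668),
}
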