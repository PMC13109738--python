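"""Published summary statistics for the three-species Kim Bang frog diet study.

These constants transcribe the printed summary tables of the field study the
package reproduces: per-species dietary composition percentages (%F, %N, %V,
IRI per prey category), per-stomach prey-count and prey-size summaries,
predator morphometrics, and the pairwise Pearson correlations among
morphometric traits.  They serve two roles:

* defaults for :mod:`dietniche.synthetic`, so generated datasets carry the
  statistical structure of the study without any download, and
* desk-scale inputs for recomputing the study's niche indices (Levins
  breadth, Pianka overlap, Simpson heterogeneity) from the printed numbers.

All percentages are as printed (0-100 scale, 2 decimals).
"""

from __future__ import annotations

MICROHYLA_HEYMONSI = "Microhyla heymonsi"
MICROHYLA_MUKHLESURI = "Microhyla mukhlesuri"
OCCIDOZYGA_LINGNANICA = "Occidozyga lingnanica"

SPECIES = (MICROHYLA_HEYMONSI, MICROHYLA_MUKHLESURI, OCCIDOZYGA_LINGNANICA)

#: stomachs flushed per species
N_STOMACHS = {
    MICROHYLA_HEYMONSI: 26,
    MICROHYLA_MUKHLESURI: 42,
    OCCIDOZYGA_LINGNANICA: 48,
}

#: total prey items recovered per species
N_ITEMS = {
    MICROHYLA_HEYMONSI: 501,
    MICROHYLA_MUKHLESURI: 878,
    OCCIDOZYGA_LINGNANICA: 280,
}

#: males / females flushed (sex ratio for the generator)
SEX_COUNTS = {
    MICROHYLA_HEYMONSI: (6, 20),
    MICROHYLA_MUKHLESURI: (31, 11),
    OCCIDOZYGA_LINGNANICA: (33, 15),
}

# ---------------------------------------------------------------------------
# Dietary composition at the finest identified level (family / larval bin /
# residual bin).  Rows: (order, category, pctF, pctN, pctV, IRI).
# ---------------------------------------------------------------------------

COMPOSITION = {
    MICROHYLA_HEYMONSI: [
        ("Coleoptera", "Carabidae", 2.33, 0.20, 0.12, 0.88),
        ("Coleoptera", "Curculionidae", 2.33, 0.20, 0.09, 0.87),
        ("Coleoptera", "Hydrophilidae", 2.33, 0.20, 0.09, 0.87),
        ("Coleoptera", "Larvae Coleoptera", 6.98, 0.60, 0.20, 2.59),
        ("Coleoptera", "Nitidulidae", 2.33, 0.20, 0.03, 0.85),
        ("Coleoptera", "Phalacridae", 2.33, 0.20, 0.99, 1.17),
        ("Hymenoptera", "Formicidae", 25.58, 6.19, 3.52, 11.76),
        ("Isoptera", "Termitidae", 55.81, 92.22, 94.94, 80.99),
    ],
    MICROHYLA_MUKHLESURI: [
        ("Araneae", "Araneae", 1.14, 0.11, 0.05, 0.43),
        ("Coleoptera", "Chrysomelidae", 1.14, 0.11, 0.05, 0.43),
        ("Coleoptera", "Hydrophilidae", 6.82, 1.48, 0.73, 3.01),
        ("Coleoptera", "Larvae Coleoptera", 7.95, 1.37, 8.89, 6.07),
        ("Coleoptera", "Nitidulidae", 1.14, 0.11, 0.02, 0.42),
        ("Coleoptera", "Phalacridae", 5.68, 0.80, 1.10, 2.52),
        ("Coleoptera", "Other Coleoptera", 1.14, 0.11, 0.07, 0.44),
        ("Hemiptera", "Mesoveliidae", 1.14, 0.11, 0.11, 0.45),
        ("Hymenoptera", "Formicidae", 31.82, 19.82, 10.32, 20.65),
        ("Isoptera", "Termitidae", 40.91, 75.85, 78.63, 65.13),
        ("Thysanoptera", "Thripidae", 1.14, 0.11, 0.03, 0.43),
    ],
    OCCIDOZYGA_LINGNANICA: [
        ("Decapoda", "Atyidae", 1.75, 1.07, 6.31, 3.04),
        ("Isopoda", "Armadillidiidae", 1.75, 1.07, 5.26, 2.70),
        ("Gastropoda", "Gastropoda", 6.14, 3.21, 2.44, 3.93),
        ("Araneae", "Araneae", 3.51, 1.43, 1.34, 2.09),
        ("Coleoptera", "Carabidae", 0.88, 0.36, 1.80, 1.01),
        ("Coleoptera", "Dytiscidae", 0.88, 1.07, 0.19, 0.71),
        ("Coleoptera", "Hydrophilidae", 6.14, 3.57, 2.42, 4.04),
        ("Coleoptera", "Larvae Coleoptera", 12.28, 15.71, 34.04, 20.68),
        ("Coleoptera", "Nitidulidae", 5.26, 3.93, 2.31, 3.84),
        ("Coleoptera", "Phalacridae", 3.51, 1.43, 0.27, 1.73),
        ("Coleoptera", "Staphylinidae", 4.39, 2.86, 0.69, 2.64),
        ("Coleoptera", "Tenebrionidae", 0.88, 0.71, 0.37, 0.66),
        ("Coleoptera", "Other Coleoptera", 14.04, 13.93, 7.69, 11.89),
        ("Diptera", "Larvae Diptera", 1.75, 2.14, 4.18, 2.69),
        ("Diptera", "Drosophilidae", 1.75, 1.07, 0.13, 0.99),
        ("Diptera", "Culicoidea", 0.88, 0.36, 0.01, 0.41),
        ("Hemiptera", "Cicadellidae", 0.88, 0.36, 0.64, 0.63),
        ("Hemiptera", "Gerridae", 0.88, 1.43, 0.29, 0.87),
        ("Hemiptera", "Pentatomidae", 1.75, 1.07, 0.86, 1.23),
        ("Hemiptera", "Mesoveliidae", 2.63, 1.43, 0.19, 1.42),
        ("Hymenoptera", "Apidae", 0.88, 0.36, 8.02, 3.08),
        ("Hymenoptera", "Formicidae", 7.02, 6.43, 2.70, 5.38),
        ("Isoptera", "Termitidae", 7.89, 14.64, 1.76, 8.10),
        ("Lepidoptera", "Larvae Lepidoptera", 0.88, 0.36, 0.86, 0.70),
        ("Orthoptera", "Acrididae", 6.14, 13.57, 5.74, 8.48),
        ("Orthoptera", "Gryllidae", 3.51, 5.00, 2.52, 3.68),
        ("Thysanoptera", "Thripidae", 0.88, 0.36, 0.13, 0.46),
        ("Gobiiformes", "Gobiidae", 0.88, 1.07, 6.84, 2.93),
    ],
}


def category_pct_n(species: str) -> dict[str, float]:
    """Printed numeric proportion (%N) per prey category for ``species``."""
    return {cat: pn for _, cat, _, pn, _, _ in COMPOSITION[species]}


def category_orders(species: str) -> dict[str, str]:
    """Category label -> order label mapping for ``species``."""
    return {cat: order for order, cat, _, _, _, _ in COMPOSITION[species]}


# ---------------------------------------------------------------------------
# Per-stomach prey counts and pooled prey sizes: (mean, sd, min, max).
# ---------------------------------------------------------------------------

PREY_COUNT = {
    MICROHYLA_HEYMONSI: (19.27, 15.57, 1, 60),
    MICROHYLA_MUKHLESURI: (20.90, 22.58, 3, 125),
    OCCIDOZYGA_LINGNANICA: (5.83, 4.42, 1, 19),
}

PREY_WIDTH_MM = {
    MICROHYLA_HEYMONSI: (1.09, 0.19, 0.5, 2.0),
    MICROHYLA_MUKHLESURI: (0.96, 0.21, 0.5, 3.0),
    OCCIDOZYGA_LINGNANICA: (1.35, 0.72, 0.5, 5.0),
}

PREY_LENGTH_MM = {
    MICROHYLA_HEYMONSI: (2.51, 1.28, 0.5, 5.0),
    MICROHYLA_MUKHLESURI: (2.03, 1.17, 0.5, 12.0),
    OCCIDOZYGA_LINGNANICA: (3.66, 3.14, 0.5, 20.0),
}

# ---------------------------------------------------------------------------
# Morphometrics (pooled sexes): trait -> (mean, sd, min, max).
# SVL/HL/MW in mm, BM in g.
# ---------------------------------------------------------------------------

MORPHOMETRICS = {
    MICROHYLA_HEYMONSI: {
        "svl_mm": (23.45, 2.54, 19.1, 27.4),
        "hl_mm": (6.96, 0.74, 5.3, 8.1),
        "mw_mm": (5.99, 0.54, 4.9, 6.7),
        "bm_g": (1.87, 0.70, 0.72, 3.02),
    },
    MICROHYLA_MUKHLESURI: {
        "svl_mm": (22.10, 3.20, 16.2, 28.9),
        "hl_mm": (6.80, 0.86, 5.0, 9.0),
        "mw_mm": (5.64, 0.74, 4.0, 7.5),
        "bm_g": (1.32, 0.56, 0.55, 3.1),
    },
    OCCIDOZYGA_LINGNANICA: {
        "svl_mm": (24.91, 3.70, 19.0, 32.5),
        "hl_mm": (8.70, 1.05, 6.4, 10.6),
        "mw_mm": (7.61, 1.00, 5.8, 9.5),
        "bm_g": (1.96, 0.96, 0.75, 4.36),
    },
}

#: published Pearson r among (SVL, MW), (SVL, BM), (MW, BM)
MORPHO_CORRELATIONS = {
    MICROHYLA_HEYMONSI: {("svl_mm", "mw_mm"): 0.839, ("svl_mm", "bm_g"): 0.945, ("mw_mm", "bm_g"): 0.827},
    MICROHYLA_MUKHLESURI: {("svl_mm", "mw_mm"): 0.905, ("svl_mm", "bm_g"): 0.943, ("mw_mm", "bm_g"): 0.897},
    OCCIDOZYGA_LINGNANICA: {("svl_mm", "mw_mm"): 0.924, ("svl_mm", "bm_g"): 0.950, ("mw_mm", "bm_g"): 0.886},
}

#: published per-species niche summary (1-D, J', B_sta) for reference/tests
NICHE_SUMMARY = {
    MICROHYLA_MUKHLESURI: {"one_minus_D": 0.39, "J": 0.27, "B_sta": 0.06},
    MICROHYLA_HEYMONSI: {"one_minus_D": 0.15, "J": 0.12, "B_sta": 0.02},
    OCCIDOZYGA_LINGNANICA: {"one_minus_D": 0.91, "J": 0.82, "B_sta": 0.33},
}
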