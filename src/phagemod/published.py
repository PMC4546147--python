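"""Published reference values for the sequenced *Campylobacter* group II
phages and the six-phage typing panel.

These printed table values (host-range spot-assay counts, genome record
lengths, G+C contents, marker states) are inputs to the percentage and
size-difference arithmetic; they are not computed by this package.
"""

#: Host-range counts: phage -> {group: (infected, tested)}.
HOST_RANGE_COUNTS = {
    "CP68": {"all": (31, 255), "C. jejuni": (21, 227), "C. coli": (10, 18)},
    "CP75": {"all": (30, 255), "C. jejuni": (20, 227), "C. coli": (10, 18)},
    "CP84": {"all": (34, 255), "C. jejuni": (24, 227), "C. coli": (10, 18)},
    "CP7": {"all": (19, 255), "C. jejuni": (14, 227), "C. coli": (5, 18)},
    "CP83": {"all": (15, 255), "C. jejuni": (13, 227), "C. coli": (2, 18)},
    "CP21": {"all": (17, 255), "C. jejuni": (13, 227), "C. coli": (4, 18)},
    "IBB_35": {"all": (12, 90), "C. jejuni": (5, 76), "C. coli": (7, 14)},
}

#: Strains of non-host species in the panel (never lysed).
NON_HOST_TESTED = {"C. lari": 5, "C. fetus": 2, "C. sputorum": 2, "C. hyointestinalis": 1}

#: Printed percent-positive values (one decimal) for cross-checking the
#: rounding convention.
HOST_RANGE_PERCENT = {
    "CP68": {"all": 12.2, "C. jejuni": 9.3, "C. coli": 55.6},
    "CP75": {"all": 11.8, "C. jejuni": 8.8, "C. coli": 55.6},
    "CP84": {"all": 13.3, "C. jejuni": 10.6, "C. coli": 55.6},
    "CP7": {"all": 7.5, "C. jejuni": 6.2, "C. coli": 27.8},
    "CP83": {"all": 5.9, "C. jejuni": 5.7, "C. coli": 11.1},
    "CP21": {"all": 6.7, "C. jejuni": 5.7, "C. coli": 22.2},
    "IBB_35": {"all": 13.3, "C. jejuni": 6.6, "C. coli": 50.0},
}

#: Genome record lengths (bp) of the sequenced phages.
GENOME_SIZES = {"CP21": 182_761, "CP220": 177_493, "CPt10": 175_720, "IBB_35": 172_065}

#: G+C content (%) of the records.
GC_PERCENT = {"CP21": 27.2, "CP220": 27.4, "CPt10": 27.3, "IBB_35": 27.4}

#: tRNA gene identities per phage record.
TRNA_GENES = {
    "CP21": ("Thr", "Pro"),
    "CP220": ("Arg", "Tyr"),
    "CPt10": ("Arg", "Tyr"),
    "IBB_35": ("Arg", "Tyr"),
}

#: Subgroup assignments of the typing panel (A = CP220 subgroup,
#: B = CP21 subgroup; IBB_35 is an atypical CP220-subgroup member).
PHAGE_SUBGROUP = {
    "CP68": "CP220like",
    "CP75": "CP220like",
    "CP84": "CP220like",
    "CP7": "CP21like",
    "CP83": "CP21like",
    "CP21": "CP21like",
    "IBB_35": "CP220like",
}

#: GenBank/EMBL accessions of the records (for provenance; never fetched).
ACCESSIONS = {
    "CP21": "NC_019507.1",
    "CP220": "FN667788",
    "CPt10": "FN667789",
    "IBB_35": ("HM246720", "HM246721", "HM246722", "HM246723", "HM246724"),
}
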