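"""Embedded vocabularies for the synthetic registry generator.

The background-diagnosis list is a fixed set of plausible ICD-10
3-character stems covering common primary-care and specialist chapters,
deliberately excluding E78 (lipoprotein metabolism, the outcome family)
and the Z chapter (contacts with health services, excluded from the
burden count).  It exists so the unique-codes-per-person calibration
needs no external terminology download.
"""

# Default FH-panel variant frequency table used by the synthetic cohort:
# (gene, protein_change, rsid, recalled count, control count) from the
# follow-up cohort's printed variant table.
DEFAULT_VARIANT_TABLE = [
    ("APOB", "p.Arg3527Gln", "rs5742904", 20, 176),
    ("APOB", "p.Gly861Glu", "rs1663664782", 1, 0),
    ("APOB", "p.Cys4217Alafs3*", "novel", 1, 0),
    ("LDLR", "p.His250Arg", "rs1256668310", 1, 22),
    ("LDLR", "p.Leu401His", "rs121908038", 1, 2),
    ("LDLR", "p.Ala431Ser", "rs28942079", 1, 13),
    ("LDLR", "p.Arg633His", "rs754536745", 1, 0),
    ("LDLR", "p.Cys329Tyr", "rs761954844", 3, 72),
    ("LDLR", "p.Arg215Cys", "rs764042910", 2, 1),
    ("LDLR", "p.Gly396Ala", "rs766474188", 1, 0),
    ("LDLR", "p.Arg115Cys", "rs774723292", 1, 0),
    ("LDLR", "p.Val436Ala", "rs779732323", 0, 2),
    ("PCSK9", "p.Arg357Cys", "rs148562777", 1, 3),
    ("PCSK9", "p.Ala103Ser", "novel", 0, 1),
]

# LLT substances with their WHO ATC codes and common package sizes.
LLT_SUBSTANCES = {
    "atorvastatin": "C10AA05",
    "rosuvastatin": "C10AA07",
    "simvastatin": "C10AA01",
    "ezetimibe": "C10AX09",
    "fenofibrate": "C10AB05",
}

PACKAGE_SIZES = (28, 30, 98, 100)

# Plausible non-E78, non-Z ICD-10 3-character stems for background
# diagnosis burden (common infections, cardiometabolic, musculoskeletal,
# respiratory, GI, GU, neuro, sensory, dermatology, injuries, symptoms).
BACKGROUND_ICD10_STEMS = [
    "A09", "A46", "B01", "B02", "B34", "B35", "B37", "B95",
    "C44", "C50", "C61", "D12", "D17", "D22", "D23", "D25", "D50", "D64",
    "E03", "E04", "E05", "E06", "E10", "E11", "E14", "E16", "E28", "E55",
    "E66", "E79", "E83", "E87", "F10", "F17", "F32", "F33", "F41", "F43",
    "F45", "F51", "G25", "G40", "G43", "G44", "G45", "G47", "G50", "G54",
    "G56", "G62", "H00", "H02", "H04", "H10", "H25", "H26", "H35", "H40",
    "H52", "H53", "H60", "H61", "H65", "H66", "H81", "H90", "H91", "H93",
    "I10", "I11", "I20", "I21", "I25", "I34", "I44", "I48", "I49", "I50",
    "I63", "I65", "I70", "I73", "I80", "I83", "I84", "I87", "J00", "J01",
    "J02", "J03", "J04", "J06", "J11", "J18", "J20", "J30", "J31", "J32",
    "J35", "J40", "J42", "J44", "J45", "K02", "K04", "K05", "K21", "K25",
    "K26", "K29", "K30", "K40", "K52", "K57", "K58", "K59", "K63", "K76",
    "K80", "K81", "L02", "L03", "L08", "L20", "L23", "L30", "L40", "L50",
    "L60", "L70", "L72", "L82", "L84", "M10", "M13", "M15", "M16", "M17",
    "M19", "M20", "M23", "M25", "M41", "M42", "M47", "M50", "M51", "M53",
    "M54", "M65", "M70", "M75", "M77", "M79", "N10", "N18", "N20", "N30",
    "N39", "N40", "N60", "N76", "N81", "N92", "N95", "R00", "R03", "R05",
    "R07", "R10", "R11", "R12", "R13", "R20", "R21", "R25", "R31", "R32",
    "R42", "R51", "R52", "R53", "R55", "R60", "R63", "R73", "S00", "S01",
    "S06", "S13", "S20", "S42", "S52", "S61", "S62", "S72", "S82", "S83",
    "S93", "T14", "T15", "T78",
]

# Survey codebook: 40 items.  Q01-Q25 agreement statements, Q26-Q33
# healthcare ratings, Q34-Q40 categorical items.
SURVEY_CODEBOOK = (
    [{"item_id": f"Q{i:02d}", "scale": "AGREEMENT"} for i in range(1, 26)]
    + [{"item_id": f"Q{i:02d}", "scale": "RATING"} for i in range(26, 34)]
    + [{"item_id": f"Q{i:02d}", "scale": "CATEGORICAL"} for i in range(34, 41)]
)
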