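"""Observed m/z reference values for the fixture-library standards.

High-resolution (Orbitrap) quasi-molecular ions and diagnostic product
ions for the worked-example compounds, used to pin the exact-mass engine
and the fragmentation rulebase.  Precursors are compared at 5 ppm.
Fragments printed to 4 decimals are compared at 10 ppm; values reported
to only 2 decimals are compared at half a unit of the last digit
(±0.005), which is looser than 10 ppm at low m/z.
"""

# (compound, formula, species, observed precursor m/z)
PRECURSORS = [
    ("emodin", "C15H10O5", "[M-H]-", 269.0456),
    ("physcion", "C16H12O5", "[M-H]-", 283.0613),
    ("cosmosiin", "C21H20O10", "[M-H]-", 431.0988),
    ("baicalein", "C15H10O5", "[M-H]-", 269.0455),
    ("daidzein", "C15H10O4", "[M+H]+", 255.0652),
    ("naringenin", "C15H12O5", "[M-H]-", 271.0613),
    ("rutin", "C27H30O16", "[M-H]-", 609.1469),
    ("cianidanol", "C15H14O6", "[M-H]-", 289.0720),
    ("epicatechin", "C15H14O6", "[M-H]-", 289.0719),
    ("phellodendrine", "C20H24NO4", "M+", 342.1699),
    ("yuanhunine", "C21H25NO4", "[M+H]+", 356.1858),
    ("epiberberine", "C20H18NO4", "M+", 336.1230),
    ("berberine", "C20H18NO4", "M+", 336.1229),
    ("berberrubine", "C19H15NO4", "[M+H]+", 322.1075),
    ("magnoflorine", "C20H24NO4", "M+", 342.1700),
    ("magnocurarine", "C19H24NO3", "M+", 314.1751),
    ("geniposidic acid", "C16H22O10", "[M-H]-", 373.1141),
    ("rutaevine", "C26H30O9", "[M-H]-", 485.1823),
    ("ginsenoside Re", "C48H82O18", "[M-H]-", 945.5422),
    ("ginsenoside Rg1 (formate)", "C42H72O14", "[M+COOH]-", 845.4920),
    ("ginsenoside Rg1", "C42H72O14", "[M-H]-", 799.4860),
    ("chikusetsusaponin IVa", "C47H74O18", "[M-H]-", 925.4816),
    ("schizandrin A", "C24H32O6", "[M+H]+", 417.2273),
    ("angelicin", "C11H6O3", "[M+H]+", 187.0390),
    ("chlorogenic acid", "C16H18O9", "[M-H]-", 353.0881),
    ("gallic acid", "C7H6O5", "[M-H]-", 169.0142),
    ("ferulic acid", "C10H10O4", "[M-H]-", 193.0505),
    ("azelaic acid", "C9H16O4", "[M-H]-", 187.0975),
    ("echinacoside", "C35H46O20", "[M-H]-", 785.2524),
    ("acteoside", "C29H36O15", "[M-H]-", 623.1994),
    ("tubuloside A", "C37H48O21", "[M-H]-", 827.2631),
    ("phenylalanine", "C9H11NO2", "[M+H]+", 166.0864),
    ("beta-ecdysterone", "C27H44O7", "[M+H]+", 481.3162),
    ("adenosine", "C10H13N5O4", "[M+H]+", 268.1039),
    ("tetrahydroxystilbene glucoside", "C20H22O9", "[M-H]-", 405.1194),
    ("levistilide A", "C24H28O4", "[M+H]+", 381.2060),
]

# (compound, formula, species, class, [observed fragment m/z], max enum depth)
# 2-decimal fragments are matched at +-0.005 instead of 10 ppm.
FRAGMENT_LADDERS = [
    ("emodin", "C15H10O5", "[M-H]-", "anthraquinone",
     [241.0507, 225.0559, 210.0320, 197.0612], 3),
    ("physcion", "C16H12O5", "[M-H]-", "anthraquinone",
     [268.0376, 212.0477], 3),
    ("cosmosiin", "C21H20O10", "[M-H]-", "flavone",
     [269.0457, 151.0040, 117.0345, 107.0135], 3),
    ("baicalein", "C15H10O5", "[M-H]-", "flavone",
     [241.0508, 225.0559, 197.0607], 3),
    ("daidzein", "C15H10O4", "[M+H]+", "isoflavone",
     [237.0549, 227.0703, 199.0756, 137.0233], 3),
    ("naringenin", "C15H12O5", "[M-H]-", "flavanone",
     [151.0037, 119.0502, 177.0193, 107.0139], 3),
    ("rutin", "C27H30O16", "[M-H]-", "flavonol",
     [300.0273, 271.0250, 257.0457, 151.0035], 3),
    ("epicatechin", "C15H14O6", "[M-H]-", "flavanol",
     [245.08, 203.07, 123.05, 109.03], 3),
    ("phellodendrine", "C20H24NO4", "M+", "tetrahydroprotoberberine",
     [192.1021, 177.0785], 3),
    ("berberine", "C20H18NO4", "M+", "protoberberine",
     [320.09, 306.08, 292.10, 278.08], 3),
    ("berberrubine", "C19H15NO4", "[M+H]+", "protoberberine",
     [307.0841, 292.0593, 279.0891, 264.0665, 251.0947], 3),
    ("magnoflorine", "C20H24NO4", "M+", "aporphine",
     [297.1123, 282.0882, 265.0859, 237.0906], 3),
    ("magnocurarine", "C19H24NO3", "M+", "benzylisoquinoline",
     [269.1173, 237.0909, 107.0496], 3),
    ("geniposidic acid", "C16H22O10", "[M-H]-", "iridoid",
     [211.0612, 167.0713, 149.0607, 123.0451], 4),
    ("ginsenoside Re", "C48H82O18", "[M-H]-", "triterpenoid_saponin",
     [783.4907, 637.4339, 475.3798], 3),
    ("ginsenoside Rg1", "C42H72O14", "[M-H]-", "triterpenoid_saponin",
     [637.4330, 475.3802, 391.2874], 3),
    ("schizandrin A", "C24H32O6", "[M+H]+", "lignan",
     [402.2037, 386.2092, 347.1488], 3),
    ("angelicin", "C11H6O3", "[M+H]+", "coumarin",
     [159.04, 143.05, 131.05, 115.05], 3),
    ("chlorogenic acid", "C16H18O9", "[M-H]-", "quinic_acid_derivative",
     [191.06, 179.04, 173.05, 135.05], 3),
    ("gallic acid", "C7H6O5", "[M-H]-", "phenolic_acid",
     [125.0244, 97.0295, 69.0347], 3),
    ("ferulic acid", "C10H10O4", "[M-H]-", "phenolic_acid",
     [178.0271, 149.0608, 134.0374], 3),
    ("azelaic acid", "C9H16O4", "[M-H]-", "aliphatic_acid",
     [169.0870, 143.1077, 125.0972], 3),
    ("echinacoside", "C35H46O20", "[M-H]-", "phenylethanoid_glycoside",
     [623.2195, 477.1642, 315.1101], 3),
    ("acteoside", "C29H36O15", "[M-H]-", "phenylethanoid_glycoside",
     [461.1646, 315.1086, 135.0452], 4),
    ("phenylalanine", "C9H11NO2", "[M+H]+", "amino_acid",
     [149.0594, 120.0810, 103.0546], 3),
    ("beta-ecdysterone", "C27H44O7", "[M+H]+", "steroid",
     [463.3061, 319.1910, 301.1805], 3),
    ("adenosine", "C10H13N5O4", "[M+H]+", "nucleoside",
     [136.0619, 119.0356], 3),
    ("tetrahydroxystilbene glucoside", "C20H22O9", "[M-H]-", "stilbene",
     [243.0663, 225.0559, 215.0714, 137.0244, 93.0346], 3),
    ("levistilide A", "C24H28O4", "[M+H]+", "phthalide",
     [191.1068, 173.0962, 149.0598, 135.0441], 3),
]


def fragment_matches(observed: float, theoretical: float) -> bool:
    """Printed-precision-aware match: 10 ppm for 4-decimal values; for
    2-decimal values, half a unit of the last printed digit plus the
    10 ppm matching tolerance (the true observed value may sit anywhere
    in the printed rounding interval)."""
    text = f"{observed!r}"
    decimals = len(text.split(".")[1]) if "." in text else 0
    if decimals <= 2:
        return abs(observed - theoretical) <= 0.005 + theoretical * 1e-5
    return abs(observed - theoretical) / theoretical * 1e6 <= 10.0
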