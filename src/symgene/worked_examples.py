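"""Reference data for the worked evaluation examples.

Two published ranked candidate-gene lists — the 46 headache candidates and
the 83 hemiplegia candidates scoring above the 0.01 potential-gene cutoff on
a 14,221-gene interaction network — together with the benchmark sets they
are scored against and the muscle-cramp enrichment arithmetic.

The benchmarks are partly reconstructed: only some members of the curated
sets are public.  Unnamed members are filled with SYNTH-* placeholder
identifiers (synthetic stand-ins that by construction match nothing in the
candidate lists), which leaves every overlap count, and hence every recall,
exactly as published.
"""

from __future__ import annotations

from .evaluation import BenchmarkSet

__all__ = [
    "HEADACHE_TOP46",
    "HEMIPLEGIA_TOP83",
    "headache_benchmark",
    "hemiplegia_benchmark",
    "MUSCLE_CRAMP_ENRICHMENT",
    "UNIVERSE_SIZE",
]

#: Number of genes in the interaction network underlying the examples.
UNIVERSE_SIZE = 14_221

#: Top-ranked headache candidates (gene, propagation score), best first.
HEADACHE_TOP46: list[tuple[str, float]] = [
    ("CALCA", 0.12828040612489), ("F2", 0.12201692087326),
    ("TGFBR2", 0.12033672267710), ("TNF", 0.11489921901213),
    ("ESR1", 0.11394663869964), ("KCNK18", 0.11171558541349),
    ("HTR2A", 0.10968115391880), ("EDNRA", 0.10800919199361),
    ("TREX1", 0.10295846965404), ("MTHFR", 0.10278770151638),
    ("CALCRL", 0.02849332330671), ("RAMP2", 0.02819497378019),
    ("RAMP1", 0.02816780187933), ("EDN3", 0.02015371056218),
    ("NAA38", 0.01897112176120), ("GNA11", 0.01715273254725),
    ("PROZ", 0.01677771421601), ("NRD1", 0.01533854606373),
    ("EDN1", 0.01522967177446), ("NT5DC3", 0.01477167543805),
    ("PDIK1L", 0.01477167543805), ("PON2", 0.01413140552619),
    ("SLC31A2", 0.01392606686194), ("RP11-9H12.2", 0.01392606686194),
    ("ATP2B2", 0.01342703847737), ("PROC", 0.01319213392192),
    ("TGFBR1", 0.01314425880888), ("F2RL3", 0.01305473906526),
    ("MRPL28", 0.01303120114399), ("RP1-90J20.6", 0.01292643824309),
    ("NDUFB10", 0.01268903908242), ("GRK6", 0.01178478736965),
    ("BBS4", 0.01167226005919), ("THBD", 0.01165325302184),
    ("RAMP3", 0.01155667772559), ("HSP90B3P", 0.01154759481953),
    ("ATP2B4", 0.01147183196121), ("GGCX", 0.01145977743914),
    ("BBS1", 0.01135926399377), ("NME3", 0.01105404047118),
    ("F9", 0.01092877796805), ("AKR7A2", 0.01081719314504),
    ("TCTEX1D4", 0.01078978137476), ("GP5", 0.01063032851227),
    ("SERPINA5", 0.01041954082501), ("PROS1", 0.01034320224653),
]

#: Top-ranked hemiplegia candidates (gene, propagation score), best first.
HEMIPLEGIA_TOP83: list[tuple[str, float]] = [
    ("HMOX1", 0.1332389455434), ("MMP9", 0.1287040668111),
    ("COL4A1", 0.1243046971781), ("SERPIND1", 0.1195621966536),
    ("PLAT", 0.1133487392385), ("OFD1", 0.1121152624575),
    ("CDKN1A", 0.1107796508251), ("STAT3", 0.1106360535810),
    ("HDAC3", 0.1104973436194), ("CACNA1A", 0.1072041148709),
    ("PGK1", 0.1041298451985), ("TREX1", 0.1033025393792),
    ("MTHFR", 0.1028354996936), ("ATP1A2", 0.1023789578124),
    ("SCN1A", 0.1019561553063), ("INPP5E", 0.1005153381688),
    ("BLVRB", 0.0399295586077), ("CTA-286B10.6", 0.0241333799518),
    ("POR", 0.0229706000329), ("COL4A2", 0.0203674650216),
    ("NAA38", 0.0192928165139), ("THBS2", 0.0186100092167),
    ("SAA4", 0.0176962732383), ("F2", 0.0172012123620),
    ("CACNB1", 0.0165565034731), ("COL4A4", 0.0164204509392),
    ("FN1", 0.0161953766962), ("TPT1", 0.0159187987328),
    ("COL4A3", 0.0159043555825), ("SERPINE2", 0.0158807849607),
    ("HABP2", 0.0155572576434), ("COL4A6", 0.0154901122445),
    ("COL4A5", 0.0153811800445), ("SAA2", 0.0151416061199),
    ("XXyac-YX65C7_A.1", 0.0148026704536), ("PLG", 0.0144321310724),
    ("MATN2", 0.0144194792723), ("OSM", 0.0142128473336),
    ("SNTA1", 0.0142116180479), ("RECK", 0.0140016715074),
    ("FBLN2", 0.0137418115855), ("COCH", 0.0137176242361),
    ("MMP10", 0.0135697895912), ("ELANE", 0.0134913849548),
    ("THBS1", 0.0133469773733), ("CACNB4", 0.0132782710879),
    ("KLK6", 0.0131043482021), ("CXCL6", 0.0130491204825),
    ("CXCL1", 0.0130308002686), ("TGFBI", 0.0129966667251),
    ("MMP26", 0.0128881745922), ("BMP3", 0.0128183446929),
    ("UFD1L", 0.0126019281191), ("KISS1", 0.0124874609423),
    ("LCN2", 0.0123446041858), ("CXCL5", 0.0122282204837),
    ("HAPLN1", 0.0121753323548), ("CTSG", 0.0121249443517),
    ("SERPINI1", 0.0120388399124), ("CABP1", 0.0120280578478),
    ("CD93", 0.0120005018879), ("COL16A1", 0.0119332179348),
    ("PRSS2", 0.0119006841698), ("COL1A1", 0.0118755109423),
    ("IGHG1", 0.0117128695292), ("THBS3", 0.0115158569766),
    ("TFPI", 0.0115052630961), ("DCN", 0.0112824650786),
    ("UBC", 0.0110403727935), ("MMP2", 0.0109667286026),
    ("COL7A1", 0.0109021629899), ("LAMA1", 0.0106705480427),
    ("YWHAG", 0.0106543097610), ("IGHA1", 0.0104865314738),
    ("RP11-157P1.6", 0.0103829026309), ("FAM190B", 0.0103401713298),
    ("PZP", 0.0103015667226), ("BTC", 0.0102664672842),
    ("NID2", 0.0102327719152), ("TF", 0.0101538081025),
    ("RP11-417O11.1", 0.0101229813573), ("SERPINA5", 0.0101166365026),
    ("NID1", 0.0100899609704),
]

# Benchmark members named publicly: the two hits inside the top-46 list and
# sixteen further genes that rank below it.
_HEADACHE_NAMED = [
    "TNF", "EDNRA",
    "ENG", "ACVRL1", "TGFB1", "VHL", "COL4A1", "NF2", "TTR", "MSX2",
    "FGFR2", "PGK1", "FAM123B", "SH2B3", "LRP5", "NOTCH3", "SDHB", "CACNA1A",
]

_HEMIPLEGIA_NAMED = ["COL4A1", "CACNA1A", "ATP1A2", "SCN1A", "DOCK8"]


def _with_placeholders(named: list[str], total: int, tag: str) -> frozenset[str]:
    fillers = [f"SYNTH-{tag}-{i:02d}" for i in range(1, total - len(named) + 1)]
    return frozenset(named + fillers)


def headache_benchmark() -> BenchmarkSet:
    """The 32-gene headache benchmark.

    Eighteen members are named; the remaining fourteen are synthetic
    placeholders absent from every candidate list, so the overlap with the
    top-46 list is exactly {TNF, EDNRA}.
    """
    return BenchmarkSet("Headache", _with_placeholders(_HEADACHE_NAMED, 32, "HEADACHE"))


def hemiplegia_benchmark() -> BenchmarkSet:
    """The 6-gene hemiplegia benchmark.

    Five members are named (DOCK8 ranks far outside the candidate list); the
    sixth is a synthetic placeholder, so the overlap with the top-83 list is
    exactly the four genes COL4A1, CACNA1A, ATP1A2, SCN1A.
    """
    return BenchmarkSet(
        "Hemiplegia", _with_placeholders(_HEMIPLEGIA_NAMED, 6, "HEMIPLEGIA")
    )


#: Muscle-cramp enrichment inputs: 10 benchmark hits observed among the top
#: 251 candidates, 27 benchmark genes, 14,221-gene universe.
MUSCLE_CRAMP_ENRICHMENT = {
    "observed": 10,
    "k": 251,
    "benchmark_size": 27,
    "universe_size": UNIVERSE_SIZE,
}
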