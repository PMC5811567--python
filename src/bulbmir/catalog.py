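"""Published mature miRNA catalogs of Lilium lancifolium.

The 25 conserved mature sequences (with their MIR family assignments) and
the 44 novel mature sequences reported for flower, leaf, bulblet and bulb
libraries of L. lancifolium. Bundled as desk-scale fixtures so composition
statistics and homology distances can be recomputed without any downloads.
"""

from __future__ import annotations

from .conserved import MiRNACall
from .fold import HairpinFold, PrecursorCandidate, amfe_mfei

#: (family, name, mature sequence 5'-3')
CONSERVED_CATALOG: list[tuple[str, str, str]] = [
    ("MIR156", "LL-miR156a", "ugacagaagagagugagcac"),
    ("MIR156", "LL-miR156i", "ugacagaaagaguagugagca"),
    ("MIR159", "LL-miR159a", "uggauugaagggagcucuaca"),
    ("MIR159", "LL-miR159b", "uuuggauugaagggagcucua"),
    ("MIR159", "LL-miR319a", "uuggacugaagggagcucccu"),
    ("MIR160", "LL-miR160a", "ugccuggcucccuguaugcca"),
    ("MIR160", "LL-miR160f", "cugccuggcucccugaaugcc"),
    ("MIR162", "LL-miR162a", "ucgauaaaccucugcauccgg"),
    ("MIR164", "LL-miR164a", "uggagaagcagggcacgugca"),
    ("MIR166", "LL-miR166f", "ucucggaccaggcuucauucc"),
    ("MIR166", "LL-miR166g", "ucggaccaggcuucauuccuc"),
    ("MIR167", "LL-miR167a", "ugaagcugccagcaugaucuga"),
    ("MIR168", "LL-miR168a", "ucgcuuggugcaggucgggaa"),
    ("MIR172", "LL-miR172a", "agaaucuugaugaugcugcaa"),
    ("MIR390", "LL-miR390a", "aagcucaggagggauagcgcc"),
    ("MIR395", "LL-miR395a", "ugaaguguuugggggaacucc"),
    ("MIR395", "LL-miR395k", "ugaagcguuugggggaacucc"),
    ("MIR396", "LL-miR396a", "uuccacagcuuucuugaacug"),
    ("MIR396", "LL-miR396f", "uuccacggcuuucuugaacua"),
    ("MIR398", "LL-miR398b", "uguguucucaggucaccccug"),
    ("MIR399", "LL-miR399a", "ugccaaaggagacuugcccug"),
    ("MIR408", "LL-miR408b", "ugcacugccucuucccuggcu"),
    ("MIR845", "LL-miR845", "cgcucugauaccacuuguugg"),
    ("MIR2118", "LL-miR2118e", "uucccaaugccucucaugccaa"),
    ("MIR2118", "LL-miR2118a", "uugccgauaccacccauaccga"),
]

#: (name, mature sequence 5'-3')
NOVEL_CATALOG: list[tuple[str, str]] = [
    ("LL-miR01", "uaguaaguuugcagagcagag"),
    ("LL-miR02", "cuugugcuucuggacugcucc"),
    ("LL-miR03", "aagguauagagucagacacuu"),
    ("LL-miR04", "agacgaucgcaccaaacuggcuau"),
    ("LL-miR05", "uuuucuaugucacucaauccaa"),
    ("LL-miR06", "aguaaguugagaagaguaggagaa"),
    ("LL-miR07", "uucacugccaccauccgccugu"),
    ("LL-miR08", "cgguugcuuagcuuguacucu"),
    ("LL-miR09", "ugcaccuccuccuccuuuucu"),
    ("LL-miR10", "gguuugaugaaucugagcauc"),
    ("LL-miR11", "uuacgugucccuuaaucugacggg"),
    ("LL-miR12", "gcucggguuaacggggaagug"),
    ("LL-miR13", "uaugaaguuauauagguuguccgg"),
    ("LL-miR14", "uuuacugccaccauccgccugc"),
    ("LL-miR15", "aagguaagagaaucaacaagaggu"),
    ("LL-miR16", "uaggcaacaaauuagagucucu"),
    ("LL-miR17", "uuuguauggucuguugaaauu"),
    ("LL-miR18", "caggcggcgaggauggggaug"),
    ("LL-miR19", "uugcuuagcuuguacucucgc"),
    ("LL-miR20", "ugaaaauguagcacuagcacc"),
    ("LL-miR21", "uugagaguagagagccaggug"),
    ("LL-miR22", "aaaugaugaaucugagccuc"),
    ("LL-miR23", "uagaggcgaugaugaugaaau"),
    ("LL-miR24", "ugaagacuuggcaaccgacauc"),
    ("LL-miR25", "ucugcccugauaugagcuccag"),
    ("LL-miR26", "ucugaauagcaaacccaauuc"),
    ("LL-miR27", "aaacgaucgauaaaccucugc"),
    ("LL-miR28", "aaugagaagacuagugacaagauu"),
    ("LL-miR29", "uucccuucggcugcaaauagc"),
    ("LL-miR30", "uagaggcgaugaugaugaaau"),
    ("LL-miR31", "aucuuuggccuggagauagagg"),
    ("LL-miR32", "ugugccaugcugugugcgucc"),
    ("LL-miR33", "ugccgggcuaagauacaaggau"),
    ("LL-miR34", "ucuauaugacucucggcaacgg"),
    ("LL-miR35", "uccaaagucagugaggggagc"),
    ("LL-miR36", "uucgagugacauauggaaacu"),
    ("LL-miR37", "ucaaucuuuggccuggagauagag"),
    ("LL-miR38", "ugggucuccucucauuccaug"),
    ("LL-miR39", "uucgagugacauauggaaacu"),
    ("LL-miR40", "ucaaagacgaaucugagcaua"),
    ("LL-miR41", "ucguaucugugguuugcuccu"),
    ("LL-miR42", "ugcaguuugguuuguggugug"),
    ("LL-miR43", "cugucgagcuuccauacuggc"),
    ("LL-miR44", "uggaucuugaaccaaguguuc"),
]

#: published degradome cleavage-site counts per category 0-4 and the
#: published overall total
DEGRADOME_CATEGORY_COUNTS = {0: 22, 1: 10, 2: 9, 3: 5, 4: 7}
DEGRADOME_TOTAL_SITES = 53


def conserved_catalog_calls() -> list[MiRNACall]:
    """The conserved catalog wrapped as pre-made calls for summarisation.

    The precursor slot carries a placeholder unfolded carrier (the catalog
    prints matures only), which is all family/composition summaries need.
    """
    calls = []
    for family, name, seq in CONSERVED_CATALOG:
        mature = seq.upper().replace("T", "U")
        fold = HairpinFold(sequence=mature, structure="." * len(mature), mfe=0.0)
        amfe, mfei, gc = amfe_mfei(fold)
        calls.append(MiRNACall(
            mature=mature, kind="conserved", family=family,
            precursor=PrecursorCandidate(
                source_id=name, window=(0, len(mature)), fold=fold,
                mature=(0, len(mature)), star=None,
                amfe=amfe, mfei=mfei, gc_percent=gc),
            counts={}, star_supported=False, name=name,
        ))
    return calls


def novel_catalog_matures() -> list[str]:
    return [seq.upper().replace("T", "U") for _, seq in NOVEL_CATALOG]
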