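"""Known Penicillium chrysogenum milRNAs (milR-1 … milR-34).

Mature sequences and precursor locations on the P2niaD18 assembly, used as
reference inputs for worked examples (5'-nucleotide tallies, precursor
length bookkeeping, set-union accounting of the two discovery libraries).
Locations use 1-based inclusive coordinates; ``rev(a–b)`` marks the minus
strand.  For milRNAs whose precursor occurs at several loci, the first
location is listed.
"""

from typing import List, NamedTuple


class KnownMilRNA(NamedTuple):
    name: str
    mature: str      # RNA alphabet, 5'->3'
    location: str    # "Chr: a–b" or "Chr: rev(a–b)"


KNOWN_MILRNAS: List[KnownMilRNA] = [
    KnownMilRNA("milR-1", "uugguacgaucgauuggaga", "ChrI: 11548223–11548283"),
    KnownMilRNA("milR-2", "ugagaacgcugauauauauau", "ChrIII: 2410668–2410742"),
    KnownMilRNA("milR-3", "uagaagaucaugcagcaugua", "ChrI: 13214806–13214889"),
    KnownMilRNA("milR-4", "ugcgacacaagaacaaucggacgau", "ChrIII: 3988218–3988278"),
    KnownMilRNA("milR-5", "ugacauaggaacgacgaga", "ChrIV: rev(37091–37159)"),
    KnownMilRNA("milR-6", "ucgggcccguagcugugaugc", "ChrI: 11697045–11697111"),
    KnownMilRNA("milR-7", "uagguucaggaaguucucucc", "ChrI: rev(11697681–11697758)"),
    KnownMilRNA("milR-8", "uggcuacggauaugacucuc", "ChrII: 4498587–4498671"),
    KnownMilRNA("milR-9", "ggccccagagaucguuggucuaa", "ChrII: rev(6202677–6202728)"),
    KnownMilRNA("milR-10", "uagccaucucgucgagguaga", "ChrIII: rev(877512–877577)"),
    KnownMilRNA("milR-11", "uaugucugcucugguccaugac", "ChrI: 12126475–12126539"),
    KnownMilRNA("milR-12", "uccaggcugacgguggcgca", "ChrIV: 2408756–2408823"),
    KnownMilRNA("milR-13", "uaggacuugaucgcgugagac", "ChrI: 8239273–8239341"),
    KnownMilRNA("milR-14", "uagaaugcaagcgcguugagc", "ChrII: rev(3729478–3729558)"),
    KnownMilRNA("milR-15", "uucgauugggaucugggccu", "ChrI: rev(7068824–7068895)"),
    KnownMilRNA("milR-16", "ugggcgggcgagauugaac", "ChrI: rev(9237687–9237761)"),
    KnownMilRNA("milR-17", "uccaucguggcugugcacuu", "ChrII: rev(5605185–5605257)"),
    KnownMilRNA("milR-18", "uggacgaggaacaucugcac", "ChrI: rev(8625875–8625949)"),
    KnownMilRNA("milR-19", "cggacgagaaugccgaggcucuguu", "ChrIV: 979955–980021"),
    KnownMilRNA("milR-20", "uccuacguuacuccaaaggau", "ChrI: 8009736–8009780"),
    KnownMilRNA("milR-21", "ucccccucgagaagaucuagucugccucu", "ChrI: 7174825–7174898"),
    KnownMilRNA("milR-22", "uuuggaugaaauucgaaugaa", "ChrIII: 1228283–1228364"),
    KnownMilRNA("milR-23", "uagacuguuccaaggaugcu", "ChrII: 8010371–8010446"),
    KnownMilRNA("milR-24", "ugcacaaguggacucucccu", "ChrI: 12845073–12845153"),
    KnownMilRNA("milR-25", "ucaucggcaaaacuuggagaa", "ChrII: rev(3651114–3651202)"),
    KnownMilRNA("milR-26", "ucacacguagaaauccagau", "ChrI: 10506362–10506430"),
    KnownMilRNA("milR-27", "ucuaccgagacugucuuuga", "ChrI: 4059417–4059459"),
    KnownMilRNA("milR-28", "uuagcaugcaugguauugua", "ChrII: 8593139–8593200"),
    KnownMilRNA("milR-29", "ugcuuggucgucacucggga", "ChrII: 2351660–2351714"),
    KnownMilRNA("milR-30", "uaccaagucgucgaaaugcu", "ChrIV: 190879–190926"),
    KnownMilRNA("milR-31", "ugagaccgcggagcaaacg", "ChrI: 3765153–3765197"),
    KnownMilRNA("milR-32", "uggagaaugucacuuguggaa", "ChrIII: rev(719002–719055)"),
    KnownMilRNA("milR-33", "augcccuucggcguuagucuacc", "ChrIV: rev(1820276–1820326)"),
    KnownMilRNA("milR-34", "uuucccaucucgaucaccgga", "ChrIV: rev(1325461–1325507)"),
]
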