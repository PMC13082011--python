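"""Partition a peptide catalog by polyprotein structure.

Builds a tiny catalog on one annotated polyprotein and assigns each peptide
to CE1-VP1 (overlaps both the VP1 capsid chain and the CE1 consensus-epitope
window), non-CE1 VP1, or non-VP1.
"""

from mimiscan.catalog import (ChainAnnotation, ChainName, PeptideRecord,
                              assign_groups)

annotations = [
    ChainAnnotation("DEMO1", ChainName.VP2, 1, 300),
    ChainAnnotation("DEMO1", ChainName.VP3, 301, 799),
    ChainAnnotation("DEMO1", ChainName.VP1, 800, 1090,
                    ce1_start=860, ce1_end=900),
    ChainAnnotation("DEMO1", ChainName.NONSTRUCTURAL, 1091, 2200),
]
peptides = [
    PeptideRecord("pep_ce1", "DEMO1", 850, 905),     # straddles CE1
    PeptideRecord("pep_edge", "DEMO1", 801, 860),    # one residue into CE1
    PeptideRecord("pep_vp1", "DEMO1", 801, 859),     # VP1 but misses CE1
    PeptideRecord("pep_vp2", "DEMO1", 10, 65),       # capsid VP2 only
    PeptideRecord("pep_nsp", "DEMO1", 1500, 1556),   # non-structural
]

groups = assign_groups(peptides, annotations)
for pep in peptides:
    print(f"{pep.peptide_id:>9}  [{pep.start:>4}, {pep.end:>4}]  ->  "
          f"{groups[pep.peptide_id].value}")

# A single shared residue with the CE1 window (pep_edge ends at 860) is
# enough for a CE1-VP1 call; pep_vp1 stops one residue short and stays
# non-CE1 VP1.  Counts over the three groups always sum to the catalog size.
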