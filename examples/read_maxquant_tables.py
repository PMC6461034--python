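"""Parse MaxQuant-dialect tables and build the merged class-I site table.

Writes two tiny tab-separated inputs inline — a quantified phosphopeptide
table (modificationSpecificPeptides dialect) and a phosphosite table
(Phospho (STY)Sites dialect) — then reads, filters, and merges them.
"""

import tempfile
from pathlib import Path

from inka import merge_site_peptide, read_phosphopeptide_table, read_phosphosite_table

PEPTIDES = """Sequence\tGene Names\tPhospho (STY)\ttumor_1
LIEDNEYTAR\tSRC;FYN\t1\t12
DIYETDYYRK\tINSR\t2\t3
NOPHOSPHOK\tEGFR\t0\t9
"""

SITES = """Protein\tGene names\tPosition\tAmino acid\tLocalization prob\tPeptide sequence
P12931\tSRC\t419\tY\t0.99\tLIEDNEYTAR
P06241\tFYN\t420\tY\t0.88\tLIEDNEYTAR
P06213\tINSR\t1185\tY\t0.95\tDIYETDYYRK
P06213\tINSR\t1189\tY\t0.60\tDIYETDYYRK
"""

with tempfile.TemporaryDirectory() as tmp:
    pep_path = Path(tmp) / "peptides.tsv"
    site_path = Path(tmp) / "sites.tsv"
    pep_path.write_text(PEPTIDES)
    site_path.write_text(SITES)

    peptides = read_phosphopeptide_table(pep_path, ["tumor_1"])
    sites = read_phosphosite_table(site_path)
    merged = merge_site_peptide(peptides, sites)

print(f"{len(peptides)} peptide records (multi-gene rows split, non-phospho dropped)")
print(f"{len(sites)} class-I sites (localization probability > 0.75)")
print("\nmerged site-peptide table:")
print(merged.to_string(index=False))
# INSR Y1189 fails the class-I filter, so the INSR peptide carries a single
# inferred site and its full phosphosignal goes to Y1185.
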