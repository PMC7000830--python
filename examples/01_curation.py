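"""Curate a raw control-region alignment into a haplotype table.

Builds a small alignment containing the two artefacts the curation stage
handles — a hypervariable (homoplasic) column and a variable-length TA
repeat tract — then removes the noisy site, collapses the repeat so each
motif copy counts as one mutational step, and pools identical sequences
into haplotypes.
"""

import haplogeo as hg
from haplogeo.alignment import AlignmentRecord, HaplotypeAlignment

# Six samples from two localities. Site 4 is hypervariable (a parallel
# mutation splits two haplotypes), and a TA microsatellite starts at site 6
# with 2-3 copies per sequence.
core = {
    "hapA": "ACG" + "A" + "G" + "TATA--",
    "hapA'": "ACG" + "T" + "G" + "TATA--",   # hapA + hypervariable site
    "hapB": "ACC" + "A" + "G" + "TATATA",
    "hapB'": "ACC" + "T" + "G" + "TATATA",   # hapB + the same parallel change
}
records = []
for name, seq in core.items():
    pops = ["SOUTH", "NORTH"] if name.startswith("hapA") else ["SOUTH"]
    for j, pop in enumerate(pops):
        records.append(AlignmentRecord(f"{name}_{j}", pop, seq))
aln = HaplotypeAlignment(records)
print(f"raw alignment: {aln.n} sequences, {aln.L} sites")
print(f"raw haplotypes: {len(hg.collapse_haplotypes(aln).haplotypes)}")

# 1. drop the hypervariable column (1-based coordinate, as reported)
aln = hg.remove_sites(aln, [4])

# 2. collapse the TA repeat starting at (now) site 5
aln = hg.collapse_repeat_motif(aln, "TA", 5)

# 3. pool identical sequences
table = hg.collapse_haplotypes(aln)
print(f"curated alignment: L = {aln.L}")
print("curated haplotype table (counts per locality):")
print(table.counts)
# The parallel mutation at site 4 had split each true haplotype in two;
# after curation only the two real lineages remain, and the repeat-length
# difference between them counts as a single mutational step per copy.
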