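"""Marker-level genotyping: IS5 junctions, diagnostic SNPs, COI haplotypes.

wMel-like genomes carry an IS5 element at WD0516/7 but not WD1310; the
converse marks wMelCS-like; absence at both marks wMel3.  The calls come
from reads spanning insertion or empty-site junctions.
"""

import numpy as np

from cytosym.markers import (HaplotypeTable, JunctionReference,
                             assign_coi_haplotype, assign_is5_genotype,
                             classify_mt_snp_type, detect_is5_presence,
                             extract_coi, simulate_reads)

rng = np.random.default_rng(0)
bases = np.array(list("ACGT"))


def locus(seed, flank=400, element=300):
    r = np.random.default_rng(seed)
    left, right = ("".join(r.choice(bases, flank)) for _ in range(2))
    el = "".join(r.choice(bases, element))
    return (JunctionReference(left + el + right, (flank, flank + element)),
            JunctionReference(left + right, (flank,)))


ins1, emp1 = locus(1)
ins2, emp2 = locus(2)
# a wMel-like strain: element present at WD0516/7, absent at WD1310
reads1 = simulate_reads(ins1.sequence, depth=20, read_length=100,
                        error_rate=0.005, seed=3)
reads2 = simulate_reads(emp2.sequence, depth=20, read_length=100,
                        error_rate=0.005, seed=4)
c1 = detect_is5_presence(reads1, "WD0516_7", ins1, emp1)
c2 = detect_is5_presence(reads2, "WD1310", ins2, emp2)
print(f"WD0516/7: {c1.status} ({c1.junction_reads} junction reads); "
      f"WD1310: {c2.status} ({c2.empty_reads} empty-site reads)")
print("IS5 genotype:", assign_is5_genotype(c1, c2))

consensus = list("A" * 2400)
consensus[2159], consensus[2186] = "C", "T"      # wMel-diagnostic pair
consensus = "".join(consensus)
print("mtDNA SNP type:", classify_mt_snp_type(consensus))

table = HaplotypeTable({2: extract_coi(consensus)})
coi = extract_coi(consensus)
print("COI haplotype:", assign_coi_haplotype(coi, table).haplotype_id,
      "(known haplotype 2)")
novel = coi[:100] + ("T" if coi[100] != "T" else "A") + coi[101:]
print("novel variant gets id:", assign_coi_haplotype(novel, table).haplotype_id,
      "(new haplotypes are numbered from 20)")
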