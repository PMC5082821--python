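"""Clonality rules for structural variants and L1 insertions.

Applies the >30% junction-support rule with blood subtraction to SV calls
and the RAM-based allele-frequency estimator (with copy-number
adjustment) to retrotransposon insertion calls.
"""
from somamosaic.clonality import (InsertionCall, SVCall,
                                  classify_subclonal, cn_adjusted_clonality,
                                  filter_clonal_sv, insertion_clonality)

svs = [
    SVCall("deletion", "chr1", 10_000, 25_000, 45, 100, 0),
    SVCall("inversion", "chr1", 40_000, 60_000, 28, 100, 0),   # <= 30%
    SVCall("translocation", "chr2", 5_000, 5_001, 60, 100, 2),  # blood
]
clonal = filter_clonal_sv(svs)
print("clonal SVs:", [(s.sv_type, s.supporting_reads, s.total_reads)
                      for s in clonal])

ins = InsertionCall("L1", "chr3", 120_000, ram_count=5,
                    concordant_count=45, local_depth=50.0,
                    genome_average_depth=50.0)
freq = insertion_clonality(ins)
print(f"L1 insertion allele frequency: {freq:.2f}"
      f" -> {classify_subclonal(freq)}")

dup = InsertionCall("L1", "chr4", 80_000, ram_count=4, concordant_count=96,
                    local_depth=100.0, genome_average_depth=50.0)
print(f"in a duplicated region: raw {insertion_clonality(dup):.3f}, "
      f"copy-number adjusted {cn_adjusted_clonality(dup):.3f} (upper bound)")
# Only the first SV passes (support > 30% and clean blood). The insertion
# at ~10% frequency is subclonal — acquired during clonal expansion, not
# present in the progenitor cell.
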