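"""Simulate a clone's mutation catalog and recover it by consensus filtering.

Generates a small reference, plants somatic mutations with a UV-dominated
process mixture plus germline variants, emits three noisy caller tables
with a matched blood table, then runs the consensus filter chain
(three-caller intersection, depth/alt thresholds, blood subtraction,
clonal VAF windows).
"""
from somamosaic import filtering as flt
from somamosaic import synthetic as syn

genome = syn.generate_reference(length=200_000, gc_fraction=0.41, seed=1)
genes = syn.emit_genes(genome, n_genes=6, seed=2)
mix = syn.ProcessMix.default(n_mutations=2000)
truth = syn.plant_somatic_mutations(genome, mix, genes, seed=3)
germline = syn.plant_germline(genome, seed=4)
tables, blood = syn.emit_caller_tables(
    truth, germline, genome, depth_mean=50,
    fp_rate_per_caller=0.05, fn_rate_per_caller=0.05, seed=5)

catalog, stage_counts = flt.consensus_catalog(tables, blood)
print("planted somatic records:", len(truth),
      f"({(truth['zygosity'] != 'subclonal').sum()} clonal)")
print("stage counts:", stage_counts)
print("final catalog:", catalog.mutation_load, "calls;",
      (catalog.calls["zygosity"] == "het").sum(), "het /",
      (catalog.calls["zygosity"] == "hom").sum(), "hom")
counts, edges, frac_het, frac_hom = flt.vaf_histogram(tables["A"])
print(f"caller A VAF fractions: {frac_het:.2f} in 45-55%, "
      f"{frac_hom:.2f} above 90%")
# Each filter stage only removes records; the catalog keeps the clonal
# het/hom truth that survived caller noise and binomial VAF sampling,
# while germline (blood-subtracted) and subclonal records are excluded.
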