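"""Transcription-strand bias of UV-signature mutations.

Plants UV mutations with transcription-coupled repair at half efficiency
on gene template strands (tcr_factor = 0.5), classifies genic mutations by
the strand carrying the mutated pyrimidine, and runs the one-sided
binomial test expecting an excess on the non-transcribed strand; the
non-UV pyrimidine mutations serve as the unbiased control.
"""
from somamosaic import covariates as cov
from somamosaic import synthetic as syn

genome = syn.generate_reference(150_000, 0.41, seed=20)
genes = syn.emit_genes(genome, 5, seed=21, length_range=(12_000, 20_000))
mix = syn.ProcessMix({"UV_YC": 0.5, "UV_TT5": 0.2, "BACKGROUND": 0.3},
                     2000, tcr_factor=0.5)
truth = syn.plant_somatic_mutations(genome, mix, genes, seed=22)

uv = cov.uv_strand_counts(genome, truth, genes, "clone")
ctl = cov.non_uv_control(genome, truth, genes, "clone")
for c in cov.strand_bias_table([uv, ctl]):
    print(f"{c.signature_class:>6}: non-transcribed {c.non_transcribed:4d}"
          f"  transcribed {c.transcribed:4d}  p={c.p:.3g}  q={c.q:.3g}")
# The UV class shows the planted repair asymmetry (expected transcribed
# fraction tcr/(1+tcr) = 1/3) and rejects the 50:50 null; the control
# class, untouched by the repair model, does not.
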