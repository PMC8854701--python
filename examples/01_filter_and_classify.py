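"""Somatic-call filtering and MAF classification.

Builds a handful of candidate calls, applies the whole-genome confidence
filters, and classifies the survivors' mutant allele fractions into the
trimodal subclonal / clonal / clonal-with-allelic-imbalance scheme.
"""

from glandevo import (
    MutationRecord,
    binomial_imbalance_test,
    classify_maf,
    filter_somatic_calls,
)

candidates = [
    MutationRecord("g1", "chr1", 1000, "C", "T", depth=60, alt_reads=30,
                   blood_depth=40, blood_alt_reads=0, context="ACA"),
    MutationRecord("g1", "chr1", 2000, "C", "A", depth=19, alt_reads=10,
                   blood_depth=40, blood_alt_reads=0, context="GCG"),
    MutationRecord("g1", "chr2", 3000, "T", "G", depth=80, alt_reads=70,
                   blood_depth=40, blood_alt_reads=0, context="ATA"),
    MutationRecord("g1", "chr2", 4000, "C", "T", depth=90, alt_reads=40,
                   blood_depth=40, blood_alt_reads=6, context="TCT"),
]

kept, tally = filter_somatic_calls(candidates, mode="wgs")
print(f"kept {len(kept)}/{len(candidates)} calls; rejections: {dict(tally)}")
# A call needs depth >= 20, >= 8 mutant reads, MAF >= 0.25, clean blood and
# a sub-0.001 population frequency to survive.

for rec in kept:
    label = classify_maf(rec.maf)
    p = binomial_imbalance_test(rec.alt_reads, rec.depth)
    print(f"  {rec.chrom}:{rec.pos} MAF={rec.maf:.2f} -> {label} "
          f"(binomial balance test p={p:.2e})")
# MAF ~0.5 marks a clonal heterozygous mutation; MAF >= 0.75 with a tiny
# binomial p indicates allelic imbalance favouring the mutant allele.
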