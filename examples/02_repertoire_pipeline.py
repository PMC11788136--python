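"""Simulate junction amplicon reads and recover the clonotype table.

Builds a segmented reference from an annotated synthetic locus, simulates
3,000 V(D)J amplicon reads (geometric trimming, Poisson insertions, D
inclusion, 200-300 bp amplicons), runs alignment + CDR3 extraction +
clonotype assembly, and prints the sequencing-summary accounting row.
"""

from iglocus import (
    LocusSpec,
    RepertoireSpec,
    build_reference,
    generate_locus,
    run_repertoire,
    simulate_repertoire,
    summarize_sample,
)

locus = generate_locus(LocusSpec(seed=1))
reference = build_reference(locus.genes)
sim = simulate_repertoire(RepertoireSpec(reference=reference, n_reads=3000, seed=2))
result = run_repertoire(sim.reads, reference, sample_id="demo")

s = summarize_sample(result.raw_sample)
print(f"Total reads:        {s.total_reads}")
print(f"Aligned reads:      {s.aligned_reads} ({s.aligned_pct}%)")
print(f"Clonotype count:    {s.clonotype_count}   (reads in retained clonotypes)")
print(f"Unique clones:      {s.unique_clones}   ({s.unique_over_total_pct}% of clonotypes)")
print(f"Removed by filter:  {result.removed}  (stop codons / out-of-frame junctions)")

cols = ["junction", "v_call", "j_call", "duplicate_count"]
truth = sim.clonotypes[cols].sort_values(cols[:3]).reset_index(drop=True)
found = result.table[cols].sort_values(cols[:3]).reset_index(drop=True)
print(f"\nClonotype table equals simulator truth: {truth.equals(found)}")
print("(zero-mutation simulation: sequences, counts and V/J calls recover exactly)")
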