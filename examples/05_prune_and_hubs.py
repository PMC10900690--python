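"""Post-processing: redundancy pruning, QTL annotation and hub calling.

Builds a small table of significant pairs with hand-placed genomic
coordinates to show each rule firing: interchromosomal redundancy (lower
FDR-adjusted p retained), mirror redundancy (first encountered retained),
cis removal (<10 Mb intrachromosomal pairs dropped), QTL relabeling within
10 Mb, collapsing of clustered non-QTL loci to their average position, and
the >=10-interaction hub threshold.
"""

import pandas as pd

from epiflex import call_hubs, make_annotation, prune_redundant, qtl_annotate

ann = make_annotation(
    ["a1", "a2", "b1", "b2", "c1", "c2", "d1", "d2"],
    ["1", "2", "1", "2", "2", "1", "3", "3"],
    [5e6, 8e6, 9e6, 11e6, 10e6, 6e6, 1e6, 9e6])
pairs = pd.DataFrame({
    "locus1": ["a1", "b1", "c1", "d1"],
    "locus2": ["a2", "b2", "c2", "d2"],
    "q_fdr": [1e-6, 1e-3, 1e-4, 1e-5]})

pruned = prune_redundant(pairs, ann)
print(pruned[["locus1", "locus2", "pair_class", "q_fdr", "pruned_reason"]]
      .to_string(index=False))

survivors = pruned[pruned["pruned_reason"].isna()]
qtls = pd.DataFrame({"chrom": ["1"], "bp": [6_000_000]},
                    index=pd.Index(["QTL1"], name="qtl_id"))
annotated, counts = qtl_annotate(survivors, ann, qtls)
print("\nper-locus interaction counts after QTL relabeling:")
print(counts.to_string())
print("\nhubs at threshold 2 (toy scale):", list(call_hubs(counts, 2).index))
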