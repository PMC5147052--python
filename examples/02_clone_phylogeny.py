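"""Build a rooted clone phylogeny from single-cell CNV genotypes.

Cells with identical call sets collapse into genotype classes; Jaccard
distances between class genotypes are fitted with the Fitch-Margoliash
least-squares method and rooted on a CNV-free "normal" out-group.
"""

import pandas as pd

import cnvphylo as cp

# a small hand-written genotype matrix: 3 nested clones over 3 regions
calls = pd.DataFrame(
    {
        "chr7:gain": [1] * 18 + [0] * 2,
        "chr10:loss": [1] * 12 + [0] * 8,
        "chr13:loss": [1] * 5 + [0] * 15,
    },
    index=[f"cell{i}" for i in range(20)],
)

tree = cp.build_clone_phylogeny(calls)
print("newick:", cp.to_newick(tree))
print(f"least-squares residual: {tree.residual:.3g}")
# each leaf is a genotype class labeled with its cell count; the residual
# is ~0 when the Jaccard distances are tree-additive, as for nested clones

classes, D = cp.collapse_genotypes(calls)
for c in classes:
    print(f"  {c.name}: {sorted(c.genotype) or 'no CNVs'} ({c.frequency} cells)")
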