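"""Generate a synthetic 16S case/control study with a planted genus effect.

Builds a random 7-rank taxonomy, plants a 3-fold abundance shift on every
OTU of one genus in the case samples, and prints what was planted.  The
same generator backs `hfe simulate` on the command line.
"""

from hfe.synthetic import _otu_descendants, simulate

table, labels, tree, truth = simulate(
    n_otus=200, n_samples=100, effect_size=3.0, seed=17
)

clade = _otu_descendants(tree, truth.planted_node)
n_cases = sum(1 for c in labels.mapping.values() if c == "case")

print(f"table: {table.n_samples} samples x {table.n_features} OTU features")
print(f"taxonomy: {tree.m_prime} named taxa over {tree.m} OTUs, "
      f"{len(tree.incomplete_leaves())} OTUs with incomplete lineages")
print(f"labels: {n_cases} case / {table.n_samples - n_cases} control")
print(f"planted: {truth.planted_node}")
print(f"  effect x{truth.effect_size} on its {len(clade)} member OTUs in cases")
# The planted genus is the ground truth that feature engineering should
# recover; its member OTUs are redundant with it and should be pruned.
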