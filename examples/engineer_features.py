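"""Run the four feature-engineering phases on one training set.

Grows the feature space from m OTUs to m + m' taxon aggregates, then
prunes correlation-redundant children (s1), uninformative path nodes (s2)
and uninformative incomplete-path leaves (s3).  Prints the surviving
features with their information gain.
"""

from hfe.core import run_hfe
from hfe.synthetic import recovery_neighborhood, simulate

table, labels, tree, truth = simulate(seed=17)
result = run_hfe(table, labels, tree, theta=0.7)

m, mp = result.m, result.m_prime
print(f"feature space: {m} OTUs -> {m + mp} candidates "
      f"-> {len(result.selected)} selected")
print(f"discards: s1={result.s1} (correlation), s2={result.s2} (path IG), "
      f"s3={result.s3} (incomplete-leaf IG)")
print(f"count identity: {len(result.selected)} == "
      f"{m}+{mp}-{result.s1}-{result.s2}-{result.s3}")
print("\nselected features (IG in bits):")
for f in result.selected:
    tag = " <- planted clade" if f in recovery_neighborhood(
        tree, truth.planted_node) else ""
    print(f"  {f.split(';')[-1] if ';' in f else f:<16} {result.ig_scores[f]:.3f}{tag}")
# A feature tagged "planted clade" means the method found the simulated
# signal at (or one rank away from) the taxon that truly carries it.
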