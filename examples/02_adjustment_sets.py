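"""Which variables must be controlled to test for vocal dialects?

Builds the assumed causal graph (location, environment, genetics,
individual, context, community, acoustic structure) and prints every
minimally sufficient adjustment set for the community -> acoustic-structure
query.  Each printed set blocks all confounding backdoor paths; controlling
any one of them gives an unbiased community/acoustics association.
"""

from panthoot import AdjustmentQuery, minimal_adjustment_sets, pant_hoot_dialect_dag
from panthoot.dag import backdoor_paths

dag = pant_hoot_dialect_dag()
query = AdjustmentQuery("community", "acoustic_structure")

print("backdoor paths:")
for path in backdoor_paths(dag, query):
    print("  " + " - ".join(path))

print("minimally sufficient adjustment sets:")
for s in sorted(sorted(s) for s in minimal_adjustment_sets(dag, query)):
    print(f"  {s}")
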