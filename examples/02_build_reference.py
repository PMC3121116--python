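"""Build candidate regulatory networks from TF->target relations + gene sets.

A gene set "claims" every relation whose target gene it contains; the
claimed relations form one named candidate network (the TFs come along as
nodes).  Sets claiming nothing produce no network.
"""

from netscreen import BinaryRelation, GeneSet, build_reference

relations = [
    BinaryRelation("STAT5", "SOCS2"),
    BinaryRelation("STAT5", "IGF1"),
    BinaryRelation("HNF4A", "APOA1"),
    BinaryRelation("HNF4A", "TTR"),
    BinaryRelation("ATF3", "IL6"),
]

gene_sets = [
    GeneSet("GROWTH_SIGNALING", frozenset({"SOCS2", "IGF1", "TTR"})),
    GeneSet("INFLAMMATION", frozenset({"IL6"})),
    GeneSet("UNRELATED", frozenset({"MYOD1"})),
]

for net in build_reference(relations, gene_sets):
    print(f"{net.name}: {net.n_v} nodes, {net.n_e} edges")
    for tf, target in sorted(net.edges):
        print(f"    {tf} -> {target}")

print("\nUNRELATED matched no target, so it defines no candidate network.")
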