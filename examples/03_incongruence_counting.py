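"""Count gene-tree/taxonomy incongruences by small parsimony.

Reads a small TE-copy phylogeny with branch supports, collapses weakly
supported branches (<0.7) into polytomies, and counts the minimum number
of label changes needed to explain the taxonomic labels on the leaves.
Each change beyond the n_labels-1 required by monophyly is an excess event
— the parsimony floor on the number of horizontal transfers.
"""

from httdetect import treeops as to

# Lep1..4 are Lepidoptera copies, Dip1/2 Diptera, Hym1/2 parasitoid wasps.
# Hym1's copy nests INSIDE the Diptera clade while the rest of its order
# (Hym2) sits elsewhere; the 0.55-support branch is collapsed first.
newick = ("((((Lep1:1,Lep2:1)0.95:2,(Lep3:1.5,Lep4:1.5)0.55:1.5)0.9:2,"
          "Hym2:5)0.85:1,((Dip1:1,Hym1:1)0.92:1,Dip2:2)0.88:3);")
labels = {"Lep1": "Lepidoptera", "Lep2": "Lepidoptera", "Lep3": "Lepidoptera",
          "Lep4": "Lepidoptera", "Dip1": "Diptera", "Dip2": "Diptera",
          "Hym1": "Hymenoptera", "Hym2": "Hymenoptera"}

tree = to.read_newick(newick)
collapsed = to.collapse_low_support(tree, threshold=0.7)

res = to.parsimony_transitions(collapsed, labels, label_rank="order")
print(f"labels: {res.n_labels}, parsimony score: {res.parsimony_score}, "
      f"excess events: {res.excess_events}")

for inc in to.enumerate_incongruences(collapsed, labels):
    kind = "basal origin" if inc.basal_origin else "INCONGRUENCE"
    print(f"  {kind}: {sorted(inc.focal_clade)} ({inc.focal_label}) "
          f"inside {inc.context_label} context"
          + ("  [ambiguous]" if inc.ambiguous else ""))
# The single excess event is the wasp copy inside the fly clade: at least
# one horizontal transfer is required to explain this topology.
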