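"""Classify the contact states of a tiny two-parent chimera library.

Two parents ACDE and AGDF recombined at one crossover give four chimeras.
Each residue-residue contact realizes one of a handful of residue-pair
states, each parental (seen in some parent) or novel; the novel-state
count per chimera is its SCHEMA disruption.
"""

from recfield import (
    ContactMap,
    LibraryDesign,
    ParentAlignment,
    classify_states,
    schema_disruption,
)

alignment = ParentAlignment(("parentA", "parentB"), ("ACDE", "AGDF"))
design = LibraryDesign(length=4, crossovers=(2,))
contacts = ContactMap(length=4, contacts=((2, 3), (2, 4), (3, 4)))

table = classify_states(alignment, design, contacts)
print(f"{table.k} contacts, {table.n_states} distinct states "
      f"({int(table.is_novel.sum())} novel)")
for t, (i, j) in enumerate(table.contacts):
    lo, hi = table.state_slices[t]
    states = ", ".join(
        f"{a}{b}({'N' if table.is_novel[s] else 'P'})"
        for s, (a, b) in zip(
            range(lo, hi), table.state_residues[lo:hi]
        )
    )
    print(f"  contact ({i},{j}): {states}")

n_c, mean_nc = schema_disruption(table)
print("disruption n_c per chimera:", dict(zip(table.codes, n_c.tolist())))
print(f"library mean <n_c> = {mean_nc}")
# The two parents carry no novel states; each single-block swap (12, 21)
# creates exactly one novel residue pair at the block-spanning contact.
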