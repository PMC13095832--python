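"""Load the compiled cutting-preference table and summarize it.

The packaged table lists every valid leaf-cutting ant species with its
predominant cutting preference (dicot, grass, or mixed dicot-grass),
whether it is sampled in the dated phylogeny, and literature references.
"""

import cutevo as cv

table = cv.load_trait_table()  # the builtin compiled table
counts = cv.count_by_state(table)

print(f"valid species: {len(table)}")
print(f"included in phylogeny: {counts.n_in_phylogeny}")
print()
print(counts.to_frame().to_string(index=False))
print()
print(
    "Each row is a bookkeeping state; the three analysis states (dicot, "
    "grass, dicot_grass)\nenter the Mk model, while 'unknown' species are "
    "excluded and the social parasite is\ntreated as an ambiguous tip."
)
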