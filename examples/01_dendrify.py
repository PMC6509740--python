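"""Dendrification: how ordinal snapshot ratings become binary sub-items.

A 5-point creative-quality rating is recoded as a walk through the four
internal nodes of a linear response tree: pass every node below the rating,
stop at the rating itself; a 5 passes everything.  Nodes after the stop are
structurally missing — they are not zeros.
"""

import pandas as pd

from treequal import expand_to_subitems, collapse_from_subitems

ratings = pd.DataFrame([
    dict(person_id="anna", item_id="brick", rater_id="r1",
         instruction="be_fluent", fluency=12, rating=1),
    dict(person_id="anna", item_id="rope", rater_id="r1",
         instruction="be_creative", fluency=6, rating=3),
    dict(person_id="ben", item_id="rope", rater_id="r1",
         instruction="be_creative", fluency=9, rating=5),
])

subitems = expand_to_subitems(ratings)
print(subitems[["person_id", "item_id", "node", "outcome"]].to_string(index=False))
# anna/brick (rating 1): a single row, node 1 failed.
# anna/rope  (rating 3): nodes 1-2 passed, node 3 failed, node 4 absent.
# ben/rope   (rating 5): all four nodes passed.

recovered = collapse_from_subitems(subitems)
print("\nratings recovered from the sub-items:",
      recovered["rating"].tolist(), "(identical to the input)")
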