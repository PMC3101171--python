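"""Rank a TF's coexpression neighborhood on a five-sample toy matrix.

The TF profile rises monotonically, g1 follows it exactly (rho = 1),
g2 mirrors it (rho = -1), and g3/g4 track it loosely (rho = 0.8 each).
"""

import numpy as np

from tfcluster import AssociationParams, ExpressionMatrix, top_coexpressed

expr = ExpressionMatrix(
    gene_ids=("t", "g1", "g2", "g3", "g4"),
    sample_ids=("s1", "s2", "s3", "s4", "s5"),
    values=np.array(
        [
            [1, 2, 3, 4, 5],
            [2, 3, 4, 5, 6],
            [5, 4, 3, 2, 1],
            [1, 3, 2, 5, 4],
            [2, 1, 4, 3, 5],
        ],
        dtype=float,
    ),
)

for direction in ("positive", "absolute"):
    nb = top_coexpressed("t", expr, AssociationParams(omega=2, direction=direction))
    print(f"direction={direction}: members={nb.members} scores={nb.scores}")

# direction=positive picks g1 (rho 1.0) then g3 — g3 and g4 tie at 0.8 and
# the lexicographically smaller id wins; direction=absolute instead ranks
# g2 second because |rho| = 1.0 beats 0.8.
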