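"""Look inside the candidate engine: segment filter plus bounded verification.

Indexes a handful of sequences at tau=2 with t+k=4 segments, queries one
of them, and verifies the surviving candidates with the banded edit
distance — showing how most of the pool is never aligned at all.
"""

from ampliswarm import (
    Amplicon,
    bounded_edit_distance,
    build_indices,
    candidates,
    partition_positions,
)

pool = [
    Amplicon("a", "ACGTACGTACGTACGTACGT", 9, 0),
    Amplicon("b", "ACGTACGAACGTACGTACGT", 5, 1),   # 1 substitution from a
    Amplicon("c", "ACGTACGTACGTACGACGT", 3, 2),    # 1 deletion from a
    Amplicon("d", "TTTTTTTTTTTTTTTTTTTT", 8, 3),   # unrelated
    Amplicon("e", "GGGGGGGGGGGGGGGGGGGG", 2, 4),   # unrelated
]
tau, k = 2, 2
print("even partition of length 20 into tau+k=4 segments:",
      partition_positions(20, tau + k).segments)

idx = build_indices(pool, tau, k)
query = pool[0]
cand = sorted(candidates(query, idx))
print(f"candidates of {query.id!r} at tau={tau}: {cand} "
      f"(the unrelated sequences share no segment and are never aligned)")

for ident in cand:
    other = next(a for a in pool if a.id == ident)
    outcome = bounded_edit_distance(query.sequence, other.sequence, tau)
    print(f"  verify {query.id}~{ident}: "
          f"{'d=%d' % outcome.value if outcome.within else 'exceeds tau'}")
print("Verification computes only the banded diagonals and stops early, so "
      "the exact distance is returned exactly when it is <= tau.")
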