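"""Compare slice-inspection sequences with alignment-based similarity.

Observers page through a 31-slice stack; each visit sequence is
collapsed (consecutive repeats dropped), encoded as tokens, and pairs
are scored by Needleman-Wunsch global alignment with a substitution
score that falls off linearly with slice distance, normalized to [0, 1].
"""

from delinmetrics import (
    GroupParams,
    collapse_repeats,
    similarity_score,
    simulate_sequence,
)

n = 31
sweep = list(range(n))                                  # textbook sweep
messy_a = simulate_sequence(n, GroupParams(revisit_rate=1.0), seed=7)
messy_b = simulate_sequence(n, GroupParams(revisit_rate=1.0), seed=8)
reverse = sweep[::-1]

print(f"messy sequence length {len(messy_a)}, collapsed {len(collapse_repeats(messy_a))}")
print(f"sweep   vs itself : {similarity_score(sweep, sweep, n):.3f}")
print(f"messy   vs messy  : {similarity_score(messy_a, messy_b, n):.3f}")
print(f"sweep   vs messy  : {similarity_score(sweep, messy_a, n):.3f}")
print(f"sweep   vs reverse: {similarity_score(sweep, reverse, n):.3f}")
print(f"slice 0 vs slice {n - 1}: {similarity_score([0], [n - 1], n):.3f}")
# 1 means identical inspection technique; 0 means no similarity at all.
# Two observers who both sweep with local revisits look alike; a clean
# sweep against a revisit-heavy one scores low because the score is
# normalized by the longer sequence, so length mismatches are penalized.
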