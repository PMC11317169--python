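"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the libraries the package itself uses: edit
distances are computed by textbook dynamic programming and clustering by
a direct re-implementation of the greedy rule.
"""

from __future__ import annotations


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) unit-cost edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def semiglobal_best_edits(pattern: str, seq: str) -> int:
    """Minimal edits to align the full pattern inside seq (free seq ends)."""
    prev = [0] * (len(seq) + 1)  # free start anywhere in seq
    for i, cp in enumerate(pattern, 1):
        cur = [i]
        for j, cs in enumerate(seq, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cp != cs))
            )
        prev = cur
    return min(prev)  # free end anywhere in seq


def greedy_cluster_reference(
    ordered_seqs: list[str], max_dist: int
) -> list[list[str]]:
    """Direct re-implementation of abundance-seeded greedy clustering."""
    reps: list[str] = []
    groups: list[list[str]] = []
    for seq in ordered_seqs:
        for rep, group in zip(reps, groups):
            if dp_levenshtein(seq, rep) <= max_dist:
                group.append(seq)
                break
        else:
            reps.append(seq)
            groups.append([seq])
    return groups
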