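"""Candidate selection and Levenshtein-distance family clustering.

A SELEX "family" is a cluster of abundant sequences within a fixed edit
distance of a representative; tracking a family's summed frequency per
round exposes the exponential enrichment of binders and the diversity
collapse of late rounds.

Clustering is greedy and abundance-seeded: candidates are processed in
decreasing total-count order, and each either joins the first existing
family whose representative lies within ``max_dist`` edits or founds a
new family.  The representative is therefore always the most abundant
member, and all members satisfy the radius bound
``levenshtein(member, representative) <= max_dist``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .ingest import RoundLibrary, normalize_sequence


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def _within(a: str, b: str, k: int) -> bool:
    """Bounded edit-distance test; cheaper than a full distance for large k-fails."""
    return edlib.align(a, b, task="distance", k=k)["editDistance"] != -1


@dataclass
class CandidateSet:
    """Sequences reaching an abundance threshold in at least one round.

    ``max_frequency`` records, per sequence, the highest per-round
    frequency attained (provenance for the threshold decision);
    ``total_counts`` sums read counts across all supplied rounds and
    drives the clustering order.
    """

    sequences: list[str]
    threshold: float
    max_frequency: dict[str, float]
    total_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class Family:
    """One sequence family: representative, members, and total abundance."""

    family_id: str
    representative: str
    members: frozenset[str]
    total_count: int

    def __len__(self) -> int:
        return len(self.members)


def select_candidates(
    libs: Sequence[RoundLibrary], threshold: float = 1e-5
) -> CandidateSet:
    """Sequences whose frequency reaches ``threshold`` (inclusive) in >=1 round.

    The default 1e-5 is the 0.001 % rule commonly applied to deep SELEX
    sequencing.
    """
    nonempty = [lib for lib in libs if lib.total > 0]
    if not nonempty:
        raise ValueError("candidate selection requires at least one non-empty library")
    max_freq: dict[str, float] = {}
    totals: dict[str, int] = {}
    for lib in nonempty:
        lib_total = lib.total
        for seq, count in lib.counts.items():
            f = count / lib_total
            if f > max_freq.get(seq, 0.0):
                max_freq[seq] = f
            totals[seq] = totals.get(seq, 0) + count
    kept = [s for s, f in max_freq.items() if f >= threshold]
    kept.sort(key=lambda s: (-totals[s], s))
    return CandidateSet(
        sequences=kept,
        threshold=threshold,
        max_frequency={s: max_freq[s] for s in kept},
        total_counts={s: totals[s] for s in kept},
    )


def cluster_families(candidates: CandidateSet, max_dist: int = 7) -> list[Family]:
    """Greedy abundance-seeded clustering at edit distance ``max_dist``.

    Candidates are processed in decreasing total-count order (ties broken
    lexicographically); each joins the first family whose representative
    is within ``max_dist`` edits (inclusive), else founds a new family.
    Family ids F0, F1, ... are assigned by decreasing family total count
    after clustering.
    """
    if len(candidates) == 0:
        raise ValueError("cannot cluster an empty candidate set")
    reps: list[str] = []
    members: list[list[str]] = []
    totals: list[int] = []
    order = sorted(
        candidates.sequences, key=lambda s: (-candidates.total_counts[s], s)
    )
    for seq in order:
        placed = False
        for i, rep in enumerate(reps):
            if _within(seq, rep, max_dist):
                members[i].append(seq)
                totals[i] += candidates.total_counts[seq]
                placed = True
                break
        if not placed:
            reps.append(seq)
            members.append([seq])
            totals.append(candidates.total_counts[seq])
    rank = sorted(range(len(reps)), key=lambda i: (-totals[i], reps[i]))
    return [
        Family(
            family_id=f"F{j}",
            representative=reps[i],
            members=frozenset(members[i]),
            total_count=totals[i],
        )
        for j, i in enumerate(rank)
    ]


def family_trajectory(
    family: Family, libs: Sequence[RoundLibrary]
) -> np.ndarray:
    """Per-round summed member frequency (members absent in a round add 0)."""
    traj = np.zeros(len(libs))
    for t, lib in enumerate(libs):
        total = lib.total
        if total == 0:
            continue
        traj[t] = sum(lib.counts.get(m, 0) for m in family.members) / total
    return traj


def diversity_per_round(
    families: Sequence[Family],
    libs: Sequence[RoundLibrary],
    presence_threshold: float | None = None,
) -> np.ndarray:
    """Number of families present per round.

    A family is present when its trajectory entry is > 0, or >=
    ``presence_threshold`` when one is given.
    """
    counts = np.zeros(len(libs), dtype=int)
    for fam in families:
        traj = family_trajectory(fam, libs)
        present = traj > 0 if presence_threshold is None else traj >= presence_threshold
        counts += present.astype(int)
    return counts


def frequency_matrix(
    families: Sequence[Family],
    libs: Sequence[RoundLibrary],
    round_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Families x rounds matrix of summed member frequencies (heat-map input)."""
    labels = (
        list(round_labels)
        if round_labels is not None
        else [f"{lib.selex_id}_r{lib.round_index}" for lib in libs]
    )
    data = {fam.family_id: family_trajectory(fam, libs) for fam in families}
    return pd.DataFrame(data, index=labels).T


def write_family_tables(
    families: Sequence[Family],
    libs: Sequence[RoundLibrary],
    out_dir: str | Path,
) -> None:
    """Write families.tsv, members.tsv and the families x rounds matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = frequency_matrix(families, libs)
    rows = []
    for fam in families:
        rows.append(
            {
                "family_id": fam.family_id,
                "representative": fam.representative,
                "n_members": len(fam),
                "total_count": fam.total_count,
                **{c: mat.loc[fam.family_id, c] for c in mat.columns},
            }
        )
    pd.DataFrame(rows).to_csv(out / "families.tsv", sep="\t", index=False)
    member_rows = [
        {"sequence": m, "family_id": fam.family_id}
        for fam in families
        for m in sorted(fam.members)
    ]
    pd.DataFrame(member_rows).to_csv(out / "members.tsv", sep="\t", index=False)
    mat.to_csv(out / "family_frequency_matrix.tsv", sep="\t")
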