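"""Approximate motif search and per-round motif prevalence.

A motif "occurs" in a sequence when some substring aligns to the full
motif pattern with at most ``max_edits`` unit-cost edits (semi-global
alignment: the pattern is consumed entirely, the subject's ends are
free).  Family-level membership is judged on the family representative
by default; a strict mode scans every member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import edlib
import numpy as np
import pandas as pd

from .families import Family, family_trajectory
from .ingest import RoundLibrary, normalize_sequence


class MotifHit(NamedTuple):
    """Best semi-global match of a motif in a subject sequence."""

    found: bool
    edits: int | None
    start: int | None
    end: int | None  # inclusive end, subject coordinates


@dataclass(frozen=True)
class Motif:
    """A conserved sequence motif searched with an edit tolerance.

    ``pattern`` is DNA-normalized on construction (U -> T); ``max_edits``
    defaults to 1, the usual tolerance for motif scans over SELEX family
    representatives.
    """

    name: str
    pattern: str
    max_edits: int = 1

    def __post_init__(self):
        object.__setattr__(self, "pattern", normalize_sequence(self.pattern))
        if len(self.pattern) < 4:
            raise ValueError(f"motif {self.name!r}: pattern must be >= 4 nt")
        if self.max_edits >= len(self.pattern):
            raise ValueError(f"motif {self.name!r}: max_edits must be < pattern length")


def approx_contains(motif: Motif, seq: str) -> MotifHit:
    """Best match of ``motif.pattern`` as an approximate substring of ``seq``.

    Semi-global (infix) alignment, unit edit costs.  Returns the minimal
    edit count and the first best-match location, or a non-found hit when
    no substring aligns within ``motif.max_edits`` edits.
    """
    seq = normalize_sequence(seq)
    res = edlib.align(
        motif.pattern, seq, mode="HW", task="locations", k=motif.max_edits
    )
    if res["editDistance"] == -1:
        return MotifHit(False, None, None, None)
    start, end = res["locations"][0]
    # edlib may report a None start for zero-length prefixes of the subject
    return MotifHit(True, res["editDistance"], 0 if start is None else start, end)


def motif_prevalence(
    motif: Motif,
    families: Sequence[Family],
    libs: Sequence[RoundLibrary],
    check_all_members: bool = False,
) -> pd.DataFrame:
    """Per-round library fraction and family count carrying ``motif``.

    A family contains the motif when its representative matches
    (``check_all_members=True`` widens this to any member; a family still
    counts once regardless of how many members or positions match).
    ``library_fraction`` sums the trajectories of containing families.
    """
    containing = []
    for fam in families:
        if approx_contains(motif, fam.representative).found:
            containing.append(fam)
        elif check_all_members and any(
            approx_contains(motif, m).found for m in fam.members
        ):
            containing.append(fam)
    fraction = np.zeros(len(libs))
    for fam in containing:
        fraction += family_trajectory(fam, libs)
    rounds = [f"{lib.selex_id}_r{lib.round_index}" for lib in libs]
    return pd.DataFrame(
        {
            "round": rounds,
            "motif": motif.name,
            "library_fraction": fraction,
            "n_families": len(containing),
        }
    )


def prevalence_table(
    motifs: Sequence[Motif],
    families: Sequence[Family],
    libs: Sequence[RoundLibrary],
    check_all_members: bool = False,
) -> pd.DataFrame:
    """Long-form prevalence for several motifs (round x motif)."""
    return pd.concat(
        [
            motif_prevalence(m, families, libs, check_all_members=check_all_members)
            for m in motifs
        ],
        ignore_index=True,
    )
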