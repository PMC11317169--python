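"""Normalized enrichment ratios (RN) and median footprints for aptamer panels.

A footprinting assay incubates a defined mixture of ``n`` aptamers (plus
a scramble control) with a target, sequences the bound fraction, and
summarizes differential retention per aptamer ``a`` between a target
condition ``x`` and the starting mixture (condition 0) by a three-step
cascade over assigned-read frequencies ``f``:

    r_raw  = f(a, x) / f(a, 0)
    r_norm = r_raw / sum_a r_raw            (sums to 1 over the panel)
    RN     = (r_norm - 1/n) / (1/n) = n * r_norm - 1

By construction sum_a RN = 0 and RN lies in [-1, n-1]: RN = -1 signals
complete depletion, positive RN preferential retention.  The *footprint*
of a condition is the per-aptamer median RN across technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import pysam

from .families import levenshtein
from .ingest import normalize_sequence

#: condition label conventionally used for the starting mixture
REFERENCE_CONDITION = "0"


class PanelError(ValueError):
    """Raised when a panel definition cannot support unambiguous assignment."""


@dataclass(frozen=True)
class Panel:
    """Ordered list of named reference sequences (aptamers + scramble)."""

    names: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise PanelError("names and sequences differ in length")
        if len(set(self.names)) != len(self.names):
            raise PanelError("panel names must be unique")
        object.__setattr__(
            self, "sequences", tuple(normalize_sequence(s) for s in self.sequences)
        )

    @property
    def n(self) -> int:
        return len(self.names)

    def validate(self, max_dist: int = 3) -> None:
        """Reject panels whose references are too close for assignment.

        Any two references within ``max_dist`` edits of each other would
        make the minimal-distance assignment rule ambiguous for reads
        equal to either reference.
        """
        for i in range(self.n):
            for j in range(i + 1, self.n):
                d = levenshtein(self.sequences[i], self.sequences[j])
                if d <= max_dist:
                    raise PanelError(
                        f"panel members {self.names[i]!r} and {self.names[j]!r} are "
                        f"only {d} edits apart (assignment threshold {max_dist})"
                    )

    @classmethod
    def from_fasta(cls, path: str | Path, max_dist: int = 3) -> "Panel":
        names, seqs = [], []
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                names.append(rec.name)
                seqs.append(rec.sequence)
        panel = cls(names=tuple(names), sequences=tuple(seqs))
        panel.validate(max_dist)
        return panel

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.names, self.sequences):
                fh.write(f">{name}\n{seq}\n")


@dataclass
class AssayCounts:
    """Per-panel-member read counts for one (condition, replicate)."""

    condition: str
    replicate: int
    counts: dict[str, int]
    n_unassigned: int = 0

    @property
    def total_assigned(self) -> int:
        return sum(self.counts.values())

    def frequencies(self, panel: Panel) -> pd.Series:
        """Assigned-read frequencies over the panel (unassigned excluded)."""
        total = self.total_assigned
        if total == 0:
            raise ValueError(
                f"no panel reads in condition {self.condition!r} "
                f"replicate {self.replicate}"
            )
        return pd.Series(
            [self.counts.get(name, 0) / total for name in panel.names],
            index=list(panel.names),
            name=f"{self.condition}/{self.replicate}",
            dtype=float,
        )


def assign_reads(
    reads: Iterable[str],
    panel: Panel,
    max_dist: int = 3,
    condition: str = "x",
    replicate: int = 1,
) -> AssayCounts:
    """Assign each read to the unique closest panel member.

    A read is assigned when exactly one member attains the minimal edit
    distance and that distance is <= ``max_dist``; ties and distant reads
    are counted as unassigned.  Sequencing-error-free reads hit an exact
    hash; only the (few) mismatching reads pay for alignments.
    """
    panel.validate(max_dist)
    exact = {seq: name for name, seq in zip(panel.names, panel.sequences)}
    cache: dict[str, str | None] = {}
    counts = {name: 0 for name in panel.names}
    n_unassigned = 0
    for read in reads:
        read = normalize_sequence(read)
        name = exact.get(read)
        if name is None:
            if read in cache:
                name = cache[read]
            else:
                best_d, best_name, tie = max_dist + 1, None, False
                for pname, ref in zip(panel.names, panel.sequences):
                    r = edlib.align(read, ref, task="distance", k=max_dist)
                    d = r["editDistance"]
                    if d == -1:
                        continue
                    if d < best_d:
                        best_d, best_name, tie = d, pname, False
                    elif d == best_d:
                        tie = True
                name = None if tie else best_name
                cache[read] = name
        if name is None:
            n_unassigned += 1
        else:
            counts[name] += 1
    return AssayCounts(
        condition=condition,
        replicate=replicate,
        counts=counts,
        n_unassigned=n_unassigned,
    )


def enrichment_raw(
    f_x: pd.Series, f_0: pd.Series, pseudofrequency: float = 0.0
) -> pd.Series:
    """Raw enrichment r_raw = f(a, x) / f(a, 0) per panel member.

    Every member must be represented in the starting mixture (f_0 > 0);
    a zero in condition x legitimately yields r_raw = 0 (complete
    depletion).  ``pseudofrequency`` is added to both numerators and
    denominators when working at low depth.
    """
    f_0 = f_0.reindex(f_x.index)
    if f_0.isna().any() or (f_0 <= 0).any():
        missing = list(f_x.index[f_0.isna() | (f_0 <= 0)])
        raise ValueError(
            f"starting mixture must represent every panel member; zero/missing: {missing}"
        )
    return (f_x + pseudofrequency) / (f_0 + pseudofrequency)


def normalize(r_raw: pd.Series) -> pd.Series:
    """Renormalize raw enrichments onto the panel simplex (sums to 1)."""
    total = float(r_raw.sum())
    if total <= 0:
        raise ValueError("all raw enrichments are zero: no panel reads in condition x")
    return r_raw / total


def rn(r_norm: pd.Series | np.ndarray, n: int | None = None) -> pd.Series | np.ndarray:
    """Normalized enrichment ratio RN = (r_norm - 1/n) / (1/n) = n*r_norm - 1.

    With r_norm on the simplex, sum(RN) = 0 exactly and RN is bounded in
    [-1, n-1].
    """
    if n is None:
        n = len(r_norm)
    return n * r_norm - 1


def median_footprint(rn_by_replicate: pd.DataFrame) -> pd.Series:
    """Element-wise median RN across replicates (columns).

    With an even replicate count the median is the mean of the two
    central values (standard convention).
    """
    return rn_by_replicate.median(axis=1)


@dataclass
class FootprintTable:
    """Long-form per-replicate RN table plus the median footprint matrix.

    ``long`` has one row per (condition, replicate, member) with columns
    count, f, r_raw, r_norm, rn; ``median`` is members x conditions.
    """

    long: pd.DataFrame
    median: pd.DataFrame
    panel: Panel

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(out / "footprint_long.tsv", sep="\t", index=False)
        self.median.to_csv(out / "footprint_median.tsv", sep="\t")


def footprint_table(
    assays: Sequence[AssayCounts],
    panel: Panel,
    reference_condition: str = REFERENCE_CONDITION,
    pseudofrequency: float = 0.0,
) -> FootprintTable:
    """Run the RN cascade for every non-reference (condition, replicate).

    Each condition-x replicate is paired with the reference-condition
    measurement of the same replicate id; when the reference condition
    was measured once only, that single measurement serves all
    replicates.
    """
    refs = {a.replicate: a for a in assays if a.condition == reference_condition}
    if not refs:
        raise ValueError(f"no assays found for reference condition {reference_condition!r}")
    rows = []
    for assay in assays:
        if assay.condition == reference_condition:
            continue
        if assay.replicate in refs:
            ref = refs[assay.replicate]
        elif len(refs) == 1:
            ref = next(iter(refs.values()))
        else:
            raise ValueError(
                f"no reference replicate {assay.replicate} for condition "
                f"{assay.condition!r} and multiple reference replicates exist"
            )
        f_x = assay.frequencies(panel)
        f_0 = ref.frequencies(panel)
        r_raw = enrichment_raw(f_x, f_0, pseudofrequency=pseudofrequency)
        r_norm = normalize(r_raw)
        rn_vals = rn(r_norm, panel.n)
        for name in panel.names:
            rows.append(
                {
                    "condition": assay.condition,
                    "replicate": assay.replicate,
                    "member": name,
                    "count": assay.counts.get(name, 0),
                    "f": f_x[name],
                    "r_raw": r_raw[name],
                    "r_norm": r_norm[name],
                    "rn": rn_vals[name],
                }
            )
    long = pd.DataFrame(rows)
    if long.empty:
        raise ValueError("no non-reference assays supplied")
    median = (
        long.pivot_table(index="member", columns="condition", values="rn", aggfunc="median")
        .reindex(list(panel.names))
    )
    median.columns.name = None
    return FootprintTable(long=long, median=median, panel=panel)
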