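"""FASTQ ingestion: primer trimming, random-region recovery, round tables.

Amplicon reads from a SELEX round carry the structure
``5'-primer5 | random region | primer3-3'`` where the random region is
nominally 35 nt but may have gained or lost a few bases during selection
and amplification.  Trimming is *anchored*: the 5' primer is matched as a
prefix window with a bounded Hamming mismatch count, and the 3' primer
window is scanned over a small set of offsets around its nominal start so
that insert-length variation is absorbed without allowing indels inside
the primers themselves.  Recovered regions are then length-filtered to a
closed window (33-37 nt by default) and tallied into a per-round
frequency table.

Sequences are stored in the DNA alphabet throughout; RNA input (U) is
normalized to T on ingest.  Chemistry (e.g. 2'F-pyrimidine RNA) is
metadata only.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

logger = logging.getLogger(__name__)

_NORMALIZE = str.maketrans("acgtun", "ACGTTN")

#: rejection reasons used by :func:`extract_random_region` / :func:`build_round_library`
REJECT_PRIMER = "primer-not-found"
REJECT_LENGTH = "length"


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.translate(_NORMALIZE).upper().replace("U", "T")


@dataclass(frozen=True)
class TrimParams:
    """Primer-trimming and length-filter parameters.

    Parameters
    ----------
    primer5, primer3
        Constant regions flanking the random region (DNA alphabet).
    max_mismatch
        Maximum Hamming mismatches tolerated per primer window.  Ambiguous
        bases (N) count as mismatches.
    nominal_insert
        Designed random-region length; the 3' primer window is scanned at
        ``nominal_insert + offset`` for each offset in ``offset_range``.
    offset_range
        Inclusive (min, max) offsets for the 3'-primer scan; the default
        (-2, +2) admits inserts of 33-37 nt.
    length_window
        Closed retention interval for the recovered random region.
    min_mean_quality
        Optional mean-Phred threshold; ``None`` (default) disables quality
        filtering entirely.
    """

    primer5: str
    primer3: str
    max_mismatch: int = 2
    nominal_insert: int = 35
    offset_range: tuple[int, int] = (-2, 2)
    length_window: tuple[int, int] = (33, 37)
    min_mean_quality: float | None = None

    def __post_init__(self):
        if not self.primer5 or not self.primer3:
            raise ValueError("primers must be non-empty")
        object.__setattr__(self, "primer5", normalize_sequence(self.primer5))
        object.__setattr__(self, "primer3", normalize_sequence(self.primer3))


@dataclass
class TrimReport:
    """Per-file read accounting; kept + rejected partitions the raw total."""

    n_total: int = 0
    n_kept: int = 0
    n_rejected_primer: int = 0
    n_rejected_length: int = 0
    n_rejected_quality: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_random_region(
    read: str,
    primer5: str,
    primer3: str,
    max_mismatch: int = 2,
    nominal_insert: int = 35,
    offset_range: tuple[int, int] = (-2, 2),
) -> tuple[str | None, str | None]:
    """Recover the random region between anchored primer matches.

    Returns ``(region, None)`` on success or ``(None, reason)`` on
    rejection.  The 5' primer must match the read prefix within
    ``max_mismatch`` Hamming mismatches; the 3' primer window is scanned
    over ``nominal_insert + offset`` start positions, taking the
    minimal-mismatch offset (ties broken toward the smallest offset).
    """
    read = normalize_sequence(read)
    p5 = normalize_sequence(primer5)
    p3 = normalize_sequence(primer3)
    if not p5 or not p3:
        raise ValueError("primers must be non-empty")
    if len(read) < len(p5) + len(p3):
        return None, REJECT_PRIMER
    if _hamming(read[: len(p5)], p5) > max_mismatch:
        return None, REJECT_PRIMER

    best: tuple[int, int] | None = None  # (mismatches, offset)
    for offset in range(offset_range[0], offset_range[1] + 1):
        start = len(p5) + nominal_insert + offset
        if start < len(p5) or start + len(p3) > len(read):
            continue
        mm = _hamming(read[start : start + len(p3)], p3)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, offset)
    if best is None:
        return None, REJECT_PRIMER
    start = len(p5) + nominal_insert + best[1]
    return read[len(p5) : start], None


def length_filter(region: str, window: tuple[int, int] = (33, 37)) -> bool:
    """True iff the region length lies in the closed retention window."""
    return window[0] <= len(region) <= window[1]


@dataclass
class RoundLibrary:
    """Unique-sequence read counts for one SELEX round (or assay library).

    ``counts`` maps each kept, normalized random-region sequence to its
    read count; ``total`` is the kept-read denominator used for all
    frequencies (rejected reads never enter denominators).
    """

    selex_id: str
    round_index: int
    counts: dict[str, int] = field(default_factory=dict)
    report: TrimReport | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, seq: str) -> float:
        """Fraction of kept reads equal to ``seq`` (0 if absent)."""
        total = self.total
        if total == 0:
            raise ValueError(
                f"frequency undefined: library {self.selex_id!r} round "
                f"{self.round_index} has no kept reads"
            )
        return self.counts.get(seq, 0) / total

    def frequencies(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise ValueError("frequencies undefined for an empty library")
        return {s: c / total for s, c in self.counts.items()}

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, int], selex_id: str = "S", round_index: int = 0
    ) -> "RoundLibrary":
        return cls(selex_id=selex_id, round_index=round_index, counts=dict(counts))

    # -- TSV round-trip (sequence, count, frequency) --------------------

    def to_tsv(self, path: str | Path) -> None:
        total = self.total
        with open(path, "w") as fh:
            fh.write("sequence\tcount\tfrequency\n")
            for seq in sorted(self.counts, key=lambda s: (-self.counts[s], s)):
                c = self.counts[seq]
                f = c / total if total else 0.0
                fh.write(f"{seq}\t{c}\t{f:.10g}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, selex_id: str = "S", round_index: int = 0
    ) -> "RoundLibrary":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_seq, i_count = header.index("sequence"), header.index("count")
            except ValueError as exc:
                raise ValueError(f"{path}: expected 'sequence' and 'count' columns") from exc
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                counts[normalize_sequence(parts[i_seq])] = int(parts[i_count])
        return cls(selex_id=selex_id, round_index=round_index, counts=counts)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str | None]]:
    """Yield (sequence, quality-string) records from FASTQ or FASTQ.gz."""
    n = 0
    try:
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                n += 1
                yield rec.sequence, rec.quality
    except OSError as exc:
        raise IOError(f"failed reading FASTQ {path!s} at record {n + 1}: {exc}") from exc


def build_round_library(
    fastq_path: str | Path,
    params: TrimParams,
    selex_id: str = "S",
    round_index: int = 0,
) -> RoundLibrary:
    """Trim every read of one FASTQ and tally kept random regions.

    Deterministic for identical input.  An empty FASTQ yields a library
    with total 0 and a logged warning.
    """
    counts: dict[str, int] = {}
    report = TrimReport()
    for seq, qual in iter_fastq(fastq_path):
        report.n_total += 1
        if params.min_mean_quality is not None and qual:
            mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
            if mean_q < params.min_mean_quality:
                report.n_rejected_quality += 1
                continue
        region, reason = extract_random_region(
            seq,
            params.primer5,
            params.primer3,
            max_mismatch=params.max_mismatch,
            nominal_insert=params.nominal_insert,
            offset_range=params.offset_range,
        )
        if region is None:
            report.n_rejected_primer += 1
            continue
        if not length_filter(region, params.length_window):
            report.n_rejected_length += 1
            continue
        report.n_kept += 1
        counts[region] = counts.get(region, 0) + 1
    if report.n_total == 0:
        logger.warning("FASTQ %s contained no reads", fastq_path)
    return RoundLibrary(
        selex_id=selex_id, round_index=round_index, counts=counts, report=report
    )


def frequency(seq: str, lib: RoundLibrary) -> float:
    """Frequency of ``seq`` among kept reads of ``lib`` (0 if absent)."""
    return lib.frequency(normalize_sequence(seq))
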