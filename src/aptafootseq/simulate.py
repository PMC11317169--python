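"""Synthetic SELEX rounds and footprinting assays with planted ground truth.

The generator produces data with the same shape as a real selection
campaign — FASTQ reads of a random 35-mer flanked by constant primer
sites, enriched round over round — but from a fully known model, so
every downstream stage (trimming, family clustering, motif prevalence,
RN footprints, tree building) can be checked against planted truth.

Selection is modeled as one multiplicative fitness step per round: if
``f`` are the current population fractions and ``w`` the per-lineage
fitnesses, the post-selection expectation is ``f' = w f / sum(w f)``
(the replicator recurrence), after which the sequenced sample is a
multinomial draw at the requested depth.  Planted families mutate at a
per-base rate ``mu`` (heritable; mutants stay in their family), and
sequencing adds non-heritable substitution errors at per-base rate
``epsilon``.  The unselected background (fitness 1 by default) is drawn
fresh each round as unique random 35-mers.

Assays are simpler: condition-0 counts are multinomial draws from the
known starting composition ``f0`` and condition-x counts from the known
bound composition ``q``, with the analytic truth
``RN = n * ((q/f0) / sum(q/f0)) - 1`` recorded alongside.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .footprint import Panel, AssayCounts
from .ingest import RoundLibrary

# constant regions of the amplicon design (DNA alphabet)
DEFAULT_PRIMER5 = "CCTACACGACGCTCTTCCGATCT"
DEFAULT_PRIMER3 = "TCAGCCTCAACGGATACTCTCCC"

#: default names for a 15-member assay panel (14 aptamers + scramble control)
PANEL_NAMES = (
    "F0", "F0AC", "F1", "F2", "F3", "F4", "F5", "F15",
    "F20", "F30", "F62", "F73", "F124", "F164", "Scr",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq_array(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n random DNA sequences, vectorized."""
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    letters = _BASES[codes]
    return [row.tobytes().decode() for row in np.ascontiguousarray(letters)]


def random_sequence(rng: np.random.Generator, length: int = 35) -> str:
    return _random_seq_array(rng, 1, length)[0]


def _substitute(seq: str, rng: np.random.Generator, n_subs: int) -> str:
    """Apply n_subs substitutions at distinct positions (base always changes)."""
    arr = bytearray(seq.encode())
    for pos in rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False):
        old = arr[pos]
        choices = [b for b in b"ACGT" if b != old]
        arr[pos] = choices[rng.integers(0, 3)]
    return arr.decode()


def _sequencing_noise(
    seq: str, rng: np.random.Generator, error_rate: float, indel_rate: float = 0.0
) -> str:
    """Non-heritable read-level noise: substitutions, optional 1-nt indels."""
    if error_rate > 0:
        n_err = rng.binomial(len(seq), error_rate)
        if n_err:
            seq = _substitute(seq, rng, n_err)
    if indel_rate > 0 and rng.random() < indel_rate:
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5 and len(seq) > 1:
            seq = seq[:pos] + seq[pos + 1 :]
        else:
            seq = seq[:pos] + "ACGT"[rng.integers(0, 4)] + seq[pos:]
    return seq


def replicator_step(fractions: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """One deterministic selection step: f' = w f / sum(w f)."""
    wf = np.asarray(fractions, dtype=float) * np.asarray(fitness, dtype=float)
    total = wf.sum()
    if total <= 0:
        raise ValueError("degenerate selection: all fitness-weighted fractions are 0")
    return wf / total


# ---------------------------------------------------------------------------
# SELEX simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedFamily:
    """A planted founder lineage: 35-mer, multiplicative fitness, start fraction."""

    name: str
    founder: str
    fitness: float
    initial_fraction: float


@dataclass
class SelexScenario:
    """Conditions for one simulated selection campaign.

    Defaults mirror a desk-scale campaign: 15 rounds sequenced at 1e5
    reads per round, per-base heritable mutation rate 1e-3 and per-base
    sequencing error 1e-3.  ``background_fraction`` (the unselected part
    of the starting pool) is inferred as 1 - sum(initial fractions).
    """

    seed_families: Sequence[SeedFamily]
    n_rounds: int = 15
    reads_per_round: int = 100_000
    background_fitness: float = 1.0
    mutation_rate: float = 1e-3
    error_rate: float = 1e-3
    indel_error_rate: float = 0.0
    region_length: int = 35
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    rng_seed: int = 0

    def __post_init__(self):
        planted = sum(f.initial_fraction for f in self.seed_families)
        if planted > 1 + 1e-12:
            raise ValueError("initial family fractions exceed 1")
        if any(f.fitness < 0 for f in self.seed_families) or self.background_fitness < 0:
            raise ValueError("fitness must be >= 0")
        if self.background_fraction == 0 and all(
            f.fitness == 0 for f in self.seed_families
        ):
            raise ValueError("degenerate scenario: every lineage has fitness 0")
        if min(self.mutation_rate, self.error_rate, self.indel_error_rate) < 0:
            raise ValueError("rates must be >= 0")

    @property
    def background_fraction(self) -> float:
        return max(0.0, 1.0 - sum(f.initial_fraction for f in self.seed_families))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelexScenario":
        cfg = yaml.safe_load(Path(path).read_text())
        fams = [SeedFamily(**f) for f in cfg.pop("seed_families")]
        return cls(seed_families=fams, **cfg)


def planted_selex_scenario(
    n_families: int = 10,
    fitness_range: tuple[float, float] = (1.8, 3.0),
    total_initial_fraction: float = 0.1,
    seed: int = 0,
    **kwargs,
) -> SelexScenario:
    """Convenience scenario: n founders with log-spaced fitnesses.

    Fitnesses are log-spaced across ``fitness_range`` so that even the
    weakest planted lineage outcompetes the neutral background and stays
    detectable at desk-scale depth through the final round.
    """
    rng = np.random.default_rng(seed)
    founders = _random_seq_array(rng, n_families, kwargs.get("region_length", 35))
    fitnesses = np.geomspace(fitness_range[0], fitness_range[1], n_families)
    frac = total_initial_fraction / n_families
    fams = [
        SeedFamily(name=f"P{i}", founder=s, fitness=float(w), initial_fraction=frac)
        for i, (s, w) in enumerate(zip(founders, fitnesses))
    ]
    return SelexScenario(seed_families=fams, rng_seed=seed, **kwargs)


@dataclass
class SelexResult:
    """Planted-truth bookkeeping for one simulated campaign.

    ``round_counts[t]`` are the sequenced unique-sequence counts of round
    t+1 (before sequencing error, which is applied only when reads are
    emitted); ``truth`` is the families x rounds fraction matrix;
    ``membership`` maps every planted-lineage sequence ever sequenced to
    its family name (background sequences are absent).
    """

    scenario: SelexScenario
    round_counts: list[dict[str, int]]
    truth: pd.DataFrame
    membership: dict[str, str]

    def round_libraries(self, selex_id: str = "SIM") -> list[RoundLibrary]:
        """Expose the sequenced rounds as in-memory frequency tables."""
        return [
            RoundLibrary.from_counts(c, selex_id=selex_id, round_index=t + 1)
            for t, c in enumerate(self.round_counts)
        ]


def run_selex(scenario: SelexScenario) -> SelexResult:
    """Simulate the campaign in memory (no files, no sequencing error)."""
    rng = np.random.default_rng(scenario.rng_seed)
    L = scenario.region_length
    fams = list(scenario.seed_families)
    # population of planted lineages: seq -> (family index, fraction)
    pop: dict[str, tuple[int, float]] = {
        f.founder: (i, f.initial_fraction) for i, f in enumerate(fams)
    }
    membership: dict[str, str] = {f.founder: f.name for f in fams}
    bg_fraction = scenario.background_fraction
    reads = scenario.reads_per_round

    round_counts: list[dict[str, int]] = []
    truth_rows = []
    for _ in range(scenario.n_rounds):
        seqs = list(pop)
        fracs = np.array([pop[s][1] for s in seqs] + [bg_fraction])
        fits = np.array(
            [fams[pop[s][0]].fitness for s in seqs] + [scenario.background_fitness]
        )
        expected = replicator_step(fracs, fits)
        sampled = rng.multinomial(reads, expected)
        counts: dict[str, int] = {}
        new_pop: dict[str, tuple[int, float]] = {}
        p_mut = 1.0 - (1.0 - scenario.mutation_rate) ** L
        for seq, c in zip(seqs, sampled[:-1]):
            if c == 0:
                continue
            fam_idx = pop[seq][0]
            n_mut = rng.binomial(c, p_mut) if p_mut > 0 else 0
            if c - n_mut > 0:
                counts[seq] = counts.get(seq, 0) + int(c - n_mut)
            for _m in range(n_mut):
                k = max(1, rng.binomial(L, scenario.mutation_rate))
                mut = _substitute(seq, rng, k)
                counts[mut] = counts.get(mut, 0) + 1
                membership.setdefault(mut, fams[fam_idx].name)
            # mutants inherit family; record/refresh lineage fractions below
        b = int(sampled[-1])
        if b:
            for s in _random_seq_array(rng, b, L):
                counts[s] = counts.get(s, 0) + 1
        # next-round composition = sequenced composition
        fam_index = {f.name: i for i, f in enumerate(fams)}
        fam_totals = np.zeros(len(fams))
        for seq, c in counts.items():
            fam_name = membership.get(seq)
            if fam_name is None:
                continue
            idx = fam_index[fam_name]
            new_pop[seq] = (idx, c / reads)
            fam_totals[idx] += c
        pop = new_pop
        bg_fraction = 1.0 - sum(v[1] for v in pop.values())
        round_counts.append(counts)
        truth_rows.append(fam_totals / reads)

    truth = pd.DataFrame(
        np.array(truth_rows).T,
        index=[f.name for f in fams],
        columns=[f"r{t + 1}" for t in range(scenario.n_rounds)],
    )
    return SelexResult(
        scenario=scenario,
        round_counts=round_counts,
        truth=truth,
        membership=membership,
    )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        # mtime=0 keeps output byte-identical across runs with the same seed
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
    return open(path, "wb")


def _write_fastq(
    path: Path,
    regions: Sequence[tuple[str, int]],
    scenario_primer5: str,
    scenario_primer3: str,
    rng: np.random.Generator,
    error_rate: float,
    indel_rate: float,
    name_prefix: str,
) -> None:
    with _open_maybe_gz(path) as fh:
        i = 0
        for region, count in regions:
            for _ in range(count):
                read = scenario_primer5 + region + scenario_primer3
                read = _sequencing_noise(read, rng, error_rate, indel_rate)
                qual = "?" * len(read)  # constant Q30 placeholder
                fh.write(f"@{name_prefix}_{i}\n{read}\n+\n{qual}\n".encode())
                i += 1


def simulate_selex(
    scenario: SelexScenario, out_dir: str | Path, gzip_output: bool = True
) -> SelexResult:
    """Run :func:`run_selex` and write per-round FASTQ plus truth tables.

    Deterministic: the same scenario (including seed) yields
    byte-identical files.
    """
    result = run_selex(scenario)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    err_rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 1]))
    ext = ".fastq.gz" if gzip_output else ".fastq"
    for t, counts in enumerate(result.round_counts, start=1):
        regions = sorted(counts.items())
        _write_fastq(
            out / f"round_{t:02d}{ext}",
            regions,
            scenario.primer5,
            scenario.primer3,
            err_rng,
            scenario.error_rate,
            scenario.indel_error_rate,
            f"sim_r{t}",
        )
    result.truth.to_csv(out / "truth_family_frequencies.tsv", sep="\t")
    pd.DataFrame(
        [{"sequence": s, "family": f} for s, f in sorted(result.membership.items())]
    ).to_csv(out / "truth_membership.tsv", sep="\t", index=False)
    return result


# ---------------------------------------------------------------------------
# Assay simulation
# ---------------------------------------------------------------------------


@dataclass
class AssayScenario:
    """Conditions for simulated footprinting assays.

    ``f0`` is the starting-mixture composition (default equimolar over
    the panel); ``q`` maps each condition label to the bound-fraction
    composition the assay samples from.  Depth and replication default
    to the usual assay scale: 1e5 reads, 3 technical replicates.
    """

    panel: Panel
    q: Mapping[str, Sequence[float]]
    f0: Sequence[float] | None = None
    reads_per_assay: int = 100_000
    replicates: int = 3
    error_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self):
        n = self.panel.n
        if self.f0 is None:
            self.f0 = np.full(n, 1.0 / n)
        self.f0 = np.asarray(self.f0, dtype=float)
        if len(self.f0) != n or abs(self.f0.sum() - 1) > 1e-9:
            raise ValueError("f0 must be a probability vector over the panel")
        if (self.f0 <= 0).any():
            raise ValueError("starting mixture must represent every panel member")
        self.q = {c: np.asarray(v, dtype=float) for c, v in self.q.items()}
        for cond, vec in self.q.items():
            if len(vec) != n or abs(vec.sum() - 1) > 1e-9 or (vec < 0).any():
                raise ValueError(f"q[{cond!r}] must be a probability vector")

    @classmethod
    def from_yaml(cls, path: str | Path, panel: Panel) -> "AssayScenario":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(panel=panel, **cfg)


def truth_rn(f0: Sequence[float], q: Sequence[float]) -> np.ndarray:
    """Analytic RN implied by a bound composition q and start composition f0."""
    f0 = np.asarray(f0, dtype=float)
    q = np.asarray(q, dtype=float)
    ratio = q / f0
    return len(f0) * ratio / ratio.sum() - 1.0


@dataclass
class AssayResult:
    """Simulated assay count tables plus the analytic truth footprints."""

    scenario: AssayScenario
    assays: list[AssayCounts]
    truth: pd.DataFrame  # members x conditions, analytic RN


def simulate_assay(scenario: AssayScenario) -> AssayResult:
    """Multinomial count tables per (condition, replicate), plus truth RN.

    Condition "0" (the starting mixture) is sampled from ``f0`` and every
    other condition from its bound composition ``q``; each replicate is
    an independent draw at the configured depth.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    names = list(scenario.panel.names)
    assays: list[AssayCounts] = []
    for rep in range(1, scenario.replicates + 1):
        draw = rng.multinomial(scenario.reads_per_assay, scenario.f0)
        assays.append(
            AssayCounts(condition="0", replicate=rep, counts=dict(zip(names, map(int, draw))))
        )
    for cond, qvec in scenario.q.items():
        for rep in range(1, scenario.replicates + 1):
            draw = rng.multinomial(scenario.reads_per_assay, qvec)
            assays.append(
                AssayCounts(
                    condition=str(cond),
                    replicate=rep,
                    counts=dict(zip(names, map(int, draw))),
                )
            )
    truth = pd.DataFrame(
        {str(c): truth_rn(scenario.f0, qvec) for c, qvec in scenario.q.items()},
        index=names,
    )
    return AssayResult(scenario=scenario, assays=assays, truth=truth)


def assay_reads(
    counts: AssayCounts,
    panel: Panel,
    rng: np.random.Generator,
    error_rate: float = 1e-3,
) -> list[str]:
    """Expand a count table into reads with substitution sequencing errors."""
    ref = dict(zip(panel.names, panel.sequences))
    reads: list[str] = []
    for name, c in counts.counts.items():
        seq = ref[name]
        for _ in range(c):
            reads.append(_sequencing_noise(seq, rng, error_rate))
    return reads


def write_assay_fastq(result: AssayResult, out_dir: str | Path) -> Path:
    """Write per-(condition, replicate) FASTQ, a manifest and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = result.scenario
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 2]))
    manifest = []
    for assay in result.assays:
        fname = f"assay_c{assay.condition}_rep{assay.replicate}.fastq.gz"
        reads = assay_reads(assay, scenario.panel, rng, scenario.error_rate)
        with _open_maybe_gz(out / fname) as fh:
            for i, read in enumerate(reads):
                fh.write(f"@sim_{assay.condition}_{assay.replicate}_{i}\n{read}\n+\n{'?' * len(read)}\n".encode())
        manifest.append(
            {"condition": assay.condition, "replicate": assay.replicate, "fastq": fname}
        )
    scenario.panel.to_fasta(out / "panel.fasta")
    (out / "manifest.yaml").write_text(yaml.safe_dump({"assays": manifest}))
    result.truth.to_csv(out / "truth_rn.tsv", sep="\t")
    return out


def random_panel(
    n: int = 15,
    length: int = 35,
    min_dist: int = 8,
    seed: int | np.random.Generator = 0,
    names: Sequence[str] | None = None,
) -> Panel:
    """A synthetic panel of mutually distant random references.

    Candidates are drawn until all pairwise edit distances exceed
    ``min_dist`` (random 35-mers are typically ~20 edits apart, so
    rejection is rare).  Default names follow the usual 14-aptamer +
    scramble layout when n = 15.
    """
    import edlib

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if names is None:
        names = PANEL_NAMES if n == len(PANEL_NAMES) else tuple(
            [f"A{i:02d}" for i in range(1, n)] + ["Scr"]
        )
    refs: list[str] = []
    while len(refs) < n:
        cand = random_sequence(rng, length)
        if all(
            edlib.align(cand, r, task="distance", k=min_dist)["editDistance"] == -1
            for r in refs
        ):
            refs.append(cand)
    return Panel(names=tuple(names), sequences=tuple(refs))
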