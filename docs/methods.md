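# Methods

## Read trimming and frequency tables (`ingest`)

Amplicon reads have the structure `primer5 | random region | primer3`
with a nominally 35-nt random region that commonly gains or loses a few
bases during selection. Primer matching is **anchored**: `primer5` is
matched as a prefix window and `primer3` as a window starting at
`len(primer5) + 35 + offset` for offsets −2…+2, each within a Hamming
mismatch budget (default 2 per primer, ambiguous bases counting as
mismatches). The minimal-mismatch offset wins, ties going to the
smallest offset. No indels are allowed inside primers — the library
design fixes their positions, and insert-length variation is absorbed by
the offset scan. Recovered regions are retained when their length lies
in the closed window [33, 37].

Sequences are DNA-normalized (U→T, uppercased); chemistry is metadata.
Quality scores are ignored by default (an optional mean-Phred threshold
exists but is off). Frequencies are computed over **kept** reads only;
rejected reads never enter denominators. The invariant
`kept + rejected(primer) + rejected(length) = total` is enforced by
construction and tested.

## Family clustering (`families`)

Candidates are all sequences whose frequency reaches the threshold
(default 1e-5, i.e. 0.001 %, inclusive) in at least one round.
Clustering is **greedy, abundance-seeded and representative-anchored**:
candidates in decreasing total-count order (ties lexicographic) either
join the first family whose representative is within `max_dist`
Levenshtein edits (default 7, inclusive) or found a new family. This is
deterministic, O(n·k) for k families, and guarantees the radius bound
(every member within `max_dist` of its representative) and
cross-representative separation (> `max_dist`). It is not single
linkage: two members of one family may be up to `2·max_dist` apart.
Family ids F0, F1, … rank families by total count. Edit distances come
from edlib; the test suite checks them against an independent
dynamic-programming oracle, and the clusterer against a re-implementation.

"Distance of 7" is read inclusively (≤ 7); `max_dist` is exposed for the
strict reading (use 6).

## Motif prevalence (`motifs`)

A motif occurs in a sequence when some substring aligns to the full
pattern within `max_edits` unit-cost edits (semi-global alignment, edlib
HW mode; tolerance default 1). Families are judged by their
representative (a `check_all_members` mode widens this to any member); a
family counts once per motif regardless of hit multiplicity. Prevalence
per round is the summed trajectory of containing families plus their
count. With `max_edits = 0` the search reduces to exact substring
matching, which is tested against a naive scan.

## Footprints (`footprint`)

Panel reads are assigned to the member with the uniquely minimal edit
distance ≤ 3 (default); ties and distant reads are unassigned, and panel
loading rejects any two references within the assignment threshold.
Frequencies are computed over assigned reads only — the mixture is
closed over the panel, so contaminants must not distort the simplex.

The cascade `r_raw → r_norm → RN` is computed per (condition,
replicate), then the footprint takes the per-member **median across
replicates** (even counts: mean of the central pair) — ratios first,
median second. Each condition-x replicate i is normalized against
condition-0 replicate i; a single condition-0 measurement serves all
replicates. Σ RN = 0 follows algebraically from RN = n·r_norm − 1 with
r_norm on the simplex, and is asserted to 1e-9 in tests.

Zero counts in condition x give r_raw = 0 and RN = −1 (complete
depletion) with no pseudocount; a `pseudofrequency` option exists for
very low-depth data.

## Footprint comparison (`clustering`)

Conditions are compared on their median footprints by d = 1 − Pearson r
(centered by default; an uncentered variant is provided because
Cluster-3.0-family tools offer both). Agglomerative clustering defaults
to average linkage (the Cluster-3.0/TreeView default; single and
complete are flags). Labels are sorted lexicographically before linkage
so equal-height merges resolve deterministically. Trees serialize to
Newick (branch lengths from merge heights, ultrametric under average
linkage; round-trip tested via scikit-bio) and to a `.cdt`/`.gtr` pair
with similarities 1 − height. Replicate reproducibility is summarized as
the squared Pearson correlation between replicate RN vectors.

## Synthetic data (`simulate`)

Selection is one multiplicative fitness step per round — the replicator
recurrence `f' = w·f / Σ w·f` — followed by a multinomial draw at the
sequencing depth. Planted founder lineages carry fitness `w` and initial
fractions; the unselected background (fitness 1) is drawn fresh each
round as unique random 35-mers. Heritable mutation applies per base at
rate μ (default 1e-3), mutants inheriting family membership; sequencing
adds non-heritable substitution errors at ε per base (default 1e-3,
optional 1-nt indels to exercise the length window), with constant-Q30
quality strings. Same seed ⇒ byte-identical FASTQ (gzip written with
zeroed mtime). Assays are multinomial draws from a known starting
composition `f0` (default equimolar) and per-condition bound
compositions `q`, with the analytic truth
`RN = n·((q/f0)/Σ(q/f0)) − 1` recorded alongside.

What this emulates: exponential family enrichment, late-round diversity
collapse, counting noise at assay depth, sequencing error, and a
no-selection control (`q = f0`). What it does not: PCR chimeras and
amplification bias, realistic Illumina error profiles, wash/elution
kinetics, and competition or cooperativity between aptamers in a
mixture. Passing recovery tests therefore validates the **analysis
code**, not the biochemical assumptions of an experiment.

### Problem sizes and scenario choices

End-to-end checks run at desk scale: assays at 100 000 reads × 3
replicates (the typical per-assay depth), selection campaigns at 15
rounds × 100 000 reads with 10 planted lineages. At this depth the
0.001 % candidate rule would admit single-read sequences, so the scaled
campaign uses a threshold of 5e-4 — a ~50-read cutoff, the same
stringency the 0.001 % rule has at the multi-million-read depth of a
real campaign. Planted fitnesses are log-spaced over 1.8–3.0 against a
neutral background, chosen from the deterministic replicator expectation
so that even the weakest lineage remains detectable in the final round
at this depth.

## Numerical conventions

* Medians: numpy convention (mean of central pair for even counts).
* Distance matrices are symmetrized and clipped to [0, 2] before
  linkage to absorb floating-point asymmetry in the correlation matrix.
* Abundance ties everywhere break lexicographically; clustering output
  is therefore a pure function of its input.
* Zero-variance footprints and empty libraries raise errors naming the
  offending condition or file rather than propagating NaNs.

## Known limitations

* Greedy clustering depends on processing order; a different seed
  ranking (e.g. joint vs separate clustering of two selection arms) can
  split or merge borderline families. Representatives, not consensus
  sequences, define families.
* Read assignment assumes panel references are mutually distant; panels
  with near-duplicate members (edit distance ≤ the assignment threshold)
  are rejected rather than disambiguated.
* The simulator's background never re-samples the same sequence across
  rounds, which slightly understates background family persistence.
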