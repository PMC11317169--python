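# aptafootseq

Analysis toolkit for aptamer selection (SELEX) sequencing and
**aptamer-footprint assays**: given deep-sequenced selection rounds it
tracks the enrichment of sequence families, and given sequencing of a
defined aptamer mixture bound to a target it quantifies differential
retention as a per-aptamer *footprint* that can discriminate structurally
distinct targets (e.g. amyloid fibril polymorphs, the "strains" of
α-synuclein).

It is written for molecular-biology groups running SELEX campaigns and
footprinting assays who want a tested, scriptable replacement for
spreadsheet pipelines.

## What it computes

**SELEX enrichment.** Reads are trimmed of their constant primer-binding
sites, random regions of 33–37 nt are retained, and per-round frequency
tables are built. Sequences reaching a frequency of at least 0.001 %
(1e-5) in one round become candidates and are clustered greedily into
families at Levenshtein distance ≤ 7 from an abundant representative;
family trajectories, diversity per round, and the prevalence of
user-supplied motifs (matched semi-globally with an edit tolerance,
default 1) are reported per round.

**Footprints.** Reads from an assay of a defined n-member mixture
(n = 15 by convention: 14 aptamers + a scramble control) are assigned to
panel members by minimal edit distance. For each aptamer *a* and target
condition *x* versus the starting mixture (condition 0):

    r_{a,x/0} = f_{a,C=x} / f_{a,C=0}
    r_{a,x}   = r_{a,x/0} / Σ_{a∈A} r_{a,x/0}
    RN_a      = (r_{a,x} − 1/n) / (1/n)  =  n·r_{a,x} − 1

RN sums to zero over the panel and lies in [−1, n−1]; the footprint of a
condition is the per-aptamer median RN over technical replicates.
Footprints are compared by the Pearson-correlation distance
d = 1 − r and clustered (average linkage by default), with Newick and
Cluster-3.0-style `.cdt`/`.gtr` export for tree viewers.

**Simulation.** A generator produces synthetic SELEX rounds (replicator
selection + multinomial sequencing + mutation/sequencing error) and
assay count tables with planted ground truth, so the whole pipeline is
testable without downloads.

## Worked example

```python
import numpy as np
from aptafootseq import (AssayScenario, simulate_assay, footprint_table,
                         pearson_distance, hierarchical_cluster, random_panel)

panel = random_panel(n=15, seed=7)             # 14 aptamers + scramble
rng = np.random.default_rng(7)
scenario = AssayScenario(
    panel=panel,
    q={"Ftype": rng.dirichlet(np.full(15, 3.0)),   # bound compositions
       "Rtype": rng.dirichlet(np.full(15, 3.0)),
       "no_protein": np.full(15, 1 / 15)},         # no-selection control
    rng_seed=7,
)
result = simulate_assay(scenario)                  # 3 replicates, 1e5 reads each
table = footprint_table(result.assays, panel)
print(table.median.round(3))
tree = hierarchical_cluster(pearson_distance(table.median))
print(tree.newick)
```

prints the median footprint matrix (members × conditions)

```
        Ftype  Rtype  no_protein
member
F0      0.201 -0.456      -0.019
F0AC    0.026 -0.461      -0.018
F1     -0.074  0.528       0.008
...
F164   -0.602 -0.401       0.018
Scr     0.354 -0.301       0.006
```

and the dendrogram

```
(Ftype:0.608,(Rtype:0.489,'no_protein':0.489):0.119);
```

Reading the numbers: `RN > 0` means an aptamer is retained by the target
more than the mixture average (F4 at +0.63 is strongly enriched on the
F-type target), `RN ≈ −1` means near-complete depletion, and the
no-protein control sits near 0 everywhere (|RN| < 0.03), confirming the
assay introduces no retention/amplification bias. Against the planted
truth of the simulation, the recovered footprint has a mean absolute RN
error of 0.009 at 100 000 reads. In the tree, branch length is footprint
dissimilarity: the two target conditions are far apart and easily
discriminated.

The same workflow is available from the shell:

```
aptafoot simulate assay --scenario assay.yaml --panel panel.fasta --out assays/
aptafoot footprint --manifest assays/manifest.yaml --panel assays/panel.fasta --out fp/
aptafoot tree --footprints fp/footprint_median.tsv --out tree/
```

and for SELEX rounds: `aptafoot trim`, `aptafoot cluster`,
`aptafoot motifs`, `aptafoot simulate selex`.

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical
conventions, and the limits of what the synthetic data can show.
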