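"""Synthetic-data generator: planted truth, determinism, recovery."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aptafootseq.ingest import TrimParams, build_round_library
from aptafootseq.families import select_candidates, cluster_families
from aptafootseq.motifs import Motif, motif_prevalence
from aptafootseq.footprint import assign_reads, footprint_table
from aptafootseq.simulate import (
    SeedFamily,
    SelexScenario,
    AssayScenario,
    planted_selex_scenario,
    run_selex,
    simulate_selex,
    simulate_assay,
    assay_reads,
    write_assay_fastq,
    replicator_step,
    truth_rn,
    random_panel,
    DEFAULT_PRIMER5,
    DEFAULT_PRIMER3,
)

from conftest import random_dna


class TestReplicator:
    def test_single_enriched_founder_recurrence(self):
        # f=0.01 at w=2 against neutral background: 0.02/1.01
        out = replicator_step(np.array([0.01, 0.99]), np.array([2.0, 1.0]))
        assert out[0] == pytest.approx(0.02 / 1.01)
        assert out[0] == pytest.approx(0.019802, abs=1e-6)

    def test_degenerate_all_zero_fitness(self):
        with pytest.raises(ValueError, match="degenerate"):
            replicator_step(np.array([0.5, 0.5]), np.array([0.0, 0.0]))


class TestSelexSimulation:
    def test_depth_exact_per_round(self):
        sc = planted_selex_scenario(n_families=5, seed=2, n_rounds=3, reads_per_round=5000)
        res = run_selex(sc)
        assert all(sum(c.values()) == 5000 for c in res.round_counts)

    def test_neutral_evolution_matches_multinomial(self):
        # equal fitness, no mutation: founder counts in round 1 are a plain
        # multinomial draw from the initial composition
        rng = np.random.default_rng(99)
        founders = [random_dna(rng, 35) for _ in range(5)]
        pvals = []
        for seed in range(20):
            fams = [
                SeedFamily(name=f"P{i}", founder=s, fitness=1.0, initial_fraction=0.05)
                for i, s in enumerate(founders)
            ]
            sc = SelexScenario(
                seed_families=fams,
                n_rounds=1,
                reads_per_round=20_000,
                mutation_rate=0.0,
                error_rate=0.0,
                rng_seed=seed,
            )
            res = run_selex(sc)
            counts = res.round_counts[0]
            observed = [counts.get(s, 0) for s in founders]
            observed.append(20_000 - sum(observed))  # background
            expected = [0.05 * 20_000] * 5 + [0.75 * 20_000]
            pvals.append(stats.chisquare(observed, expected).pvalue)
        # p-values are uniform under the null; more than 2 of 20 below
        # 0.01 would be wildly unlikely (p ~ 1e-3)
        assert sum(p <= 0.01 for p in pvals) <= 2

    def test_truth_fractions_match_round_counts(self):
        sc = planted_selex_scenario(n_families=4, seed=3, n_rounds=4, reads_per_round=10_000)
        res = run_selex(sc)
        for t, counts in enumerate(res.round_counts):
            by_family: dict[str, int] = {}
            for seq, c in counts.items():
                fam = res.membership.get(seq)
                if fam:
                    by_family[fam] = by_family.get(fam, 0) + c
            for fam in res.truth.index:
                assert res.truth.loc[fam].iloc[t] == pytest.approx(
                    by_family.get(fam, 0) / 10_000
                )

    def test_same_seed_byte_identical_fastq(self, tmp_path):
        sc = planted_selex_scenario(n_families=3, seed=5, n_rounds=2, reads_per_round=500)
        simulate_selex(sc, tmp_path / "a")
        simulate_selex(sc, tmp_path / "b")
        for p in sorted((tmp_path / "a").glob("*.fastq.gz")):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_fastq_reingestion_recovers_counts_without_error(self, tmp_path):
        sc = planted_selex_scenario(
            n_families=3, seed=7, n_rounds=2, reads_per_round=2000, error_rate=0.0
        )
        res = simulate_selex(sc, tmp_path)
        params = TrimParams(DEFAULT_PRIMER5, DEFAULT_PRIMER3)
        for t in (1, 2):
            lib = build_round_library(tmp_path / f"round_{t:02d}.fastq.gz", params)
            assert lib.counts == res.round_counts[t - 1]

    def test_planted_motif_families_recovered(self, rng):
        motif = Motif("planted", "ACGCGTTTAC")
        carriers = [
            random_dna(rng, 12) + motif.pattern + random_dna(rng, 13) for _ in range(3)
        ]
        others = [random_dna(rng, 35) for _ in range(7)]
        fams = [
            SeedFamily(name=f"P{i}", founder=s, fitness=2.0, initial_fraction=0.05)
            for i, s in enumerate(carriers + others)
        ]
        sc = SelexScenario(
            seed_families=fams, n_rounds=3, reads_per_round=20_000, rng_seed=17
        )
        res = run_selex(sc)
        libs = res.round_libraries()
        cands = select_candidates(libs, threshold=1e-3)
        clusters = cluster_families(cands, max_dist=7)
        out = motif_prevalence(motif, clusters, libs)
        assert out["n_families"].iloc[0] == 3
        containing_truth = {
            res.membership[f.representative]
            for f in clusters
            if f.representative in res.membership
            and any(c in f.members for c in carriers)
        }
        assert containing_truth == {"P0", "P1", "P2"}


class TestAssaySimulation:
    def test_truth_rn_no_selection_control(self):
        f0 = np.full(15, 1 / 15)
        assert np.allclose(truth_rn(f0, f0), 0.0)

    def test_truth_rn_uniform_start_closed_form(self):
        # with equimolar f0, RN reduces to n*q - 1
        f0 = np.full(3, 1 / 3)
        q = np.array([0.5, 0.3, 0.2])
        assert np.allclose(truth_rn(f0, q), [0.5, -0.1, -0.4])

    def test_zero_in_f0_rejected(self):
        panel = random_panel(n=3, seed=1, names=("A", "B", "Scr"))
        with pytest.raises(ValueError, match="every panel member"):
            AssayScenario(
                panel=panel, q={"x": [0.5, 0.3, 0.2]}, f0=[0.0, 0.5, 0.5]
            )

    def test_zero_in_q_allowed_and_depletes(self):
        panel = random_panel(n=3, seed=1, names=("A", "B", "Scr"))
        sc = AssayScenario(panel=panel, q={"x": [0.0, 0.5, 0.5]}, rng_seed=3)
        res = simulate_assay(sc)
        assert res.truth.loc["A", "x"] == pytest.approx(-1.0)

    def test_requested_depth_and_replicates(self):
        panel = random_panel(n=15, seed=2)
        sc = AssayScenario(
            panel=panel,
            q={"F": np.full(15, 1 / 15)},
            reads_per_assay=4000,
            replicates=3,
            rng_seed=4,
        )
        res = simulate_assay(sc)
        assert len(res.assays) == 6  # condition 0 + F, 3 replicates each
        assert all(a.total_assigned == 4000 for a in res.assays)

    def test_fastq_path_recovers_truth(self, tmp_path, rng):
        panel = random_panel(n=15, seed=6)
        q = rng.dirichlet(np.full(15, 5.0))
        sc = AssayScenario(
            panel=panel, q={"F": q}, reads_per_assay=20_000, rng_seed=8
        )
        res = simulate_assay(sc)
        out = write_assay_fastq(res, tmp_path)
        assays = []
        from aptafootseq.ingest import iter_fastq

        import yaml

        manifest = yaml.safe_load((out / "manifest.yaml").read_text())
        for entry in manifest["assays"]:
            reads = (s for s, _ in iter_fastq(out / entry["fastq"]))
            assays.append(
                assign_reads(reads, panel, 3, str(entry["condition"]), entry["replicate"])
            )
        table = footprint_table(assays, panel)
        mae = np.abs(table.median["F"].to_numpy() - res.truth["F"].to_numpy()).mean()
        assert mae < 0.1

    def test_two_distinct_conditions_separate_in_tree(self, rng):
        from aptafootseq.clustering import pearson_distance, hierarchical_cluster

        panel = random_panel(n=15, seed=9)
        qf = rng.dirichlet(np.full(15, 2.0))
        qr = rng.dirichlet(np.full(15, 2.0))
        sc = AssayScenario(
            panel=panel,
            q={"F1": qf, "F2": qf, "R1": qr, "R2": qr},
            reads_per_assay=50_000,
            rng_seed=10,
        )
        res = simulate_assay(sc)
        table = footprint_table(res.assays, panel)
        tree = hierarchical_cluster(pearson_distance(table.median))
        cut = tree.cut(2)
        assert cut["F1"] == cut["F2"] != cut["R1"] == cut["R2"]
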