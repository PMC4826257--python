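"""Synthetic-study generator: determinism, degenerate configs, planted effects."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pytest

from consurvey.genesets import GeneSet, derive_nontargets
from consurvey.orthology import ONE2ONE, evolutionary_rates
from consurvey.stats import rank_sum_test
from consurvey.synthgen import (
    SimConfig,
    _streams,
    simulate_families,
    simulate_network,
    simulate_orthology,
    simulate_sequences,
    simulate_study,
)


def dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestConfig:
    def test_probability_bounds_validated(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(ortholog_prob_target=1.2)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="seq_len_range"):
            SimConfig(seq_len_range=(5, 50))

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SimConfig(species=("amel", "amel"), sequence_species=("amel",))

    def test_unknown_sequence_species_rejected(self):
        with pytest.raises(ValueError, match="sequence_species"):
            SimConfig(species=("amel",), sequence_species=("mmus",))

    def test_manifest_round_trip(self, tiny_config, tiny_study_dir):
        manifest = json.loads((tiny_study_dir / "manifest.json").read_text())
        assert SimConfig.from_dict(manifest) == tiny_config


class TestSimulateOrthology:
    def test_seeded_determinism(self, tiny_config):
        t1 = simulate_orthology(tiny_config, _streams(tiny_config)["orthology"])
        t2 = simulate_orthology(tiny_config, _streams(tiny_config)["orthology"])
        assert t1.df.equals(t2.df)

    def test_zero_presence_probability(self):
        cfg = SimConfig(
            n_targets=50, n_nontargets=10, species=("amel",),
            sequence_species=(), ortholog_prob_target=0.0, seed=1,
        )
        table = simulate_orthology(cfg, _streams(cfg)["orthology"])
        target_one2one = table.df[
            table.df["human_gene"].str.startswith("T")
            & (table.df["homology_type"] == ONE2ONE)
        ]
        assert len(target_one2one) == 0

    def test_planted_group_medians_separate(self):
        # log-normal medians e^mu: 0.10 vs 0.13
        cfg = SimConfig(seed=2024, sequence_species=())
        table = simulate_orthology(cfg, _streams(cfg)["orthology"])
        targets = GeneSet("t", frozenset(cfg.target_ids()))
        nontargets = GeneSet("n", frozenset(cfg.nontarget_ids()))
        n_lower = 0
        for sp in cfg.species:
            m1 = np.median([r.omega for r in evolutionary_rates(table, targets, sp)])
            m2 = np.median([r.omega for r in evolutionary_rates(table, nontargets, sp)])
            n_lower += m1 < m2
        assert n_lower >= 19

    def test_recovered_omega_median_near_planted(self):
        cfg = SimConfig(
            n_targets=1000, n_nontargets=1000, species=("amel",),
            sequence_species=(), seed=5,
        )
        table = simulate_orthology(cfg, _streams(cfg)["orthology"])
        med = np.median(
            [r.omega for r in evolutionary_rates(
                table, GeneSet("t", frozenset(cfg.target_ids())), "amel")]
        )
        assert med == pytest.approx(0.10, rel=0.05)

    def test_ortholog_percentage_recovers_presence_probability(self):
        from consurvey.orthology import ortholog_percentage

        cfg = SimConfig(
            n_targets=400, n_nontargets=10, species=("amel",),
            sequence_species=(), seed=12,
        )
        table = simulate_orthology(cfg, _streams(cfg)["orthology"])
        pct = ortholog_percentage(
            table, GeneSet("t", frozenset(cfg.target_ids())), "amel"
        )
        sd = 100 * math.sqrt(0.9 * 0.1 / 400)
        assert abs(pct - 90.0) <= 3 * sd

    def test_missing_values_injected(self, tiny_study):
        df = tiny_study.ortholog_table.df
        assert df["dn"].isna().any() or df["ds"].isna().any()


class TestSimulateSequences:
    def test_zero_divergence_identity(self):
        cfg = SimConfig(
            n_targets=10, n_nontargets=10, species=("amel",),
            sequence_species=("amel",), divergence_scale=0.0, seed=3,
        )
        study = simulate_study(cfg)
        for h, o in study.sequence_pairs["amel"].values():
            assert h == o

    def test_divergence_cap_honored(self):
        # huge omega: substitution probability capped at 0.95
        cfg = SimConfig(
            n_targets=40, n_nontargets=10, species=("amel",),
            sequence_species=("amel",), divergence_scale=1e6,
            seq_len_range=(500, 500), seed=4,
        )
        study = simulate_study(cfg)
        fracs = [
            sum(a != b for a, b in zip(h, o)) / len(h)
            for h, o in study.sequence_pairs["amel"].values()
        ]
        # 3 binomial sd around 0.95 at length 500
        sd = math.sqrt(0.95 * 0.05 / 500)
        assert all(abs(f - 0.95) < 3.5 * sd for f in fracs)
        assert abs(np.mean(fracs) - 0.95) < 3 * sd / math.sqrt(len(fracs))

    def test_differing_fraction_tracks_omega(self):
        cfg = SimConfig(
            n_targets=60, n_nontargets=10, species=("amel",),
            sequence_species=("amel",), seq_len_range=(500, 500), seed=6,
        )
        study = simulate_study(cfg)
        table = study.ortholog_table.df
        rows = table[(table["homology_type"] == ONE2ONE) & table["dn"].notna() & table["ds"].notna()]
        omega = {g: dn / ds for g, dn, ds in zip(rows["human_gene"], rows["dn"], rows["ds"])}
        for gene, (h, o) in study.sequence_pairs["amel"].items():
            p = min(0.95, cfg.divergence_scale * omega[gene])
            frac = sum(a != b for a, b in zip(h, o)) / len(h)
            assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / len(h)) + 1e-9

    def test_pairs_only_for_one2one_rows(self, tiny_study):
        sp = tiny_study.config.sequence_species[0]
        one2one_genes = set(tiny_study.ortholog_table.one2one(sp)["human_gene"])
        assert set(tiny_study.sequence_pairs[sp]) <= one2one_genes


class TestSimulateNetwork:
    def test_simple_graph_guarantees(self, tiny_study):
        g = tiny_study.network
        for u, v in g.edges():
            assert u != v
        assert len(g.edges()) == len(set(g.edges()))

    def test_equal_weights_null_degrees(self):
        cfg = SimConfig(
            n_targets=500, n_nontargets=500, species=("amel",),
            sequence_species=(), degree_weight_target=1.0,
            degree_weight_nontarget=1.0, triad_closure_prob=0.0, seed=7,
        )
        net = simulate_network(cfg, _streams(cfg)["network"])
        d1 = [len(net.neighbors(v)) for v in cfg.target_ids()]
        d2 = [len(net.neighbors(v)) for v in cfg.nontarget_ids()]
        diff = np.mean(d1) - np.mean(d2)
        sd = math.sqrt(np.var(d1) / len(d1) + np.var(d2) / len(d2))
        assert abs(diff) < 3 * sd

    def test_planted_degree_effect(self):
        cfg = SimConfig(
            n_targets=500, n_nontargets=500, species=("amel",),
            sequence_species=(), seed=8,
        )
        net = simulate_network(cfg, _streams(cfg)["network"])
        d1 = [float(len(net.neighbors(v))) for v in cfg.target_ids()]
        d2 = [float(len(net.neighbors(v))) for v in cfg.nontarget_ids()]
        assert np.mean(d1) > np.mean(d2)
        assert rank_sum_test(d1, d2, method="normal_approx").p_two_sided < 0.01


class TestSimulateFamilies:
    def test_zero_overlap_recovers_nontargets_exactly(self):
        cfg = SimConfig(
            n_targets=40, n_nontargets=80, species=("amel",),
            sequence_species=(), family_overlap=0.0, seed=9,
        )
        fams = simulate_families(cfg, _streams(cfg)["families"])
        targets = GeneSet("t", frozenset(cfg.target_ids()))
        recovered = derive_nontargets(targets, fams)
        assert recovered.genes == frozenset(cfg.nontarget_ids())

    def test_overlap_fraction_excluded(self):
        cfg = SimConfig(
            n_targets=100, n_nontargets=900, species=("amel",),
            sequence_species=(), family_overlap=0.1, seed=10,
        )
        fams = simulate_families(cfg, _streams(cfg)["families"])
        targets = GeneSet("t", frozenset(cfg.target_ids()))
        recovered = derive_nontargets(targets, fams)
        n_excluded = 900 - len(recovered)
        sd = math.sqrt(900 * 0.1 * 0.9)
        assert abs(n_excluded - 90) <= 3 * sd

    def test_every_gene_has_a_family(self, tiny_study):
        all_genes = tiny_study.target_genes.genes | tiny_study.nontarget_genes.genes
        assert set(tiny_study.family_map.assignments) == all_genes
        assert all(len(f) >= 1 for f in tiny_study.family_map.assignments.values())


class TestSimulateStudy:
    def test_identical_file_digests(self, tiny_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(tiny_config, out_dir=d1)
        simulate_study(tiny_config, out_dir=d2)
        assert dir_digest(d1) == dir_digest(d2)

    def test_row_count_bound(self):
        cfg = SimConfig(
            n_targets=10, n_nontargets=20,
            species=("amel", "btau", "cfam"), sequence_species=(), seed=11,
        )
        table = simulate_orthology(cfg, _streams(cfg)["orthology"])
        assert len(table) <= 30 * 3

    def test_gene_sets_partition_ids(self, tiny_study):
        assert not (tiny_study.target_genes.genes & tiny_study.nontarget_genes.genes)

    def test_study_files_written(self, tiny_study_dir, tiny_config):
        names = {p.name for p in tiny_study_dir.iterdir()}
        expected = {
            "targets.txt", "nontargets.txt", "orthologs.tsv", "ppi.tsv",
            "families.tsv", "manifest.json",
        } | {
            f"seqs_{sp}_{side}.fasta"
            for sp in tiny_config.sequence_species
            for side in ("human", "ortholog")
        }
        assert expected <= names
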