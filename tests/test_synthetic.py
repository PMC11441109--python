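import numpy as np
import pytest
from scipy import stats

from xksilence import ConfigurationError, SimulationConfig, simulate_experiment
from xksilence.config import condition_species
from xksilence.synthetic import (
    _nb_draw,
    generate_references,
    plant_mirnas_and_targets,
    simulate_count_matrices,
    simulate_srna_fastq,
)
from xksilence.seq import reverse_complement


def _stage12(config):
    rng = np.random.default_rng(config.seed)
    plant, fungus, manifest = generate_references(config, rng)
    manifest = plant_mirnas_and_targets(plant, fungus, manifest, config, rng)
    return plant, fungus, manifest


class TestReferences:
    def test_sizes_and_homolog_count(self):
        cfg = SimulationConfig(
            seed=1, n_transcripts_plant=10, n_transcripts_fungus=5, frac_homologous=0.2
        )
        plant, fungus, manifest = generate_references(cfg)
        assert len(plant) == 10 and len(fungus) == 5
        assert len(manifest.homologous) == 1
        pid, fid = manifest.homologous[0]
        assert plant[pid] == fungus[fid]

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=3, n_transcripts_plant=6, n_transcripts_fungus=6)
        assert generate_references(cfg)[:2] == generate_references(cfg)[:2]

    def test_no_homologs_means_disjoint_sequence_sets(self):
        cfg = SimulationConfig(seed=2, frac_homologous=0.0)
        plant, fungus, _ = generate_references(cfg)
        assert not set(plant.values()) & set(fungus.values())

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(transcript_len_range=(1500, 300))


class TestPlantedPairs:
    def test_crosskingdom_site_is_reverse_complement_substring(self):
        cfg = SimulationConfig(
            seed=5, n_crosskingdom_pairs=1, n_endogenous_pairs=0,
            n_transcripts_plant=5, n_transcripts_fungus=5,
        )
        plant, fungus, manifest = _stage12(cfg)
        (pair,) = manifest.pairs
        assert pair["relationship"] == "cross_kingdom"
        mature = manifest.mirnas[pair["mirna_id"]]["seq"]
        transcript = fungus[pair["transcript_id"]]
        assert reverse_complement(mature) in transcript
        start, end = pair["site_start"], pair["site_end"]
        assert transcript[start:end] == reverse_complement(mature)

    def test_endogenous_pairs_stay_within_species(self, tiny_config):
        _, _, manifest = _stage12(tiny_config)
        for pair in manifest.pairs:
            m_species = manifest.mirnas[pair["mirna_id"]]["species"]
            if pair["relationship"] == "endogenous":
                assert m_species == pair["species_of_transcript"]
            else:
                assert m_species != pair["species_of_transcript"]

    def test_fixed_mirna_length(self):
        cfg = SimulationConfig(seed=1, mirna_len_range=(21, 21))
        _, _, manifest = _stage12(cfg)
        assert {len(i["seq"]) for i in manifest.mirnas.values()} == {21}

    def test_zero_pairs_gives_empty_pair_list(self):
        cfg = SimulationConfig(seed=1, n_endogenous_pairs=0, n_crosskingdom_pairs=0)
        _, _, manifest = _stage12(cfg)
        assert manifest.pairs == []

    def test_too_many_pairs_rejected(self):
        cfg = SimulationConfig(
            seed=1, n_transcripts_fungus=3, n_crosskingdom_pairs=10,
        )
        with pytest.raises(ConfigurationError):
            _stage12(cfg)


class TestCountMatrices:
    def test_small_dispersion_limit_is_poisson(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(10_000, 100.0), 1e-4)
        ratio = draws.var() / draws.mean()
        assert 0.95 < ratio < 1.05

    def test_null_repression_makes_targets_background_like(self):
        cfg = SimulationConfig(seed=11, repression_log2fc=0.0)
        plant, fungus, manifest = _stage12(cfg)
        counts, _ = simulate_count_matrices(manifest, cfg, np.random.default_rng(1))
        pair = manifest.pairs[0]
        tid, species = pair["transcript_id"], pair["species_of_transcript"]
        row = counts[species].loc[tid]
        present = [
            s for s, c in manifest.samples if species in condition_species(c)
        ]
        interaction = [s for s in present if "interaction" in s]
        control = [s for s in present if s not in interaction]
        # no planted effect: interaction and control means agree within noise
        lfc = np.log2((row[interaction].mean() + 0.5) / (row[control].mean() + 0.5))
        assert abs(lfc) < 1.0

    def test_planted_pair_anticorrelates_in_most_seeds(self):
        hits = 0
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed,
                conditions=("control_fungus", "interaction_wt"),
                n_crosskingdom_pairs=0,
                n_endogenous_pairs=2,
                n_transcripts_plant=5,
                n_transcripts_fungus=20,
                reads_per_sample=0,
            )
            exp = simulate_experiment(cfg, with_reads=False)
            pair = next(
                p for p in exp.manifest.pairs if p["species_of_transcript"] == "fungus"
            )
            samples = [s for s, _ in exp.manifest.samples]
            rho = stats.spearmanr(
                exp.mirna_counts.loc[pair["mirna_id"], samples],
                exp.counts["fungus"].loc[pair["transcript_id"], samples],
            ).statistic
            hits += rho <= -0.7
        assert hits >= 90

    def test_bad_dispersion_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(nb_dispersion=0.0)


class TestReadPools:
    def test_structural_fraction_within_binomial_interval(self):
        cfg = SimulationConfig(
            seed=13, frac_structural=0.1, reads_per_sample=1000,
            n_transcripts_plant=10, n_transcripts_fungus=10,
            n_crosskingdom_pairs=2, n_endogenous_pairs=2,
        )
        plant, fungus, manifest = _stage12(cfg)
        pools = simulate_srna_fastq(manifest, plant, fungus, cfg, np.random.default_rng(2))
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        structural = set()
        for ref in manifest.structural:
            structural.update(
                ref[i : i + n] for n in range(18, 33) for i in range(len(ref) - n + 1)
            )
        for reads in pools.values():
            n_struct = sum(1 for r in reads if r.sequence in structural)
            assert lo <= n_struct <= hi

    def test_error_free_mirna_reads_are_exact_copies(self):
        cfg = SimulationConfig(
            seed=3, seq_error_rate=0.0, frac_structural=0.0, frac_mirna=1.0,
            n_transcripts_plant=5, n_transcripts_fungus=5, reads_per_sample=200,
            n_crosskingdom_pairs=1, n_endogenous_pairs=1,
        )
        plant, fungus, manifest = _stage12(cfg)
        pools = simulate_srna_fastq(manifest, plant, fungus, cfg, np.random.default_rng(3))
        matures = {i["seq"] for i in manifest.mirnas.values()}
        lengths = {len(s) for s in matures}
        for reads in pools.values():
            assert {r.sequence for r in reads} <= matures
            assert {len(r) for r in reads} <= lengths

    def test_per_sample_read_counts_conserved(self, tiny_config):
        exp = simulate_experiment(tiny_config)
        for sample, reads in exp.reads.items():
            assert sum(r.multiplicity for r in reads) == tiny_config.reads_per_sample

    def test_zero_reads_warns_and_returns_empty(self, tiny_config):
        cfg = SimulationConfig.from_dict(
            {**tiny_config.to_dict(), "reads_per_sample": 0}
        )
        plant, fungus, manifest = _stage12(cfg)
        with pytest.warns(UserWarning):
            pools = simulate_srna_fastq(manifest, plant, fungus, cfg)
        assert all(v == [] for v in pools.values())


def test_full_simulation_is_deterministic(tiny_config):
    a = simulate_experiment(tiny_config)
    b = simulate_experiment(tiny_config)
    assert a.refs_plant == b.refs_plant
    assert a.counts["fungus"].equals(b.counts["fungus"])
    assert a.mirna_counts.equals(b.mirna_counts)
    assert {s: [r.sequence for r in v] for s, v in a.reads.items()} == {
        s: [r.sequence for r in v] for s, v in b.reads.items()
    }
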