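import numpy as np
import pytest

from supersage.simulate import (
    ConfigurationError,
    SimulationConfig,
    build_truth,
    generate_count_matrix,
    generate_ditag_reads,
    generate_reference,
)


class TestConfigValidation:
    def test_zero_transcripts_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_transcripts=0).validate()

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(duplicate_ditag_rate=1.5).validate()

    def test_small_de_fold_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(de_fold_range=(1.2, 3.0)).validate()

    def test_too_few_depths_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(library_depths=(1000,)).validate()


class TestDeterminism:
    def test_same_seed_same_matrix(self, small_config):
        m1, _ = generate_count_matrix(small_config)
        m2, _ = generate_count_matrix(small_config)
        assert m1 == m2

    def test_same_seed_same_reference_bytes(self, small_config, tmp_path):
        r1, _ = generate_reference(small_config)
        r2, _ = generate_reference(small_config)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        r1.write_fasta("ncbi_cdna", p1)
        r2.write_fasta("ncbi_cdna", p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, small_config, small_matrix):
        other = SimulationConfig(**{**small_config.to_dict(), "seed": 8})
        m2, _ = generate_count_matrix(other)
        assert not (small_matrix == m2)


class TestTruthTable:
    def test_every_matrix_tag_in_truth_once(self, small_matrix, small_truth):
        truth_tags = small_truth.frame["tag"]
        assert truth_tags.is_unique
        assert set(small_matrix.tags) <= set(truth_tags)

    def test_no_tag_has_two_classes_and_folds_recorded(self, small_truth):
        tf = small_truth.frame
        de = tf[tf.de_class > 0]
        assert de["de_class"].isin([1, 2, 3, 4]).all()
        assert (de["fold"] >= 2).all()
        assert de["direction"].isin(["up", "down"]).all()

    def test_class_mix_within_sampling_error(self):
        cfg = SimulationConfig(
            n_transcripts=20000, library_depths=(5000,) * 5,
            de_fraction=0.05, seed=11,
        )
        tf = build_truth(cfg).frame
        de = tf[tf.de_class > 0]
        n = len(de)
        for cls, expected in zip((1, 2, 3, 4), cfg.de_class_mix):
            frac = (de["de_class"] == cls).mean()
            sd = np.sqrt(expected * (1 - expected) / n)
            assert abs(frac - expected) < 4 * sd

    def test_unmappable_fraction_matches_binomial(self):
        cfg = SimulationConfig(
            n_transcripts=1000, library_depths=(2000,) * 5,
            unmappable_fraction=0.35, seed=3,
        )
        tf = build_truth(cfg).frame
        frac = tf["unmappable"].mean()
        assert abs(frac - 0.35) < 4 * np.sqrt(0.35 * 0.65 / 1000)


class TestCountMatrix:
    def test_column_sums_equal_depths(self, small_config, small_matrix):
        assert (
            small_matrix.totals.to_numpy()
            == np.array(small_config.library_depths)
        ).all()

    def test_null_config_keeps_frequencies_equal(self):
        cfg = SimulationConfig(n_transcripts=500, library_depths=(1000,) * 5,
                               de_fraction=0.0, seed=2)
        truth = build_truth(cfg)
        F = truth.frame[[f"freq_{l}" for l in cfg.library_names]].to_numpy()
        assert np.allclose(F, F[:, [0]])

    def test_planted_fold_separates_expected_frequencies(self):
        cfg = SimulationConfig(n_transcripts=2000, library_depths=(70000,) * 5,
                               de_fraction=0.02, de_fold_range=(10, 10), seed=4)
        tf = build_truth(cfg).frame
        c1 = tf[(tf.de_class == 1) & (tf.direction == "up")]
        ratio = (c1["freq_LowCa2h"] / c1["freq_C2h"]).to_numpy()
        # per-library renormalisation compresses the planted fold slightly
        # (composition effect of the added DE mass); the ratio is uniform
        # across planted tags and close to the nominal fold
        assert np.allclose(ratio, ratio[0], rtol=1e-9)
        assert 9.0 <= ratio[0] <= 10.0


class TestReference:
    def test_sense_truth_tags_present_in_some_dataset(self, small_reference, small_truth):
        tf = small_truth.frame
        mappable = tf[~tf.unmappable]
        pool = {}
        for name in ("ncbi_cdna", "ensembl_cdna", "genome"):
            pool.update(small_reference.dataset(name))
        joined = "\n".join(pool.values())
        for _, row in mappable.head(40).iterrows():
            probe = "CATG" + row["tag"]
            if row["antisense"]:
                from supersage._util import revcomp
                probe = revcomp(probe)
            assert probe in joined

    def test_unmappable_tags_absent_everywhere(self, small_reference, small_truth):
        from supersage._util import revcomp
        tf = small_truth.frame
        pool = {}
        for name in ("ncbi_cdna", "ensembl_cdna", "genome"):
            pool.update(small_reference.dataset(name))
        joined = "\n".join(pool.values())
        for _, row in tf[tf.unmappable].head(40).iterrows():
            probe = "CATG" + row["tag"]
            assert probe not in joined and revcomp(probe) not in joined

    def test_genome_contains_each_cdna(self, small_reference):
        genome = "\n".join(small_reference.genome.values())
        for seq in list(small_reference.ncbi_cdna.values())[:30]:
            assert seq in genome

    def test_every_transcript_has_anchor_site(self, small_reference):
        for seq in list(small_reference.ncbi_cdna.values())[:50]:
            assert "CATG" in seq


class TestDitagReads:
    def test_duplicate_injection_rate(self, small_matrix, small_config):
        cfg = SimulationConfig(**{
            **small_config.to_dict(),
            "duplicate_ditag_rate": 0.2,
            "incomplete_linker_rate": 0.0,
            "contaminated_linker_rate": 0.0,
            "ambiguous_base_rate": 0.0,
        })
        reads = generate_ditag_reads(cfg, small_matrix)
        n_clean = sum(1 for r in reads if r.truth_qc == "pass")
        n_dup = sum(1 for r in reads if r.truth_qc == "duplicate")
        assert n_dup == pytest.approx(0.2 * n_clean, rel=0.01)
        seqs = {r.sequence for r in reads if r.truth_qc == "pass"}
        for r in reads:
            if r.truth_qc == "duplicate":
                assert r.sequence in seqs

    def test_ambiguous_bases_confined_to_flagged_reads(self, small_matrix, small_config):
        reads = generate_ditag_reads(small_config, small_matrix)
        for r in reads:
            if "N" in r.sequence:
                assert r.truth_qc == "ambiguous_base"

    def test_each_clean_ditag_contributes_two_tags(self, small_matrix, small_config):
        cfg = SimulationConfig(**{
            **small_config.to_dict(),
            "duplicate_ditag_rate": 0.0, "incomplete_linker_rate": 0.0,
            "contaminated_linker_rate": 0.0, "ambiguous_base_rate": 0.0,
        })
        reads = generate_ditag_reads(cfg, small_matrix)
        lk = len(cfg.linker_sequences["C2h"])
        total_tags = 0
        for r in reads:
            interior = len(r.sequence) - 2 * lk
            assert interior in (26, 52)
            total_tags += interior // 26
        assert total_tags == int(small_matrix.totals.sum())

    def test_unknown_library_errors(self, small_config):
        import pandas as pd
        from supersage.matrix import TagCountMatrix
        m = TagCountMatrix(pd.DataFrame({"mystery": [1]}, index=["A" * 22]))
        with pytest.raises(ConfigurationError):
            generate_ditag_reads(small_config, m)


class TestAbundanceRealism:
    def test_singleton_regime_at_paper_depth(self):
        # one paper-scale library; the 20-seed mean band is exercised in the
        # acceptance suite, here a single seed must land in the wide band
        cfg = SimulationConfig(library_depths=(68875,) * 1,
                               library_names=("C2h",), de_fraction=0.0, seed=5,
                               linker_sequences={"C2h": "ACCTGAGGAT"})
        m, _ = generate_count_matrix(cfg)
        col = m.counts["C2h"]
        frac = (col == 1).sum() / (col >= 1).sum()
        assert 0.60 <= frac <= 0.78
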