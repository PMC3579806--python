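"""Generator contracts: determinism, validation, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from mirfsh import profiles, qpcr, simulate, targets
from mirfsh import io as mio


class TestConfigValidation:
    def test_non_positive_planted_ratio_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            simulate.SimulationConfig(planted_fold_changes={"x": 0.0})

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(noise_sd=-0.1)

    def test_negative_hormone_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(hormone_group_means={"a": (10.0, -1.0)})

    def test_unknown_yaml_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            simulate.config_from_dict({"not_a_field": 1})


class TestArrayGenerator:
    def test_zero_probes_gives_empty_table(self):
        cfg = simulate.SimulationConfig(planted_fold_changes={}, n_null_probes=0)
        df = simulate.generate_array_dataset(cfg)
        assert df.empty and list(df.columns) == mio.PROBE_COLUMNS

    def test_same_seed_identical_tables(self, sim_config):
        a = simulate.generate_array_dataset(sim_config)
        b = simulate.generate_array_dataset(simulate.SimulationConfig(seed=1))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, sim_config):
        b = simulate.generate_array_dataset(simulate.SimulationConfig(seed=2))
        a = simulate.generate_array_dataset(sim_config)
        assert not a["Hy3"].equals(b["Hy3"])

    def test_planted_ratio_exact_after_bias_removal_noise0(self, sim_config):
        """With zero noise, log-ratio minus the planted bias curve equals the
        planted log fold change exactly."""
        df = simulate.generate_array_dataset(sim_config)
        planted = df[df["miRNA"].isin(profiles.PLANTED_FOLD_CHANGES)]
        a = 0.5 * (np.log2(planted["Hy3"]) + np.log2(planted["Hy5"]))
        m = np.log2(planted["Hy3"] / planted["Hy5"])
        bias = np.polynomial.polynomial.polyval(
            a.to_numpy(), np.asarray(sim_config.dye_bias_coefficients)
        )
        expected = np.log2([profiles.PLANTED_FOLD_CHANGES[n] for n in planted["miRNA"]])
        np.testing.assert_allclose(m - bias, expected, atol=1e-9)

    def test_null_probe_mean_follows_bias_curve(self):
        cfg = simulate.SimulationConfig(
            seed=7, noise_sd=0.2, n_null_probes=4000, planted_fold_changes={},
            snr_fail_fraction=0.0,
        )
        df = simulate.generate_array_dataset(cfg)
        a = 0.5 * (np.log2(df["Hy3"]) + np.log2(df["Hy5"]))
        m = np.log2(df["Hy3"] / df["Hy5"])
        bias = np.polynomial.polynomial.polyval(
            a.to_numpy(), np.asarray(cfg.dye_bias_coefficients)
        )
        resid = (m - bias).to_numpy()
        se = cfg.noise_sd / np.sqrt(len(df))
        assert abs(resid.mean()) < 3 * se

    def test_configurable_fraction_fails_snr_gate(self):
        cfg = simulate.SimulationConfig(seed=3, snr_fail_fraction=0.2, n_null_probes=500)
        df = simulate.generate_array_dataset(cfg)
        fails = (
            (df["Hy3"] <= 0)
            | (df["Hy5"] <= 0)
            | (
                ~((df["SNR_Hy3"] > 1) & (df["SNR_Hy5"] > 1))
                & ~((df["SNR_Hy3"] > 2) | (df["SNR_Hy5"] > 2))
            )
        )
        assert fails.sum() == round(0.2 * 500)
        # planted probes always pass
        assert not fails[df["miRNA"].isin(profiles.PLANTED_FOLD_CHANGES)].any()


class TestQpcrGenerator:
    def test_missing_reference_errors(self):
        cfg = simulate.SimulationConfig(ct_effects={"geneA": -1.0})
        with pytest.raises(ValueError, match="reference"):
            simulate.generate_qpcr_dataset(cfg)

    def test_nonzero_reference_effect_errors(self):
        cfg = simulate.SimulationConfig(
            ct_effects={"geneA": -1.0, "U6": 0.5, "ACTB": 0.0}
        )
        with pytest.raises(ValueError, match="zero planted effect"):
            simulate.generate_qpcr_dataset(cfg)

    def test_planted_ddct_minus1_gives_rq2_noise0(self):
        cfg = simulate.SimulationConfig(
            ct_effects={"geneA": -1.0, "U6": 0.0, "ACTB": 0.0}, ct_noise_sd=0.0
        )
        ct = simulate.generate_qpcr_dataset(cfg)
        rq = qpcr.delta_delta_ct(ct[ct["gene"].isin(["geneA", "U6"])], "U6")
        assert rq.loc[rq["gene"] == "geneA", "rq"].item() == pytest.approx(2.0)

    def test_planted_ddct_zero_gives_rq1(self):
        cfg = simulate.SimulationConfig(
            ct_effects={"geneA": 0.0, "U6": 0.0, "ACTB": 0.0}, ct_noise_sd=0.0
        )
        ct = simulate.generate_qpcr_dataset(cfg)
        rq = qpcr.delta_delta_ct(ct[ct["gene"].isin(["geneA", "U6"])], "U6")
        assert rq.loc[rq["gene"] == "geneA", "rq"].item() == pytest.approx(1.0)

    def test_reference_ct_constant_across_groups_noise0(self):
        cfg = simulate.SimulationConfig(ct_noise_sd=0.0)
        ct = simulate.generate_qpcr_dataset(cfg)
        u6 = ct[ct["gene"] == "U6"]
        assert u6["ct"].nunique() == 1

    def test_monte_carlo_mean_rq_near_planted(self):
        """Over many noisy replicates the mean log2 RQ stays within 3 SE of
        the planted effect."""
        planted = -0.8
        log2_rqs = []
        for seed in range(300):
            cfg = simulate.SimulationConfig(
                seed=seed, ct_effects={"g": planted, "U6": 0.0, "ACTB": 0.0},
                ct_noise_sd=0.3,
            )
            ct = simulate.generate_qpcr_dataset(cfg)
            rq = qpcr.delta_delta_ct(ct[ct["gene"].isin(["g", "U6"])], "U6")
            log2_rqs.append(np.log2(rq["rq"].item()))
        log2_rqs = np.asarray(log2_rqs)
        se = log2_rqs.std(ddof=1) / np.sqrt(len(log2_rqs))
        assert abs(log2_rqs.mean() - (-planted)) < 3 * se


class TestHormoneGenerator:
    def test_exact_moments_reproduce_group_means(self, sim_config):
        df = simulate.generate_hormone_dataset(sim_config)
        per_mg = df["fsh"] / df["total_protein"]
        for group, (mean, sd) in sim_config.hormone_group_means.items():
            vals = per_mg[df["group"] == group]
            assert vals.mean() == pytest.approx(mean, abs=1e-9)
            assert vals.std(ddof=1) == pytest.approx(sd, abs=1e-9)

    def test_seed_reproducible(self, sim_config):
        a = simulate.generate_hormone_dataset(sim_config)
        b = simulate.generate_hormone_dataset(simulate.SimulationConfig(seed=1))
        pd.testing.assert_frame_equal(a, b)


class TestGenomeFixture:
    def test_truth_gff_has_planted_cluster_gap(self, sim_config):
        _, _, gff = simulate.generate_genome_fixture(sim_config)
        chr7 = gff[gff["seqid"] == "chr7"].sort_values("start")
        gap = int(chr7.iloc[1]["start"] - chr7.iloc[0]["end"] - 1)
        assert gap == profiles.CLUSTER_GAP_BP

    def test_two_copy_precursor_embedded_twice(self, sim_config):
        genome, precursors, _ = simulate.generate_genome_fixture(sim_config)
        seq = precursors["ssc-let-7a"].replace("U", "T")
        assert genome["chr6"].count(seq) == 2

    def test_unmapped_precursor_absent_from_genome(self, sim_config):
        genome, precursors, _ = simulate.generate_genome_fixture(sim_config)
        absent = precursors["ssc-mir-338"].replace("U", "T")
        assert not any(absent in chrom for chrom in genome.values())


class TestUtrGenerator:
    def test_planted_seed_complement_at_declared_position(self, sim_config):
        """Seed CCCCCAG (miR-361-3p) must appear as CUGGGGG exactly at the
        declared FSHB plant position."""
        utrs, _, _, _ = simulate.generate_utr_and_genesets(sim_config)
        mirna, tx, pos = sim_config.utr_plants[0]
        assert (mirna, tx) == ("ssc-miR-361-3p", "TX_FSHB")
        assert utrs[tx][pos - 1 : pos + 6] == "CUGGGGG"

    def test_empty_plant_list_gives_background_only(self):
        cfg = simulate.SimulationConfig(seed=4, utr_plants=[], n_background_utrs=3)
        utrs, gene_map, _, _ = simulate.generate_utr_and_genesets(cfg)
        assert len(utrs) == 3
        assert all(g.startswith("BGGENE") for g in gene_map.values())

    def test_plant_position_beyond_utr_errors(self):
        cfg = simulate.SimulationConfig(
            utr_plants=[("ssc-miR-361-3p", "TX_X", 9999)], utr_length=500
        )
        with pytest.raises(ValueError, match="outside UTR"):
            simulate.generate_utr_and_genesets(cfg)

    def test_undeclared_mirna_plant_errors(self):
        cfg = simulate.SimulationConfig(utr_plants=[("not-a-mirna", "TX_X", 100)])
        with pytest.raises(ValueError, match="undeclared miRNA"):
            simulate.generate_utr_and_genesets(cfg)

    def test_decoys_sit_above_energy_margin(self, sim_config, energy_params):
        """Background seed matches are engineered to fail the -20 filter."""
        utrs, _, _, _ = simulate.generate_utr_and_genesets(sim_config)
        matures = simulate.mature_sequences(sim_config)
        planted_tx = {tx for _, tx, _ in sim_config.utr_plants}
        checked = 0
        for tx, seq in utrs.items():
            if tx in planted_tx:
                continue
            for name, mat in matures.items():
                seed = targets.extract_seed(mat)
                for hit in targets.seed_match_scan(seed, seq, max_gu=0):
                    mfe = targets.site_energy(mat, seq, hit.start, energy_params)
                    assert mfe > -20.0
                    checked += 1
        assert checked >= len(utrs) - len(planted_tx)  # at least the engineered decoys


class TestFixtureFiles:
    def test_fixture_dir_byte_identical_across_runs(self, tmp_path):
        cfg = simulate.SimulationConfig(seed=5, n_null_probes=50, n_background_utrs=2)
        p1 = simulate.write_fixture_dir(cfg, tmp_path / "a")
        p2 = simulate.write_fixture_dir(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
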