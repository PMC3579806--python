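"""Seed extraction, wobble-aware scanning, duplex MFE DP, site acceptance,
cross-species conservation."""

import numpy as np
import pytest

from mirfsh import profiles, simulate, targets

from conftest import brute_force_duplex_mfe


class TestExtractSeed:
    def test_mir361_3p_seed_positions_2_to_8(self):
        mature = "U" + "CCCCCAG" + profiles.MIR_361_3P_TAIL
        assert targets.extract_seed(mature) == "CCCCCAG"

    def test_let7_seed(self):
        assert targets.extract_seed("UGAGGUAGUAGGUUGUAUAGUU") == "GAGGUAG"

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError, match="too short"):
            targets.extract_seed("ACGUAC", (2, 8))

    def test_alternative_window_2_to_7(self):
        assert targets.extract_seed("UGAGGUAGUAGG", (2, 7)) == "GAGGUA"

    def test_dna_input_converted(self):
        assert targets.extract_seed("TGAGGTAGTAGGTTG") == "GAGGUAG"


class TestSeedMatchScan:
    def test_reverse_complement_site_found_all_wc(self):
        utr = "AAAA" + "CUGGGGG" + "AAAA"
        hits = targets.seed_match_scan("CCCCCAG", utr)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].seed_class) == (5, 11, "all-WC")

    def test_single_gu_site_classified(self):
        """UUACCUC pairs GAGGUAG with one G:U opposite the seed's 3' G."""
        hits = targets.seed_match_scan("GAGGUAG", "GG" + "UUACCUC" + "CC")
        assert len(hits) == 1
        assert hits[0].seed_class == "contains-GU"
        assert hits[0].n_gu == 1

    def test_poly_a_utr_no_hits(self):
        assert targets.seed_match_scan("CCCCCAG", "A" * 50) == []

    def test_gu_budget_enforced(self):
        # site with two G:U pairs against GAGGUAG: positions 1 and 7
        two_gu = "UUACCUU"
        assert targets.seed_match_scan("GAGGUAG", two_gu, max_gu=1) == []
        hits = targets.seed_match_scan("GAGGUAG", two_gu, max_gu=2)
        assert len(hits) == 1 and hits[0].n_gu == 2

    def test_allow_gu_false_excludes_wobble(self):
        assert targets.seed_match_scan("GAGGUAG", "UUACCUC", allow_gu=False) == []
        assert len(targets.seed_match_scan("GAGGUAG", "CUACCUC", allow_gu=False)) == 1

    def test_overlapping_hits_all_reported(self):
        utr = "CUGGGGGCUGGGGG"  # two overlapping-window candidates
        hits = targets.seed_match_scan("CCCCCAG", utr, max_gu=0)
        assert [h.start for h in hits] == [1, 8]

    def test_reversed_utr_destroys_hits(self):
        """Reversing (not complementing) the UTR removes all seed hits of a
        non-palindromic seed: orientation matters."""
        utr = "AGCAUGC" + "CUGGGGG" + "GCAUGCA"
        assert len(targets.seed_match_scan("CCCCCAG", utr, max_gu=0)) == 1
        assert targets.seed_match_scan("CCCCCAG", utr[::-1], max_gu=0) == []

    def test_n_never_pairs(self):
        assert targets.seed_match_scan("CCCCCAG", "CUGNGGG") == []

    def test_empty_seed_errors(self):
        with pytest.raises(ValueError, match="empty seed"):
            targets.seed_match_scan("", "ACGU")


class TestDuplexMfe:
    def test_single_base_pair_is_no_duplex(self, energy_params):
        assert targets.duplex_mfe("A", "U", energy_params).mfe is None

    def test_no_complementarity_is_no_duplex(self, energy_params):
        assert targets.duplex_mfe("AAAA", "AAAA", energy_params).mfe is None

    def test_gc_duplex_lower_than_au_duplex(self, energy_params):
        gc = targets.duplex_mfe(
            "GCGCGCG", targets.reverse_complement_rna("GCGCGCG"), energy_params
        ).mfe
        au = targets.duplex_mfe(
            "AUAUAUA", targets.reverse_complement_rna("AUAUAUA"), energy_params
        ).mfe
        assert gc < au < 0

    def test_dp_equals_enumeration_oracle_on_200_random_pairs(self, energy_params):
        """DP MFE equals exhaustive enumeration over all antiparallel
        non-crossing pairings for 200 random pairs of length <= 8."""
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        for _ in range(200):
            s1 = "".join(rng.choice(bases, rng.integers(1, 9)))
            s2 = "".join(rng.choice(bases, rng.integers(1, 9)))
            dp = targets.duplex_mfe(s1, s2, energy_params).mfe
            oracle = brute_force_duplex_mfe(s1, s2, energy_params)
            if oracle is None:
                assert dp is None, (s1, s2)
            else:
                assert dp == pytest.approx(oracle, abs=1e-9), (s1, s2)

    def test_trace_antiparallel_non_crossing(self, energy_params):
        res = targets.duplex_mfe(
            "GCAUGCAU", targets.reverse_complement_rna("GCAUGCAU"), energy_params
        )
        pos1 = [p for p, _, _ in res.pairing_trace]
        pos2 = [q for _, q, _ in res.pairing_trace]
        assert pos1 == sorted(pos1)
        assert pos2 == sorted(pos2, reverse=True)
        assert all(cls in {"WC", "GU"} for _, _, cls in res.pairing_trace)

    def test_appending_wc_stack_never_raises_mfe(self, energy_params):
        """Energy monotonicity: extending both strands by a stackable
        Watson-Crick pair can only lower (or keep) the optimum."""
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGU"))
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(30):
            s1 = "".join(rng.choice(bases, 6))
            s2 = targets.reverse_complement_rna(s1)
            base_mfe = targets.duplex_mfe(s1, s2, energy_params).mfe
            extra = str(rng.choice(bases))
            ext = targets.duplex_mfe(s1 + extra, comp[extra] + s2, energy_params).mfe
            assert ext <= base_mfe + 1e-9


class TestSiteEnergyAndPrediction:
    def test_planted_full_complement_site_accepted(self, sim_config, energy_params):
        utrs, gene_map, _, _ = simulate.generate_utr_and_genesets(sim_config)
        matures = simulate.mature_sequences(sim_config)
        mirna, tx, pos = sim_config.utr_plants[0]
        mfe = targets.site_energy(matures[mirna], utrs[tx], pos, energy_params)
        assert mfe < -25.0

    @pytest.mark.parametrize("mfe,accepted", [(-25.3, True), (-19.0, False),
                                              (-20.0, False), (-20.001, True)])
    def test_strict_minus20_rule(self, mfe, accepted):
        assert (mfe < targets.DEFAULT_ENERGY_THRESHOLD) == accepted

    def test_predict_accepts_plants_rejects_decoys(self, sim_config):
        """All planted strong sites pass the -20 kcal/mol filter; all
        engineered weak decoys fail it."""
        utrs, gene_map, _, _ = simulate.generate_utr_and_genesets(sim_config)
        matures = simulate.mature_sequences(sim_config)
        sites = targets.predict_targets(matures, utrs, gene_map=gene_map)
        accepted_pairs = {
            (r.mirna_name, r.transcript_id)
            for r in sites[sites["accepted"]].itertuples()
        }
        planted_pairs = {(m, tx) for m, tx, _ in sim_config.utr_plants}
        assert planted_pairs <= accepted_pairs
        decoy_tx = {tx for tx in utrs if tx.startswith("TX_BG")}
        assert not any(tx in decoy_tx for _, tx in accepted_pairs)

    def test_acceptance_monotone_in_threshold(self, sim_config):
        utrs, gene_map, _, _ = simulate.generate_utr_and_genesets(sim_config)
        matures = {
            k: v for k, v in simulate.mature_sequences(sim_config).items()
        }
        counts = []
        for threshold in (-10.0, -20.0, -30.0):
            sites = targets.predict_targets(
                matures, utrs, energy_threshold=threshold, gene_map=gene_map
            )
            counts.append(int(sites["accepted"].sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            targets.predict_targets({}, {}, energy_threshold=0.0)

    def test_best_site_lowest_mfe_smallest_start(self, energy_params):
        mature = "U" + "CCCCCAG" + "GUGUGAUUCUGAUU"
        site = targets.reverse_complement_rna(mature)
        utr = "A" * 30 + site + "A" * 30 + site + "A" * 30
        sites = targets.predict_targets({"m": mature}, {"t": utr})
        best = sites[sites["best"]]
        assert len(best) == 1
        accepted = sites[sites["accepted"]]
        assert best["site_start"].item() == accepted["site_start"].min()


class TestConservation:
    def test_five_species_all_with_site_conserved(self, sim_config):
        _, _, _, orth = simulate.generate_utr_and_genesets(sim_config)
        rep = targets.conservation_check(profiles.SEEDS["ssc-miR-361-3p"], orth)
        assert rep["conserved"] and rep["n_with_site"] == 5

    def test_one_species_missing_site_not_conserved(self, sim_config):
        _, _, _, orth = simulate.generate_utr_and_genesets(sim_config)
        orth = dict(orth)
        orth["mouse"] = orth["mouse"].replace("CUGGGGG", "CUGAGGG")
        rep = targets.conservation_check("CCCCCAG", orth)
        assert not rep["conserved"] and rep["n_with_site"] == 4

    def test_single_species_errors(self):
        with pytest.raises(ValueError, match="2 species"):
            targets.conservation_check("CCCCCAG", {"pig": "CUGGGGG"})
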