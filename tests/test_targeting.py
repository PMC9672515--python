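"""Seed-site scanning, context scoring and duplex energetics."""

import numpy as np
import pytest

from cernapipe._seq import revcomp
from cernapipe.targeting import (
    DUPLEX_INITIATION,
    STACK_WC,
    SeedSite,
    SITE_LENGTH,
    duplex_energy,
    dual_threshold,
    find_seed_sites,
    predict_targets,
    score_site,
    site_energy,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def brute_force_sites(mirna: str, target: str) -> set[tuple[int, str]]:
    """Independent per-offset scanner testing each class definition in full."""
    s7 = revcomp(mirna[1:8])  # seed+m8 match, target 5'->3'
    s6 = revcomp(mirna[1:7])
    m8c = revcomp(mirna[7])
    L = len(target)
    found = set()
    for i in range(L):
        if target[i : i + 8] == s7 + "A":
            found.add((i, "8mer"))
        if target[i : i + 7] == s7 and (i + 7 == L or target[i + 7] != "A"):
            found.add((i, "7mer-m8"))
        if (
            target[i : i + 7] == s6 + "A"
            and (i == 0 or target[i - 1] != m8c)
        ):
            found.add((i, "7mer-A1"))
        if (
            target[i : i + 6] == s6
            and (i == 0 or target[i - 1] != m8c)
            and (i + 6 == L or target[i + 6] != "A")
        ):
            found.add((i, "6mer"))
    return found


class TestFindSeedSites:
    def test_8mer_by_construction(self):
        sites = find_seed_sites(LET7, "AAACUACCUCAAAA", "t")
        assert [(s.position, s.site_class) for s in sites] == [(3, "8mer")]

    def test_7mer_m8_when_not_followed_by_a(self):
        sites = find_seed_sites(LET7, "AAACUACCUCGAAA", "t")
        assert [(s.position, s.site_class) for s in sites] == [(3, "7mer-m8")]

    def test_each_window_reported_at_highest_class_only(self):
        # 7mer-A1: seed core + A, without the m8 match 5'-adjacent
        target = "GG" + revcomp(LET7[1:7]) + "AGG"
        sites = find_seed_sites(LET7, target, "t")
        assert [(s.position, s.site_class) for s in sites] == [(2, "7mer-A1")]

    def test_invalid_alphabet_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_seed_sites(LET7, "ACGXACG")

    def test_mirna_length_bounds(self):
        with pytest.raises(ValueError, match="18-26"):
            find_seed_sites("ACGUACGU", "ACGUACGU")

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(100):
            mirna = "".join(rng.choice(bases, size=int(rng.integers(18, 27))))
            # embed the seed match a few times so sites actually occur
            target = list(rng.choice(bases, size=200))
            core = revcomp(mirna[1:8]) + "A"
            for _k in range(3):
                p = int(rng.integers(0, 190))
                target[p : p + len(core)] = list(core)[: min(len(core), 200 - p)]
            target = "".join(target)[:200]
            got = {(s.position, s.site_class) for s in find_seed_sites(mirna, target)}
            assert got == brute_force_sites(mirna, target)


class TestScoreSite:
    def test_8mer_gc_flanks_no_three_prime_pairing_scores_base(self):
        site8 = revcomp(LET7[1:8]) + "A"
        target = "G" * 15 + site8 + "G" * 15
        [site] = find_seed_sites(LET7, target, "t")
        assert site.site_class == "8mer"
        assert score_site(site, LET7, target) == 75.0

    def test_6mer_au_flanks_gets_full_au_bonus(self):
        # miRNA with G-rich 3' end so all-A/U flanks cannot pair positions 13-17
        mirna = "UGAGGUAGUAGGGGGGGGGG"
        core = revcomp(mirna[1:7])
        # U guards: not the m8 complement (C) and not A, so the class stays 6mer
        target = "U" * 16 + core + "U" * 16
        sites = [s for s in find_seed_sites(mirna, target, "t") if s.site_class == "6mer"]
        assert sites
        score = score_site(sites[0], mirna, target)
        assert score == pytest.approx(40.0 + 15.0, abs=1e-9)

    def test_class_upgrade_never_lowers_score_in_same_context(self, rng):
        bases = np.array(list("ACGU"))
        order = ["6mer", "7mer-A1", "7mer-m8", "8mer"]
        for _ in range(50):
            mirna = "".join(rng.choice(bases, size=22))
            flank5 = "".join(rng.choice(bases, size=15))
            flank3 = "".join(rng.choice(bases, size=15))
            core6 = revcomp(mirna[1:7])
            m8c = revcomp(mirna[7])
            not_m8c = next(b for b in "CGUA" if b != m8c and b != "A")
            variants = {
                "6mer": not_m8c + core6 + "G",
                "7mer-A1": not_m8c + core6 + "A",
                "7mer-m8": m8c + core6 + "G",
                "8mer": m8c + core6 + "A",
            }
            scores = {}
            for cls, mid in variants.items():
                target = flank5 + mid + flank3
                sites = [
                    s for s in find_seed_sites(mirna, target, "t") if s.site_class == cls
                ]
                if not sites:  # flank happened to upgrade/duplicate the site
                    break
                scores[cls] = score_site(sites[0], mirna, target)
            else:
                ranked = [scores[c] for c in order]
                assert ranked == sorted(ranked)


class TestDuplexEnergy:
    def test_fully_complementary_gc_duplex_hand_summed(self):
        # 8 G:C pairs -> initiation + 7 GG/CC stacks from the shipped table
        expected = DUPLEX_INITIATION + 7 * STACK_WC["GG"]
        assert duplex_energy("GGGGGGGG", "CCCCCCCC") == pytest.approx(expected)

    def test_zero_pairs_is_initiation_only(self):
        assert duplex_energy("AAAAAAAA", "AAAAAAAA") == DUPLEX_INITIATION

    def test_adding_adjacent_gc_pair_strictly_lowers_energy(self):
        for k in range(4, 10):
            assert duplex_energy("G" * (k + 1), "C" * (k + 1)) < duplex_energy("G" * k, "C" * k)

    def test_interior_loop_penalized(self):
        # seed pairs + distal pairs with a gap: energy includes +1/nt loop terms
        mirna = "GGGGGGGG" + "AAAA" + "GGGGG"  # positions 9-12 cannot pair C
        target = "C" * 17
        dg = duplex_energy(mirna, target)
        expected = 4.09 + 11 * STACK_WC["GG"] + 4 * 1.0
        assert dg == pytest.approx(expected)
        contiguous = duplex_energy("G" * 13, "C" * 13)
        assert dg > contiguous  # the loop costs energy vs a contiguous helix


class TestPredictTargets:
    def test_dual_threshold_is_strict(self):
        assert dual_threshold(51.0, -21.0)
        assert not dual_threshold(50.0, -30.0)
        assert not dual_threshold(80.0, -19.0)

    def test_pass_flag_consistent_with_score_and_energy(self, small_dataset):
        ds = small_dataset
        mirnas = {m: ds.mirna_seqs[m] for m in list(ds.mirna_seqs)[:10]}
        pairs = predict_targets(mirnas, ds.utr_seqs, "mRNA")
        assert len(pairs)
        expected = (pairs["score"] > 50.0) & (pairs["energy"] < -20.0)
        assert (pairs["passes"] == expected).all()

    def test_planted_sites_recovered_and_background_clean(self):
        from cernapipe.datagen import SimulationConfig, generate_dataset

        sens_num = sens_den = 0
        fp_num = fp_den = 0
        for seed in range(1, 6):
            cfg = SimulationConfig(
                n_mirna=12, n_mrna=60, n_circ=30, rng_seed=seed, lfc_magnitude=2.0
            )
            ds = generate_dataset(cfg)
            pairs = predict_targets(ds.mirna_seqs, ds.utr_seqs, "mRNA")
            passing = {
                (r.mirna_id, r.target_id) for r in pairs.itertuples() if r.passes
            }
            truth = ds.truth.planted_pairs
            planted = {
                (r.mirna_id, r.target_id)
                for r in truth[truth["target_layer"] == "mRNA"].itertuples()
            }
            sens_num += len(planted & passing)
            sens_den += len(planted)
            unplanted_universe = {
                (m, g) for m in ds.mirna_seqs for g in ds.utr_seqs
            } - planted
            fp_num += len(passing - planted)
            fp_den += len(unplanted_universe)
        assert sens_num / sens_den >= 0.9
        assert fp_num / fp_den <= 0.05

    def test_deterministic(self, small_dataset):
        ds = small_dataset
        mirnas = {m: ds.mirna_seqs[m] for m in list(ds.mirna_seqs)[:5]}
        a = predict_targets(mirnas, ds.circ_seqs, "circRNA")
        b = predict_targets(mirnas, ds.circ_seqs, "circRNA")
        assert a.equals(b)


def test_site_energy_handles_site_at_target_end():
    # 8mer flush with the 3' end of the target: padded, not crashing
    site8 = revcomp(LET7[1:8]) + "A"
    target = "G" * 20 + site8
    [site] = find_seed_sites(LET7, target, "t")
    assert isinstance(site_energy(site, LET7, target), float)
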