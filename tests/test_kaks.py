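import numpy as np
import pytest

from agpkit.kaks import (
    CODON_TO_AA,
    STOP_CODONS,
    CodonAlignment,
    compare_groups,
    kaks,
    ng86_differences,
    ng86_site_counts,
    project_codon_alignment,
)
from oracles import oracle_codon_diffs, oracle_codon_sites, oracle_kaks

SENSE = sorted(set(CODON_TO_AA) - STOP_CODONS)


def _codon_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    return CodonAlignment(
        tuple(cds_a[i : i + 3] for i in range(0, len(cds_a), 3)),
        tuple(cds_b[i : i + 3] for i in range(0, len(cds_b), 3)),
    )


class TestProjection:
    def test_simple_two_codons(self):
        aln = project_codon_alignment(("MA", "MA"), "ATGGCT", "ATGGCA")
        assert len(aln) == 2

    def test_gapped_column_dropped(self):
        aln = project_codon_alignment(("M-A", "MKA"), "ATGGCT", "ATGAAAGCA")
        assert len(aln) == 2
        assert aln.codons_a == ("ATG", "GCT")
        assert aln.codons_b == ("ATG", "GCA")

    def test_terminal_stop_trimmed(self):
        aln = project_codon_alignment(("MA", "MA"), "ATGGCTTAA", "ATGGCA")
        assert len(aln) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            project_codon_alignment(("MA", "MA"), "ATGGC", "ATGGCA")

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            project_codon_alignment(("MA", "MA"), "ATGAAA", "ATGGCA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            project_codon_alignment(("M*A", "MKA"), "ATGTAAGCT", "ATGAAAGCA")


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,s",
        [("TTT", 1 / 3), ("ATG", 0.0), ("TGG", 0.0)],
    )
    def test_enumerated_examples(self, codon, s):
        assert ng86_site_counts(codon)[0] == pytest.approx(s)

    def test_trp_sites_reduced_by_stop_exclusion(self):
        s, n = ng86_site_counts("TGG")
        assert s + n == pytest.approx(7 / 3)  # two stop-bound changes excluded

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE:
            assert ng86_site_counts(codon) == pytest.approx(oracle_codon_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")


class TestDifferences:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("TTT", "TTC", (1.0, 0.0)),  # Phe -> Phe
            ("TTT", "TTA", (0.0, 1.0)),  # Phe -> Leu
            ("TTT", "GTA", (0.5, 1.5)),  # average over the two orderings
        ],
    )
    def test_pathway_examples(self, a, b, expected):
        assert ng86_differences(a, b) == pytest.approx(expected)

    def test_identical_codons_zero(self):
        assert ng86_differences("ATG", "ATG") == (0.0, 0.0)

    def test_random_pairs_match_pathway_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            a, b = (SENSE[i] for i in rng.integers(len(SENSE), size=2))
            assert ng86_differences(a, b) == pytest.approx(oracle_codon_diffs(a, b))

    def test_diff_totals_equal_differing_positions(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b = (SENSE[i] for i in rng.integers(len(SENSE), size=2))
            s, n = ng86_differences(a, b)
            assert s + n == sum(x != y for x, y in zip(a, b))


class TestKaks:
    def test_identical_sequences_undefined(self):
        codons = tuple(SENSE[:20])
        res = kaks(CodonAlignment(codons, codons))
        assert res.undefined and res.omega is None
        assert res.s_diffs == res.n_diffs == 0

    def test_symmetric(self):
        rng = np.random.default_rng(8)
        a = tuple(SENSE[i] for i in rng.integers(len(SENSE), size=30))
        b = tuple(SENSE[i] for i in rng.integers(len(SENSE), size=30))
        r1, r2 = kaks(CodonAlignment(a, b)), kaks(CodonAlignment(b, a))
        assert r1.s_sites == pytest.approx(r2.s_sites)
        assert r1.s_diffs == pytest.approx(r2.s_diffs)
        assert (r1.omega is None) == (r2.omega is None)
        if r1.omega is not None:
            assert r1.omega == pytest.approx(r2.omega)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        # 100 random 5-30 codon pairs vs the independent enumeration oracle
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            a = tuple(SENSE[i] for i in rng.integers(len(SENSE), size=n))
            b = tuple(
                SENSE[i] if rng.random() < 0.5 else a[k]
                for k, i in enumerate(rng.integers(len(SENSE), size=n))
            )
            res = kaks(CodonAlignment(a, b), min_codons=5)
            S, N, Sd, Nd, ds, dn = oracle_kaks(a, b)
            assert res.s_sites == pytest.approx(S)
            assert res.n_sites == pytest.approx(N)
            assert res.s_diffs == pytest.approx(Sd)
            assert res.n_diffs == pytest.approx(Nd)
            if ds is not None and dn is not None:
                assert res.ds == pytest.approx(ds)
                assert res.dn == pytest.approx(dn)
            else:
                assert res.saturated

    def test_site_counts_sum_to_three_minus_stop_fraction(self):
        for codon in SENSE:
            s, n = ng86_site_counts(codon)
            stops = sum(
                1
                for pos in range(3)
                for nuc in "ACGT"
                if nuc != codon[pos]
                and codon[:pos] + nuc + codon[pos + 1 :] in STOP_CODONS
            )
            assert s + n == pytest.approx(3 - stops / 3)

    def test_too_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            kaks(CodonAlignment(("ATG",), ("ATG",)))


class TestOmegaRecovery:
    @pytest.mark.parametrize("omega", [0.2, 0.5, 1.0])
    def test_mean_estimate_within_tolerance(self, omega):
        from agpkit.synthetic import EvolSimSpec, evolve_codon_pair

        ests = []
        for seed in range(50):
            anc, der, _ = evolve_codon_pair(
                EvolSimSpec(n_codons=300, omega=omega, target_ds=0.2, seed=seed)
            )
            res = kaks(_codon_alignment(anc.nucleotides, der.nucleotides))
            assert res.omega is not None
            ests.append(res.omega)
        assert abs(float(np.mean(ests)) - omega) <= 0.1

    def test_purifying_selection_detected(self):
        from agpkit.synthetic import EvolSimSpec, evolve_codon_pair

        for seed in range(10):
            anc, der, _ = evolve_codon_pair(
                EvolSimSpec(n_codons=300, omega=0.3, target_ds=0.25, seed=100 + seed)
            )
            res = kaks(_codon_alignment(anc.nucleotides, der.nucleotides))
            assert res.omega is not None and res.omega < 1


class TestGroupComparison:
    def test_identical_groups_share_letter(self):
        comp = compare_groups({"a": [0.2, 0.21, 0.19], "b": [0.2, 0.21, 0.19]})
        assert comp.letters["a"] == comp.letters["b"]
        assert comp.p_value > 0.5

    def test_separated_groups_distinct_letters(self):
        comp = compare_groups(
            {"slow": [0.1, 0.11, 0.12], "fast": [0.9, 0.91, 0.92]}
        )
        assert set(comp.letters["slow"]).isdisjoint(comp.letters["fast"])
        assert comp.p_value < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"only": [0.1, 0.2]})

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [0.1, 0.2], "b": [0.3]})

    def test_three_group_letter_consistency(self):
        comp = compare_groups(
            {
                "a": [0.10, 0.12, 0.11, 0.13],
                "b": [0.12, 0.14, 0.13, 0.15],
                "c": [0.90, 0.92, 0.91, 0.93],
            }
        )
        # a and b overlap, c stands apart
        assert set(comp.letters["a"]) & set(comp.letters["b"])
        assert set(comp.letters["c"]).isdisjoint(comp.letters["a"])
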