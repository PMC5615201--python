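import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endosym.composition import SequenceRecord, write_fasta
from endosym.distances import (
    Alignment,
    SaturationError,
    SiteFilterPolicy,
    distance_matrix,
    filter_sites,
    jc69_distance,
    k2p_distance,
    p_q_counts,
    relative_rate_test,
    triplet_decompose,
)
from endosym.simulate import SeqSimParams, simulate_alignment


def aln_from(seqs: dict[str, str]) -> Alignment:
    return Alignment.from_records(
        [SequenceRecord(k, v) for k, v in seqs.items()]
    )


class TestFilterSites:
    def test_gapless_unchanged(self):
        aln = aln_from({"a": "ACGTA", "b": "ACGTT"})
        assert filter_sites(aln).n_sites == 5

    def test_single_gap_drops_one_column(self):
        aln = aln_from({"a": "ACGTA", "b": "ACGTT", "c": "ACG-A"})
        out = filter_sites(aln, SiteFilterPolicy("complete_deletion"))
        assert out.n_sites == 4

    def test_all_gap_column_dropped_under_both_modes(self):
        aln = aln_from({"a": "A-GT", "b": "A-GT"})
        for mode in ("complete_deletion", "pairwise_deletion"):
            assert filter_sites(aln, SiteFilterPolicy(mode)).n_sites == 3

    def test_ambiguity_retained_when_not_missing(self):
        aln = aln_from({"a": "ANGT", "b": "ACGT"})
        strict = filter_sites(aln, SiteFilterPolicy("complete_deletion", True))
        lax = filter_sites(aln, SiteFilterPolicy("complete_deletion", False))
        assert strict.n_sites == 3 and lax.n_sites == 4

    def test_nothing_surviving_is_degenerate(self):
        with pytest.raises(ValueError, match="no columns"):
            filter_sites(aln_from({"a": "-N", "b": "A-"}))


class TestPQCounts:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", (0.0, 0.0)),
            ("AAAA", "GGGG", (1.0, 0.0)),
            ("AACC", "AGCA", (0.25, 0.25)),
            ("CCCC", "TTTT", (1.0, 0.0)),  # pyrimidine transition
            ("AAAA", "CCCC", (0.0, 1.0)),
        ],
    )
    def test_classification(self, a, b, expected):
        aln = aln_from({"x": a, "y": b})
        P, Q, n = p_q_counts(aln.codes[0], aln.codes[1])
        assert (P, Q) == expected and n == len(a)

    def test_missing_sites_excluded(self):
        aln = aln_from({"x": "A-GN", "y": "AAGT"})
        P, Q, n = p_q_counts(aln.codes[0], aln.codes[1])
        assert n == 2 and P == 0.0 and Q == 0.0

    def test_no_shared_sites_error(self):
        aln = aln_from({"x": "A-", "y": "-A"})
        with pytest.raises(ValueError, match="no shared"):
            p_q_counts(aln.codes[0], aln.codes[1])


class TestCorrections:
    def test_jc69_closed_form(self):
        assert jc69_distance(0.0) == 0.0
        assert jc69_distance(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert jc69_distance(0.1) == pytest.approx(0.107326, abs=5e-7)
        assert math.isfinite(jc69_distance(0.74))
        with pytest.raises(SaturationError):
            jc69_distance(0.75)

    def test_k2p_closed_form(self):
        assert k2p_distance(0.0, 0.0) == 0.0
        assert k2p_distance(0.1, 0.0) == pytest.approx(-0.5 * math.log(0.8))
        assert k2p_distance(0.1, 0.0) == pytest.approx(0.111572, abs=5e-7)
        assert k2p_distance(0.0, 0.1) == pytest.approx(
            -0.5 * math.log(0.9) - 0.25 * math.log(0.8)
        )
        for P, Q in [(0.5, 0.0), (0.0, 0.5), (0.45, 0.1)]:
            with pytest.raises(SaturationError):
                k2p_distance(P, Q)

    @given(p=st.floats(0.001, 0.7), q_frac=st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=100)
    def test_corrections_exceed_raw_mismatch(self, p, q_frac):
        assert jc69_distance(p) >= p
        P, Q = p * (1 - q_frac), p * q_frac
        if 1 - 2 * P - Q > 1e-9 and 1 - 2 * Q > 1e-9:
            assert k2p_distance(P, Q) >= p - 1e-12

    def test_k2p_matches_r_ape_oracle(self, tmp_path):
        """Independent cross-check of the whole distance path against ape."""
        aln = simulate_alignment(
            SeqSimParams(tree="((A:0.05,B:0.08):0.02,(C:0.1,D:0.03):0.01);",
                         length=800, model="k2p", kappa=2.0, seed=17)
        )
        fasta = tmp_path / "aln.fasta"
        write_fasta(aln.to_records(), fasta)
        script = (
            f'x <- ape::read.dna("{fasta}", format="fasta"); '
            'd <- ape::dist.dna(x, model="K80", pairwise.deletion=FALSE); '
            'cat(sprintf("%.10f", as.vector(d)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ape_vals = [float(v) for v in out.stdout.split()]
        D = distance_matrix(aln, model="k2p")
        ours = D.d[np.triu_indices(4, k=1)]
        # ape orders the lower triangle column-wise: AB, AC, AD, BC, BD, CD.
        assert np.allclose(sorted(ours), sorted(ape_vals), atol=1e-9)


class TestTripletDecompose:
    @pytest.mark.parametrize(
        "dab, dao, dbo, k1, k2",
        [
            (0.2, 0.3, 0.3, 0.1, 0.1),
            (0.196, 0.25, 0.322, 0.062, 0.134),
            (0.0, 0.3, 0.3, 0.0, 0.0),
        ],
    )
    def test_examples(self, dab, dao, dbo, k1, k2):
        got = triplet_decompose(dab, dao, dbo)
        assert got == (pytest.approx(k1), pytest.approx(k2))

    @given(
        dab=st.floats(0, 1), dao=st.floats(0, 1), dbo=st.floats(0, 1)
    )
    @settings(deadline=None, max_examples=100)
    def test_conserves_dab(self, dab, dao, dbo):
        k1, k2 = triplet_decompose(dab, dao, dbo)
        assert k1 + k2 == pytest.approx(dab, abs=1e-15)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            triplet_decompose(-0.1, 0.2, 0.2)
        with pytest.raises(ValueError):
            triplet_decompose(0.1, math.nan, 0.2)


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal(self):
        aln = simulate_alignment(
            SeqSimParams(tree="((A:0.05,B:0.05):0.05,C:0.1);", length=2000, seed=1)
        )
        D = distance_matrix(aln, model="jc69")
        assert np.allclose(D.d, D.d.T) and np.all(np.diag(D.d) == 0)
        assert D.get("A", "B") == D.get("B", "A") > 0


class TestRelativeRateTest:
    def test_identical_lineages_null(self):
        aln = simulate_alignment(
            SeqSimParams(tree="((A:0.0,B:0.0):0.05,O:0.1);", length=2000, seed=6)
        )
        res = relative_rate_test(aln, ["A"], ["B"], ["O"], n_bootstrap=100, seed=0)
        assert res.diff == 0.0 and res.p_two_sided == 1.0 and res.ratio == 1.0

    def test_swap_antisymmetry(self):
        aln = simulate_alignment(
            SeqSimParams(tree="((A:0.08,B:0.03):0.02,O:0.15);", length=5000, seed=8)
        )
        fwd = relative_rate_test(aln, ["A"], ["B"], ["O"], n_bootstrap=300, seed=4)
        rev = relative_rate_test(aln, ["B"], ["A"], ["O"], n_bootstrap=300, seed=4)
        assert fwd.diff == pytest.approx(-rev.diff)
        assert fwd.ratio == pytest.approx(1.0 / rev.ratio)
        assert fwd.k1 == pytest.approx(rev.k2)

    def test_exhaustive_triplet_oracle_small(self):
        """Bootstrap-free K1/K2 equal a literal enumeration of all triplets."""
        aln = simulate_alignment(
            SeqSimParams(
                tree="(((A1:0.04,A2:0.06):0.02,(B1:0.03,B2:0.05):0.01):0.02,"
                "(O1:0.08,O2:0.07):0.0);",
                length=30,
                seed=13,
            )
        )
        l1, l2, og = ["A1", "A2"], ["B1", "B2"], ["O1", "O2"]
        res = relative_rate_test(aln, l1, l2, og, n_bootstrap=50, seed=1)

        def d(x, y):
            P, Q, _ = p_q_counts(aln.row(x), aln.row(y))
            return k2p_distance(P, Q)

        k1s, k2s = [], []
        for a in l1:
            for b in l2:
                for o in og:
                    k1, k2 = triplet_decompose(d(a, b), d(a, o), d(b, o))
                    k1s.append(k1)
                    k2s.append(k2)
        assert res.k1 == pytest.approx(np.mean(k1s), abs=1e-12)
        assert res.k2 == pytest.approx(np.mean(k2s), abs=1e-12)

    def test_recovers_half_rate_ratio(self):
        # Lineage 1 evolving at ~0.46x the rate of lineage 2.
        aln = simulate_alignment(
            SeqSimParams(
                tree="((L1:0.06,L2:0.13):0.0,O:0.10);",
                length=100_000,
                model="k2p",
                kappa=2.0,
                seed=5,
            )
        )
        res = relative_rate_test(aln, ["L1"], ["L2"], ["O"], n_bootstrap=500, seed=2)
        assert res.ratio == pytest.approx(0.46, abs=0.06)
        assert res.p_two_sided < 0.001

    def test_input_validation(self):
        aln = aln_from({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        with pytest.raises(ValueError, match="disjoint"):
            relative_rate_test(aln, ["a"], ["a"], ["c"])
        with pytest.raises(ValueError, match="nonempty"):
            relative_rate_test(aln, ["a"], ["b"], [])
        with pytest.raises(ValueError, match="n_bootstrap"):
            relative_rate_test(aln, ["a"], ["b"], ["c"], n_bootstrap=1)
        with pytest.raises(KeyError):
            relative_rate_test(aln, ["a"], ["b"], ["zz"], n_bootstrap=10)

    def test_deterministic_given_seed(self):
        aln = simulate_alignment(
            SeqSimParams(tree="((A:0.05,B:0.08):0.0,O:0.1);", length=3000, seed=3)
        )
        r1 = relative_rate_test(aln, ["A"], ["B"], ["O"], n_bootstrap=200, seed=9)
        r2 = relative_rate_test(aln, ["A"], ["B"], ["O"], n_bootstrap=200, seed=9)
        assert r1 == r2
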