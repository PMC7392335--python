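import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualgenome import io
from dualgenome.analyses import (ClassifierConfig, DeNovoConfig, NegMatchConfig,
                                 build_matched_negatives, classify_with_cv,
                                 compare_cv_results, filter_by_tss_distance,
                                 filter_pathogenic_set, individual_risk_score,
                                 proband_sibling_tests, summarize_eqtl_effects,
                                 weight_scores)
from dualgenome.variants import Variant


class TestFilterPathogenic:
    def _v(self, pos, vid="v"):
        return Variant("chr1", pos, "A", "G", f"{vid}{pos}")

    def test_near_splice_site_removed(self):
        # variant 15 bp from a splice site: inside the 20 bp exclusion
        variants = [self._v(100)]
        sites = [("chr1", 114, 115, "")]
        assert filter_pathogenic_set(variants, sites, NegMatchConfig()) == []

    def test_beyond_exclusion_kept(self):
        variants = [self._v(100)]
        sites = [("chr1", 150, 151, "")]
        out = filter_pathogenic_set(variants, sites, NegMatchConfig())
        assert len(out) == 1

    def test_two_close_variants_one_kept(self):
        variants = [self._v(100), self._v(108)]
        out = filter_pathogenic_set(variants, [], NegMatchConfig(seed=0))
        assert len(out) == 1

    def test_transitive_chain_one_group(self):
        # gaps of 8 and 8: span 16 > 10, but chaining joins all three; the
        # union-find oracle (single merged set) expects one representative
        variants = [self._v(100), self._v(108), self._v(116)]
        parent = list(range(3))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        positions = [100, 108, 116]
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(positions[i] - positions[j]) <= 10:
                    parent[find(j)] = find(i)
        n_groups = len({find(i) for i in range(3)})
        assert n_groups == 1
        out = filter_pathogenic_set(variants, [], NegMatchConfig(seed=0))
        assert len(out) == n_groups

    def test_deterministic(self):
        variants = [self._v(p) for p in (100, 105, 300, 306, 900)]
        a = filter_pathogenic_set(variants, [], NegMatchConfig(seed=4))
        b = filter_pathogenic_set(variants, [], NegMatchConfig(seed=4))
        assert [v.id for v in a] == [v.id for v in b]


@pytest.fixture(scope="module")
def neg_genome(tmp_path_factory):
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    path = str(tmp_path_factory.mktemp("neg") / "g.fa")
    io.write_fasta(path, {"chr1": seq})
    return io.read_fasta(path), seq


class TestMatchedNegatives:
    def test_exact_offset_match_chosen(self, tmp_path):
        # ref base present exactly at pos +/- 1000: that position wins
        seq = ["C"] * 5000
        seq[2000] = "A"
        seq[3000] = "A"  # downstream anchor hit, distance exactly 1000
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": "".join(seq)})
        genome = io.read_fasta(str(tmp_path / "g.fa"))
        v = Variant("chr1", 2001, "A", "G", "p1")
        (neg,) = build_matched_negatives([v], genome, NegMatchConfig(seed=0))
        assert neg.start == 3000
        assert (neg.ref, neg.alt) == ("A", "G")

    def test_closer_to_target_wins(self, tmp_path):
        # upstream match at distance 1002, downstream at exactly 1000:
        # exhaustive-scan oracle picks downstream
        seq = ["C"] * 5000
        seq[2000] = "A"
        seq[998] = "A"   # upstream: |2000-998|  = 1002
        seq[3000] = "A"  # downstream: exactly 1000
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": "".join(seq)})
        genome = io.read_fasta(str(tmp_path / "g.fa"))
        v = Variant("chr1", 2001, "A", "G", "p1")
        (neg,) = build_matched_negatives([v], genome, NegMatchConfig(seed=0))
        assert neg.start == 3000

    def test_tie_reproducible_under_seed(self, tmp_path):
        seq = ["C"] * 5000
        seq[2000] = "A"
        seq[1000] = "A"
        seq[3000] = "A"  # both anchors at error 0: tie
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": "".join(seq)})
        genome = io.read_fasta(str(tmp_path / "g.fa"))
        v = Variant("chr1", 2001, "A", "G", "p1")
        picks = {build_matched_negatives([v], genome, NegMatchConfig(seed=7))[0].start
                 for _ in range(3)}
        assert len(picks) == 1

    def test_no_match_skipped_with_warning(self, tmp_path):
        seq = ["C"] * 5000
        seq[2000] = "A"  # only A in the genome
        io.write_fasta(str(tmp_path / "g.fa"), {"chr1": "".join(seq)})
        genome = io.read_fasta(str(tmp_path / "g.fa"))
        v = Variant("chr1", 2001, "A", "G", "p1")
        with pytest.warns(UserWarning, match="skipped"):
            out = build_matched_negatives([v], genome, NegMatchConfig(seed=0))
        assert out == []

    def test_composition_preserved_and_within_cap(self, neg_genome):
        genome, seq = neg_genome
        rng = np.random.default_rng(3)
        positives = []
        for pos0 in rng.integers(1500, 8500, size=20):
            ref = seq[pos0]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            positives.append(Variant("chr1", int(pos0) + 1, ref, alt, f"p{pos0}"))
        cfg = NegMatchConfig(seed=0)
        negatives = build_matched_negatives(positives, genome, cfg)
        assert len(negatives) == len(positives)
        assert sorted((v.ref, v.alt) for v in positives) == \
               sorted((v.ref, v.alt) for v in negatives)
        by_id = {v.id: v for v in positives}
        for neg in negatives:
            pos = by_id[neg.id.removeprefix("neg_")]
            d = abs(neg.start - pos.start)
            assert cfg.target_offset - cfg.search_cap <= d \
                   <= cfg.target_offset + cfg.search_cap
            assert seq[neg.start] == neg.ref


class TestClassifyCV:
    def test_oracle_feature_auroc_one(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=64)
        features = labels[:, None].astype(float)
        result = classify_with_cv(features, labels,
                                  ClassifierConfig(iterations=2, seed=0,
                                                   n_estimators=25))
        np.testing.assert_allclose(result.aurocs, 1.0)

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(1)
        labels = np.array([0, 1] * 32)
        features = rng.normal(size=(64, 5))
        result = classify_with_cv(features, labels,
                                  ClassifierConfig(iterations=6, seed=0,
                                                   n_estimators=25))
        assert abs(result.aurocs.mean() - 0.5) < 0.12

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            classify_with_cv(np.zeros((8, 2)), np.zeros(8),
                             ClassifierConfig(iterations=1))

    def test_separable_beats_permuted_every_iteration(self):
        rng = np.random.default_rng(2)
        labels = np.array([0, 1] * 40)
        effect = labels * 2.0 + rng.normal(0, 0.3, size=80)
        features = np.column_stack([effect, rng.normal(size=80)])
        good = classify_with_cv(features, labels,
                                ClassifierConfig(iterations=5, seed=1,
                                                 n_estimators=25))
        perm = rng.permutation(labels)
        bad = classify_with_cv(features, perm,
                               ClassifierConfig(iterations=5, seed=1,
                                                n_estimators=25))
        assert (good.aurocs > bad.aurocs.max()).all()
        u, p = compare_cv_results(good, bad)
        assert p < 0.05


class TestEqtlSummary:
    def test_mean(self):
        assert summarize_eqtl_effects([0.2, 0.4]) == pytest.approx(0.3)

    def test_single(self):
        assert summarize_eqtl_effects([0.7]) == 0.7

    def test_matches_sum_oracle(self, rng):
        vals = rng.normal(size=17)
        assert summarize_eqtl_effects(vals) == pytest.approx(vals.sum() / 17)

    def test_empty_is_nan(self):
        assert np.isnan(summarize_eqtl_effects([]))


class TestWeightScores:
    def test_negative_scaled(self):
        assert weight_scores(np.array([-0.5]), 10)[0] == pytest.approx(5.0)

    def test_positive_passthrough(self):
        assert weight_scores(np.array([0.3]), 10)[0] == pytest.approx(0.3)

    def test_weight_one_is_abs(self, rng):
        s = rng.normal(size=20)
        np.testing.assert_allclose(weight_scores(s, 1), np.abs(s))

    def test_weight_below_one_rejected(self):
        with pytest.raises(ValueError):
            weight_scores(np.array([1.0]), 0.5)


class TestTssFilter:
    def test_within_distance_kept(self):
        tss = [("chr1", 10_000, 10_001, "t")]
        near = Variant("chr1", 40_000, "A", "G", "near")
        far = Variant("chr1", 90_000, "A", "G", "far")
        out = filter_by_tss_distance([near, far], tss, 50_000)
        assert [v.id for v in out] == ["near"]


class TestProbandSiblingTests:
    def test_worked_mwu_example(self):
        # {3,4,5} vs {1,2}: U = 6, exact one-sided p = 1/10, two-sided 0.2
        u, p = sps.mannwhitneyu([3, 4, 5], [1, 2], alternative="greater",
                                method="exact")
        assert u == 6 and p == pytest.approx(0.1)
        table = proband_sibling_tests(
            pd.DataFrame({"d": [3.0, 4.0, 5.0]}),
            pd.DataFrame({"d": [1.0, 2.0]}),
            DeNovoConfig(),
        )
        assert table.p_value.iloc[0] == pytest.approx(0.2)
        assert table.effect.iloc[0] > 0

    def test_identical_multisets_null(self):
        scores = pd.DataFrame({"d": [1.0, 2.0, 3.0]})
        table = proband_sibling_tests(scores, scores.copy(), DeNovoConfig())
        assert table.effect.iloc[0] == 0.0
        assert table.p_value.iloc[0] > 0.99

    def test_bh_null_false_positive_control(self):
        # 100 seeded replicates of 20 null datasets: average fraction of
        # q < 0.05 datasets stays at or below the FDR level
        rng = np.random.default_rng(0)
        cfg = DeNovoConfig()
        fractions = []
        for _ in range(100):
            p = pd.DataFrame(rng.gamma(2.0, 1.0, size=(60, 20)),
                             columns=[f"d{i}" for i in range(20)])
            s = pd.DataFrame(rng.gamma(2.0, 1.0, size=(60, 20)),
                             columns=[f"d{i}" for i in range(20)])
            table = proband_sibling_tests(p, s, cfg)
            fractions.append(table.significant.mean())
        assert np.mean(fractions) <= 0.05

    def test_negative_scores_weighted_up(self):
        cfg = DeNovoConfig(negative_weight=10)
        p = pd.DataFrame({"d": [-1.0] * 10})
        s = pd.DataFrame({"d": [1.0] * 10})
        table = proband_sibling_tests(p, s, cfg)
        # proband -1 scores become 10, sibling stay 1: positive effect
        assert table.effect.iloc[0] == pytest.approx(np.log(11) - np.log(2))


class TestRiskScore:
    def _frame(self, fam_scores):
        rows = []
        for fam, (p, s) in enumerate(fam_scores):
            rows.append({"family": fam, "role": "proband", "score": p})
            rows.append({"family": fam, "role": "sibling", "score": s})
        return pd.DataFrame(rows)

    def test_all_tied_p_one(self):
        result = individual_risk_score(self._frame([(1.0, 1.0)] * 5))
        assert result.informative_families == 0
        assert result.p_value == 1.0

    def test_eight_of_eight_exact_binomial(self):
        result = individual_risk_score(self._frame([(2.0, 1.0)] * 8))
        assert result.successes == 8
        assert result.p_value == pytest.approx(2 * 0.5 ** 8)
        assert result.proband_fraction == 1.0

    def test_label_swap_flips_successes(self):
        fams = [(2.0, 1.0), (3.0, 5.0), (9.0, 4.0), (0.5, 1.5)]
        fwd = individual_risk_score(self._frame(fams))
        swapped = individual_risk_score(self._frame([(s, p) for p, s in fams]))
        assert swapped.successes == fwd.informative_families - fwd.successes
        assert swapped.p_value == pytest.approx(fwd.p_value)

    def test_missing_member_excluded_with_warning(self):
        frame = self._frame([(2.0, 1.0)] * 3)
        frame = pd.concat([frame, pd.DataFrame(
            [{"family": 99, "role": "proband", "score": 5.0}])])
        with pytest.warns(UserWarning, match="missing"):
            result = individual_risk_score(frame)
        assert len(result.individual_sums) == 3
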