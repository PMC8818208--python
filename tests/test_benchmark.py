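"""Configuration enumeration, similarity matrices and ranking evaluation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phenosim import (
    AnnotationCorpus,
    LabeledAdmission,
    OntologyGraph,
    PairRecord,
    PhenotypeProfile,
    SimilarityConfig,
    SimilarityEngine,
    SimilarityMatrix,
    build_pair_records,
    compute_similarity_matrix,
    correlate_metrics,
    default_roster,
    enumerate_configs,
    evaluate_auc,
    evaluate_rankings,
    profile_similarity,
    run_benchmark,
)
from phenosim.benchmark import RESULT_COLUMNS, EvaluationResult
from phenosim.similarity import MeasureDescriptor

from conftest import make_random_parents


def adm(aid, terms, diagnosis):
    return LabeledAdmission(aid, PhenotypeProfile(aid, frozenset(terms)), diagnosis)


def small_roster(n_indirect=1, n_pw=1, n_pw_ic=0, n_ic=0, n_direct=0, n_direct_ic=0):
    roster = []
    roster += [MeasureDescriptor(f"i{k}", "groupwise-indirect", needs_pairwise=True) for k in range(n_indirect)]
    roster += [MeasureDescriptor(f"p{k}", "pairwise") for k in range(n_pw)]
    roster += [MeasureDescriptor(f"q{k}", "pairwise", needs_ic=True) for k in range(n_pw_ic)]
    roster += [MeasureDescriptor(f"c{k}", "ic") for k in range(n_ic)]
    roster += [MeasureDescriptor(f"d{k}", "groupwise-direct") for k in range(n_direct)]
    roster += [MeasureDescriptor(f"g{k}", "groupwise-direct", needs_ic=True) for k in range(n_direct_ic)]
    return roster


def oracle_enumerate(roster):
    """Brute-force cross-product over the combination rules."""
    ics = sorted(m.id for m in roster if m.level == "ic")
    pw = sorted(m.id for m in roster if m.level == "pairwise")
    pw_needs = {m.id: m.needs_ic for m in roster if m.level == "pairwise"}
    combos = set()
    for m in roster:
        if m.level == "groupwise-direct":
            if m.needs_ic:
                combos |= {(m.id, None, ic) for ic in ics}
            else:
                combos.add((m.id, None, None))
        elif m.level == "groupwise-indirect":
            for p in pw:
                if pw_needs[p]:
                    combos |= {(m.id, p, ic) for ic in ics}
                else:
                    combos.add((m.id, p, None))
    return combos


class TestEnumerateConfigs:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(n_indirect=1, n_pw=1), 1),
            (dict(n_indirect=1, n_pw=0, n_pw_ic=1, n_ic=2), 2),
            (dict(n_indirect=2, n_pw=2, n_pw_ic=1, n_ic=3, n_direct=2, n_direct_ic=1), 15),
        ],
    )
    def test_counts(self, kwargs, expected):
        assert len(enumerate_configs(small_roster(**kwargs))) == expected

    def test_matches_cross_product_oracle(self):
        for kwargs in (
            dict(n_indirect=2, n_pw=2, n_pw_ic=1, n_ic=3, n_direct=2, n_direct_ic=1),
            dict(n_indirect=3, n_pw=1, n_pw_ic=2, n_ic=2, n_direct=1),
            dict(n_indirect=1, n_pw=2, n_direct_ic=2, n_ic=1),
        ):
            roster = small_roster(**kwargs)
            got = {(c.groupwise, c.pairwise, c.ic) for c in enumerate_configs(roster)}
            assert got == oracle_enumerate(roster)

    def test_order_deterministic_and_lexicographic(self):
        configs = enumerate_configs(default_roster())
        keys = [c.sort_key for c in configs]
        assert keys == sorted(keys)
        assert configs == enumerate_configs(default_roster())
        assert len({c.config_id for c in configs}) == len(configs)

    def test_duplicate_roster_entry_rejected(self):
        roster = small_roster(n_indirect=1, n_pw=1) + [MeasureDescriptor("p0", "pairwise")]
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_configs(roster)

    def test_ic_needing_measures_without_ic_rejected(self):
        with pytest.raises(ValueError, match="no IC"):
            enumerate_configs(small_roster(n_indirect=1, n_pw_ic=1, n_pw=0))


@pytest.fixture(scope="module")
def toy_setting(request):
    parents = {
        "r": set(), "a": {"r"}, "b": {"r"}, "c": {"a"},
        "d": {"a"}, "e": {"b"}, "f": {"c"},
    }
    g = OntologyGraph(parents)
    admissions = [
        adm("A1", {"a", "b"}, "X"),
        adm("A2", {"b", "c"}, "X"),
        adm("A3", {"d"}, "Y"),
    ]
    corpus = AnnotationCorpus.from_dict({a.admission_id: a.profile.terms for a in admissions})
    return g, corpus, admissions


class TestSimilarityMatrix:
    def test_identical_profiles_score_one(self, toy_setting):
        g, corpus, _ = toy_setting
        twins = [adm("A1", {"c", "e"}, "X"), adm("A2", {"c", "e"}, "X")]
        S = compute_similarity_matrix(g, corpus, twins, SimilarityConfig("jaccard"))
        assert S.values[0, 1] == 1.0

    def test_jaccard_matrix_by_hand(self, toy_setting):
        g, corpus, admissions = toy_setting
        S = compute_similarity_matrix(g, corpus, admissions, SimilarityConfig("jaccard"))
        assert S.values[0, 1] == pytest.approx(1 / 3)
        assert S.values[0, 2] == 0.0
        assert S.values[1, 2] == 0.0

    def test_engine_matches_scalar_measures_everywhere(self):
        rng = np.random.default_rng(20)
        g = OntologyGraph(make_random_parents(rng, 50))
        terms = sorted(g.terms - {g.root})
        admissions = [
            adm(f"A{i}", rng.choice(terms, size=rng.integers(1, 8), replace=False), f"D{i % 3}")
            for i in range(8)
        ]
        corpus = AnnotationCorpus.from_dict({a.admission_id: a.profile.terms for a in admissions})
        engine = SimilarityEngine(g, corpus, admissions)
        for config in enumerate_configs(default_roster()):
            S = engine.matrix(config)
            ic = engine.ic_table(config.ic) if config.ic else None
            for i, j in itertools.combinations(range(len(admissions)), 2):
                expected = profile_similarity(
                    g, config, admissions[i].profile, admissions[j].profile, ic
                )
                assert S.values[i, j] == pytest.approx(expected, abs=1e-9), config.config_id

    def test_matrix_validates_symmetry_and_finiteness(self):
        with pytest.raises(ValueError, match="symmetric"):
            SimilarityMatrix(("a", "b"), np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError, match="finite"):
            SimilarityMatrix(("a", "b"), np.array([[1.0, np.nan], [np.nan, 1.0]]))


class TestPairRecords:
    def test_count_and_shared_flags(self, toy_setting):
        g, corpus, admissions = toy_setting
        S = compute_similarity_matrix(g, corpus, admissions, SimilarityConfig("jaccard"))
        records = build_pair_records(S, admissions)
        assert len(records) == 3
        flags = {(r.i, r.j): r.shared for r in records}
        assert flags == {("A1", "A2"): True, ("A1", "A3"): False, ("A2", "A3"): False}
        assert all(r.i < r.j for r in records)

    def test_pair_count_formula(self):
        n = 40
        rng = np.random.default_rng(21)
        values = rng.random((n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        admissions = [adm(f"A{i:03d}", {"x"}, "D") for i in range(n)]
        # build a matching matrix over a tiny ontology
        S = SimilarityMatrix(tuple(a.admission_id for a in admissions), values)
        assert len(build_pair_records(S, admissions)) == n * (n - 1) // 2

    def test_duplicate_ids_rejected(self):
        values = np.ones((2, 2))
        admissions = [adm("A", {"x"}, "D"), adm("A", {"x"}, "D")]
        S = SimilarityMatrix(("A", "A"), values)
        with pytest.raises(ValueError, match="duplicate"):
            build_pair_records(S, admissions)


def rec(score, shared):
    rec.n = getattr(rec, "n", 0) + 1
    return PairRecord(f"u{rec.n}", f"v{rec.n}", score, shared)


class TestAUC:
    def test_perfect_separation(self):
        records = [rec(0.9, True), rec(0.2, False), rec(0.5, False)]
        auc, lo, hi = evaluate_auc(records)
        assert auc == 1.0
        assert 0.0 <= lo <= hi <= 1.0

    def test_all_ties_give_half(self):
        records = [rec(0.5, True), rec(0.5, False), rec(0.5, True), rec(0.5, False)]
        assert evaluate_auc(records)[0] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUC undefined"):
            evaluate_auc([rec(0.5, True), rec(0.4, True)])

    def test_matches_brute_force_with_tie_weight(self):
        rng = np.random.default_rng(22)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.random(n), 1)  # rounding forces ties
            shared = rng.random(n) < 0.4
            if shared.all() or not shared.any():
                continue
            records = [rec(float(s), bool(f)) for s, f in zip(scores, shared)]
            auc = evaluate_auc(records)[0]
            pos = scores[shared]
            neg = scores[~shared]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestRankings:
    @pytest.fixture
    def three(self):
        admissions = [adm("A1", {"x"}, "X"), adm("A2", {"x"}, "X"), adm("A3", {"x"}, "Y")]
        values = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
        return SimilarityMatrix(("A1", "A2", "A3"), values), admissions

    def test_hand_enumerated_example(self, three):
        S, admissions = three
        m = evaluate_rankings(S, admissions)
        assert m.mrr0 == pytest.approx(2 / 3)
        assert m.mrrna == pytest.approx(1.0)
        assert m.a_at_k == pytest.approx(2 / 3)
        assert m.n_matchable == 2

    def test_static_relationship(self, three):
        S, admissions = three
        m = evaluate_rankings(S, admissions)
        assert m.mrr0 == pytest.approx(m.mrrna * m.n_matchable / len(admissions), abs=1e-12)

    def test_all_nearest_neighbours_match(self):
        admissions = [adm(f"A{i}", {"x"}, "X") for i in range(4)]
        values = np.full((4, 4), 0.5)
        np.fill_diagonal(values, 1.0)
        m = evaluate_rankings(SimilarityMatrix(tuple(a.admission_id for a in admissions), values), admissions)
        assert m.mrr0 == m.mrrna == m.a_at_k == 1.0

    def test_no_shared_diagnoses_errors(self):
        admissions = [adm("A1", {"x"}, "X"), adm("A2", {"x"}, "Y")]
        values = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValueError, match="no admission"):
            evaluate_rankings(SimilarityMatrix(("A1", "A2"), values), admissions)

    def test_invalid_cutoff_rejected(self, three):
        S, admissions = three
        with pytest.raises(ValueError, match="cutoff"):
            evaluate_rankings(S, admissions, k=0)

    def test_tie_policies(self):
        # A1's neighbours A2 (non-match) and A3 (match) tie at 0.5
        admissions = [adm("A1", {"x"}, "X"), adm("A2", {"x"}, "Y"), adm("A3", {"x"}, "X")]
        values = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.1], [0.5, 0.1, 1.0]])
        S = SimilarityMatrix(("A1", "A2", "A3"), values)
        rr1 = {
            policy: evaluate_rankings(S, admissions, tie_policy=policy).mrr0
            for policy in ("optimistic", "pessimistic", "mid", "id")
        }
        # per-admission first-match ranks for A1: opt 1, pess 2, mid 1.5, id 2 (A2 < A3)
        assert rr1["optimistic"] > rr1["mid"] > rr1["pessimistic"]
        assert rr1["id"] == rr1["pessimistic"]

    def test_cutoff_capped_at_n_minus_one(self):
        admissions = [adm("A1", {"x"}, "X"), adm("A2", {"x"}, "X")]
        values = np.array([[1.0, 0.5], [0.5, 1.0]])
        m = evaluate_rankings(SimilarityMatrix(("A1", "A2"), values), admissions, k=10)
        assert m.a_at_k == 1.0


class TestCorrelation:
    def make_results(self, aucs, a10s):
        out = []
        for i, (u, a) in enumerate(zip(aucs, a10s)):
            out.append(
                EvaluationResult(
                    config=SimilarityConfig(f"m{i}"),
                    auc=u, auc_lo=u, auc_hi=u,
                    mrr0=0.1, mrrna=0.2, a10=a, a10_lo=a, a10_hi=a,
                    n=10, n_matchable=5,
                )
            )
        return out

    def test_perfect_and_inverse_correlation(self):
        res = self.make_results([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert correlate_metrics(res, "auc", "a10")[0] == pytest.approx(1.0)
        res = self.make_results([0.5, 0.6, 0.7], [0.7, 0.6, 0.5])
        assert correlate_metrics(res, "auc", "a10")[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(23)
        x, y = rng.random(10), rng.random(10)
        res = self.make_results(x, y)
        r, _ = correlate_metrics(res, "auc", "a10")
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        expected = cov / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            correlate_metrics(self.make_results([0.5], [0.5]), "auc", "a10")
        with pytest.raises(ValueError, match="constant"):
            correlate_metrics(self.make_results([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]), "auc", "a10")


class TestRunBenchmark:
    def test_single_config_matches_stage_composition(self, toy_setting):
        g, corpus, admissions = toy_setting
        config = SimilarityConfig("jaccard")
        [res] = run_benchmark(g, corpus, admissions, [config])
        S = compute_similarity_matrix(g, corpus, admissions, config)
        records = build_pair_records(S, admissions)
        auc, lo, hi = evaluate_auc(records)
        m = evaluate_rankings(S, admissions)
        assert (res.auc, res.auc_lo, res.auc_hi) == (auc, lo, hi)
        assert (res.mrr0, res.mrrna, res.a10) == (m.mrr0, m.mrrna, m.a_at_k)
        assert res.n == 3 and res.n_matchable == 2 and res.status == "ok"

    def test_empty_config_list(self, toy_setting, tmp_path):
        g, corpus, admissions = toy_setting
        assert run_benchmark(g, corpus, admissions, [], out_dir=tmp_path) == []
        header = (tmp_path / "results.tsv").read_text().splitlines()
        assert header == ["\t".join(RESULT_COLUMNS)]

    def test_failing_config_isolated(self, toy_setting, tmp_path):
        g, corpus, admissions = toy_setting
        configs = [SimilarityConfig("gic"), SimilarityConfig("jaccard")]  # gic lacks IC
        results = run_benchmark(g, corpus, admissions, configs, out_dir=tmp_path)
        assert [r.status for r in results] == ["failed", "ok"]
        rows = (tmp_path / "results.tsv").read_text().splitlines()
        assert len(rows) == 3
        assert "failed" in rows[1] and rows[2].split("\t")[-1] == "ok"

    def test_summaries_written(self, toy_setting, tmp_path):
        g, corpus, admissions = toy_setting
        configs = [SimilarityConfig("jaccard"), SimilarityConfig("ui"), SimilarityConfig("max", "rada")]
        run_benchmark(g, corpus, admissions, configs, out_dir=tmp_path)
        by_gw = pd.read_csv(tmp_path / "summary_by_groupwise.tsv", sep="\t")
        assert set(by_gw["groupwise"]) == {"jaccard", "ui", "max"}
        assert {"auc", "mrrna", "mrr0", "a10"} <= set(by_gw.columns)
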