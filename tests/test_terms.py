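import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serialcox import (
    Cohort,
    NGramStats,
    UndefinedResultError,
    cluster_ngrams,
    differential_ngrams,
    edit_distance,
    embed_patients,
    extract_ngrams,
    logrank_test,
    normalized_edit_distance,
    project_2d,
    term_survival_test,
)
from tests.conftest import make_record


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestExtractNgrams:
    def test_bigram_window_enumeration(self):
        cohort = Cohort((make_record("p", ["a b c"], 5.0, 0),))
        grams = extract_ngrams(cohort, 2, 2)
        assert set(grams) == {"a b", "b c"}

    def test_patient_level_dedup(self):
        cohort = Cohort(
            (make_record("p", ["tumour seen here", "tumour seen again"], 5.0, 0),)
        )
        assert extract_ngrams(cohort, 2, 2)["tumour seen"] == {"p"}

    def test_counts_match_brute_force_recount(self, small_synth):
        sub = Cohort(small_synth.records[:20], name="sub")
        presence = extract_ngrams(sub, 1, 3)
        from serialcox.encoder import tokenize

        rng = np.random.default_rng(0)
        grams = rng.choice(sorted(presence), size=15, replace=False)
        for gram in grams:
            want = set()
            k = len(gram.split())
            for rec in sub:
                for rep in rec.reports:
                    toks = tokenize(rep.text).tokens
                    if any(" ".join(toks[i : i + k]) == gram
                           for i in range(len(toks) - k + 1)):
                        want.add(rec.patient_id)
            assert presence[gram] == want

    def test_bad_range_rejected(self, small_synth):
        with pytest.raises(ValueError):
            extract_ngrams(small_synth, 3, 2)


class TestDifferentialNgrams:
    def test_ubiquitous_ngram_not_significant(self):
        presence = {"everywhere": {f"p{i}" for i in range(20)}}
        high = [f"p{i}" for i in range(10)]
        low = [f"p{i}" for i in range(10, 20)]
        assert differential_ngrams(presence, high, low) == []

    def test_strong_imbalance_significant_high_risk(self):
        from scipy.stats import hypergeom

        high = [f"h{i}" for i in range(50)]
        low = [f"l{i}" for i in range(50)]
        presence = {"bad sign": set(high[:30])}
        out = differential_ngrams(presence, high, low, min_patients=5)
        assert len(out) == 1
        s = out[0]
        assert s.direction == "high-risk"
        assert s.count_high == 30 and s.count_low == 0
        # balanced groups: the two-sided Fisher p is twice the upper
        # hypergeometric tail P(X >= 30)
        p_oracle = 2 * hypergeom.sf(29, 100, 30, 50)
        assert s.p_value == pytest.approx(p_oracle, rel=1e-6)

    def test_null_labels_rarely_significant(self, small_synth):
        presence = extract_ngrams(small_synth, 1, 2)
        ids = small_synth.patient_ids
        rng = np.random.default_rng(1)
        fracs = []
        for _ in range(5):
            perm = rng.permutation(ids)
            out = differential_ngrams(presence, list(perm[:60]), list(perm[60:]))
            n_tested = sum(1 for g in presence.values() if len(g) >= 5)
            fracs.append(len(out) / max(n_tested, 1))
        assert np.mean(fracs) <= 0.05 + 3 * 0.05 / np.sqrt(len(fracs))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            differential_ngrams({}, ["a"], ["a"])


class TestEditDistance:
    def test_identical_strings(self):
        assert edit_distance("crm threatening", "crm threatening") == 0

    def test_plural_is_one_edit(self):
        assert edit_distance("enlarged lymph node", "enlarged lymph nodes") == 1

    @given(st.text(max_size=12), st.text(max_size=12), st.text(max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metric_axioms_and_dp_oracle(self, a, b, c):
        dab = edit_distance(a, b)
        assert dab == dp_levenshtein(a, b)
        assert dab == edit_distance(b, a)
        assert dab <= edit_distance(a, c) + edit_distance(c, b)
        assert (dab == 0) == (a == b)


def _stats(ngram, ch=10, cl=0, p=0.01):
    return NGramStats(ngram, ch, cl, p, p, "high-risk")


class TestClusterNgrams:
    def test_threshold_zero_keeps_all_apart(self):
        stats = [_stats(g) for g in ("alpha", "beta", "gamma")]
        clusters = cluster_ngrams(stats, threshold=0.0)
        assert len(clusters) == 3

    def test_near_duplicates_merge(self):
        stats = [_stats("crm threatening", ch=12), _stats("crm threatenings", ch=9)]
        clusters = cluster_ngrams(stats, threshold=0.3)
        assert len(clusters) == 1
        assert clusters[0].representative.ngram == "crm threatening"

    def test_equal_support_prefers_most_specific_phrase(self):
        stats = [_stats("enlarged lymph", ch=10), _stats("enlarged lymph node", ch=10)]
        clusters = cluster_ngrams(stats, threshold=0.3)
        assert len(clusters) == 1
        assert clusters[0].representative.ngram == "enlarged lymph node"

    def test_matches_union_find_over_threshold_graph(self):
        rng = np.random.default_rng(2)
        vocab = ["mesorectal", "mesorectum", "fat", "infiltration", "node", "nodes"]
        stats = [
            _stats(" ".join(rng.choice(vocab, size=rng.integers(1, 3))),
                   ch=int(rng.integers(1, 20)))
            for _ in range(15)
        ]
        # dedupe names (identical strings are distance 0 anyway)
        seen = {}
        stats = [seen.setdefault(s.ngram, s) for s in stats]
        stats = list(dict.fromkeys(stats))
        threshold = 0.4
        clusters = cluster_ngrams(stats, threshold=threshold)
        # union-find oracle
        parent = list(range(len(stats)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(stats)):
            for j in range(i + 1, len(stats)):
                if normalized_edit_distance(stats[i].ngram, stats[j].ngram) <= threshold:
                    parent[find(i)] = find(j)
        oracle = {}
        for i, s in enumerate(stats):
            oracle.setdefault(find(i), set()).add(s.ngram)
        got = {frozenset(m.ngram for m in c.members) for c in clusters}
        assert got == {frozenset(v) for v in oracle.values()}

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cluster_ngrams([_stats("a")], threshold=1.5)


class TestTermSurvival:
    def test_term_in_all_patients_is_degenerate(self, tiny_cohort):
        recs = tuple(
            make_record(f"p{i}", ["shared token here"], 10.0 + i, 1) for i in range(4)
        )
        with pytest.raises(UndefinedResultError):
            term_survival_test(Cohort(recs), "shared")

    def test_equals_logrank_on_induced_grouping(self, tiny_cohort):
        chi2, p, sizes = term_survival_test(tiny_cohort, "t3")
        with_t = [r for r in tiny_cohort
                  if any("t3" in rep.text.lower().split() for rep in r.reports)]
        without = [r for r in tiny_cohort if r not in with_t]
        ref = logrank_test(
            [r.outcome.time for r in with_t], [r.outcome.event for r in with_t],
            [r.outcome.time for r in without], [r.outcome.event for r in without],
        )
        assert (chi2, p) == pytest.approx(ref)
        assert sizes["with_term"] == len(with_t)

    def test_planted_term_detected_in_most_seeds(self):
        """Log-rank on a strong planted term reaches p < 0.05 reliably."""
        from serialcox import RiskTerm, SynthConfig, generate_cohort

        hits = 0
        seeds = 10
        for seed in range(seeds):
            cfg = SynthConfig(
                n_patients=1000, seed=seed,
                risk_terms=[RiskTerm("crm threatening", 1.5, 0.5)],
            )
            cohort = generate_cohort(cfg)
            _, p, _ = term_survival_test(cohort, "crm threatening")
            hits += p < 0.05
        assert hits >= 9


class TestEmbedAndProject:
    def test_single_report_patients_equal_under_both_flags(self, small_fit):
        res, train, _ = small_fit
        sub = Cohort(tuple(r for r in train if r.n_reports == 1)[:5], name="s")
        a = embed_patients(res, sub, first_report_only=True)
        b = embed_patients(res, sub, first_report_only=False)
        for pid in a:
            np.testing.assert_array_equal(a[pid], b[pid])

    def test_embedding_is_gru_of_encoded_reports(self, small_fit):
        from serialcox import aggregate_serial, encode_report

        res, train, _ = small_fit
        rec = train[0]
        emb = embed_patients(res, Cohort((rec,), name="one"),
                             first_report_only=False)[rec.patient_id]
        pooled = [encode_report(rep, res.backbone, res.attention) for rep in rec.reports]
        np.testing.assert_allclose(emb, aggregate_serial(pooled, res.gru), atol=1e-10)

    def test_projection_deterministic_and_complete(self, small_fit):
        res, train, _ = small_fit
        vecs = embed_patients(res, train)
        for method in ("pca", "tsne"):
            xy1 = project_2d(vecs, method=method, seed=4)
            xy2 = project_2d(vecs, method=method, seed=4)
            assert xy1.keys() == vecs.keys()
            assert xy1 == xy2

    def test_identical_vectors_identical_pca_coordinates(self):
        v = {"a": np.ones(4), "b": np.ones(4)}
        xy = project_2d(v, method="pca")
        assert xy["a"] == pytest.approx(xy["b"])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            project_2d({"a": np.ones(3), "b": np.zeros(3)}, method="umap2")
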