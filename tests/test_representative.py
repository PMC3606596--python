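import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txcurate.annotate import Annotation
from txcurate.io_formats import ProteinHit, TranscriptRecord
from txcurate.representative import (
    AnnotationCluster,
    cluster_by_annotation,
    curate_redundancy,
    pairwise_identity,
    score_algorithm1,
    select_representatives,
)


def hit(qid="q", qcov=100.0, scov=100.0, sim=100.0, ev=1.0, ss=1, se=100,
        acc="s1", desc="d"):
    return ProteinHit(qid, acc, desc, qcov, scov, sim, ev, ss, se)


class TestScore:
    def test_all_unity_factors(self):
        s = score_algorithm1(hit(ev=1.0), depth=1.0)
        assert s.value == 1.0

    def test_worked_product(self):
        s = score_algorithm1(hit(qcov=50, scov=80, sim=90, ev=1e-10), depth=22.2)
        assert s.value == pytest.approx(0.5 * 0.8 * 0.9 * 1e10 * 22.2)
        assert s.value == pytest.approx(7.992e10)

    def test_zero_evalue_clamped_to_floor(self):
        s = score_algorithm1(hit(ev=0.0), depth=1.0)
        assert s.value == pytest.approx(1e180)

    def test_depth_below_one_rejected(self):
        with pytest.raises(ValueError):
            score_algorithm1(hit(), depth=0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(1.0, 99.0), st.floats(1.0, 99.0), st.floats(1.0, 99.0),
        st.floats(1e-150, 1.0), st.floats(1.0, 100.0),
    )
    def test_monotone_in_every_factor(self, qcov, scov, sim, ev, depth):
        base = score_algorithm1(hit(qcov=qcov, scov=scov, sim=sim, ev=ev), depth).value
        assert score_algorithm1(hit(qcov=qcov + 1, scov=scov, sim=sim, ev=ev), depth).value > base
        assert score_algorithm1(hit(qcov=qcov, scov=scov + 1, sim=sim, ev=ev), depth).value > base
        assert score_algorithm1(hit(qcov=qcov, scov=scov, sim=sim + 1, ev=ev), depth).value > base
        assert score_algorithm1(hit(qcov=qcov, scov=scov, sim=sim, ev=ev), depth + 1).value > base
        assert score_algorithm1(hit(qcov=qcov, scov=scov, sim=sim, ev=ev * 2), depth).value <= base


class TestIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGTGG", "ACGTACGTGG") == 100.0

    def test_exact_fragment_scores_full_identity(self):
        rng = np.random.default_rng(0)
        parent = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert pairwise_identity(parent, parent[25:75]) == 100.0

    def test_substitutions_lower_identity(self):
        rng = np.random.default_rng(1)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        b = list(a)
        for pos in rng.choice(100, size=10, replace=False):
            b[pos] = "ACGT".replace(a[pos], "")[int(rng.integers(0, 3))]
        assert pairwise_identity(a, "".join(b)) == pytest.approx(90.0, abs=1.0)

    def test_symmetric(self):
        a, b = "ACGTACGTACGTAAA", "ACGTTCGTACGTA"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)


def _annotated(records, desc_of, intervals=None):
    intervals = intervals or {}
    out = {}
    for r in records:
        ss, se = intervals.get(r.id, (1, 100))
        h = hit(qid=r.id, desc=desc_of[r.id], ss=ss, se=se, ev=1e-30)
        out[r.id] = Annotation(r.id, f"acc_{r.id}", desc_of[r.id], h)
    return out


class TestClustering:
    def test_identical_same_description_cluster_together(self):
        recs = [TranscriptRecord("a", "ACGT" * 30), TranscriptRecord("b", "ACGT" * 30)]
        ann = _annotated(recs, {"a": "kinase", "b": "kinase"})
        clusters = cluster_by_annotation(recs, ann)
        assert len(clusters) == 1 and clusters[0].member_ids == {"a", "b"}

    def test_identical_different_description_stay_apart(self):
        recs = [TranscriptRecord("a", "ACGT" * 30), TranscriptRecord("b", "ACGT" * 30)]
        ann = _annotated(recs, {"a": "kinase", "b": "phosphatase"})
        assert len(cluster_by_annotation(recs, ann)) == 2

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(2)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))

        def mutate(seq, n, seed):
            r = np.random.default_rng(seed)
            s = list(seq)
            for pos in r.choice(len(s), size=n, replace=False):
                s[pos] = "ACGT".replace(s[pos], "")[int(r.integers(0, 3))]
            return "".join(s)

        a = TranscriptRecord("a", base)
        b = TranscriptRecord("b", mutate(base, 6, 5))        # ~97% to a
        c = TranscriptRecord("c", mutate(b.seq, 6, 6))       # ~97% to b, ~94% to a
        assert pairwise_identity(a, b) > 95
        assert pairwise_identity(b, c) > 95
        ann = _annotated([a, b, c], {x: "kinase" for x in "abc"})
        clusters = cluster_by_annotation([a, b, c], ann)
        assert len(clusters) == 1 and clusters[0].member_ids == {"a", "b", "c"}

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(8):
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 150))
            recs.append(TranscriptRecord(f"r{i}", seq))
        desc = {r.id: ("kinase" if i % 2 else "ligase") for i, r in enumerate(recs)}
        ann = _annotated(recs, desc)
        forward = cluster_by_annotation(recs, ann)
        backward = cluster_by_annotation(list(reversed(recs)), ann)
        as_sets = lambda cs: sorted(tuple(sorted(c.member_ids)) for c in cs)
        assert as_sets(forward) == as_sets(backward)
        all_ids = [i for c in forward for i in c.member_ids]
        assert sorted(all_ids) == sorted(desc)  # a partition


class TestSelection:
    def make_cluster(self, intervals):
        return AnnotationCluster(
            description="kinase",
            member_ids=frozenset(intervals),
            retained_ids=frozenset(intervals),
            prot_intervals=intervals,
        )

    def scores(self, values, scov=50.0):
        return {
            k: score_algorithm1(hit(qid=k, scov=scov, ev=1.0), depth=v)
            for k, v in values.items()
        }

    def test_nested_intervals_keep_top_scorer_only(self):
        cl = self.make_cluster({"a": (1, 100), "b": (20, 60)})
        kept = select_representatives(cl, self.scores({"a": 10.0, "b": 5.0}))
        assert kept == {"a"}

    def test_disjoint_intervals_both_retained(self):
        cl = self.make_cluster({"a": (1, 100), "b": (150, 250)})
        kept = select_representatives(cl, self.scores({"a": 10.0, "b": 5.0}))
        assert kept == {"a", "b"}

    def test_singleton_cluster_kept(self):
        cl = self.make_cluster({"a": (1, 100)})
        assert select_representatives(cl, self.scores({"a": 2.0})) == {"a"}

    def test_complete_sequence_always_retained(self):
        cl = self.make_cluster({"a": (1, 100), "b": (1, 100)})
        scores = {
            "a": score_algorithm1(hit(qid="a", scov=50.0, ev=1.0), 10.0),
            "b": score_algorithm1(hit(qid="b", scov=97.0, ev=1.0), 1.0),
        }
        assert select_representatives(cl, scores) == {"a", "b"}

    def test_never_empty_and_overlap_bound(self):
        rng = np.random.default_rng(4)
        for trial in range(20):
            n = int(rng.integers(1, 7))
            intervals = {}
            values = {}
            for i in range(n):
                lo = int(rng.integers(1, 300))
                hi = lo + int(rng.integers(10, 200))
                intervals[f"m{i}"] = (lo, hi)
                values[f"m{i}"] = float(rng.uniform(1, 50))
            cl = self.make_cluster(intervals)
            kept = select_representatives(cl, self.scores(values))
            assert kept
            from txcurate.representative import _overlap_fraction

            for a in kept:
                for b in kept:
                    if a < b:
                        assert _overlap_fraction(intervals[a], intervals[b]) < 0.2


def test_curate_redundancy_end_to_end(small_transcriptome):
    from txcurate.simulate import fragmentize, make_hits

    records, truths = small_transcriptome
    parent = records[0]
    frags, ftruths = fragmentize(parent, truths[parent.id], k_fragments=4,
                                 mutation_rate=0.0, seed=9)
    pool = frags
    truth_map = {t.gene_id: t for t in ftruths}
    hits = make_hits(truth_map)
    ann = {
        h.query_id: Annotation(h.query_id, h.subject_accession, h.description, h)
        for h in hits
    }
    clusters, kept = curate_redundancy(pool, ann)
    assert kept  # never empty
    assert all(cl.retained_ids <= cl.member_ids for cl in clusters)
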