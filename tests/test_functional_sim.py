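"""PSB and SemFunSim: pair measures, best-match average, profiles."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsim import GeneNetwork, bma_setsim, gene_funsim, psb, semfunsim
from dsim.functional_sim import PSBScorer, SemFunSimScorer


def make_net(edges):
    net = GeneNetwork()
    for a, b, s in edges:
        net.edges[frozenset((a, b))] = s
    return net


class TestGeneFunsim:
    def test_identity_is_one(self):
        net = make_net([("a", "b", 1.0), ("b", "c", 2.0)])
        assert gene_funsim("a", "a", net) == 1.0

    def test_absent_pair_is_zero(self):
        net = make_net([("a", "b", 1.0), ("b", "c", 2.0)])
        assert gene_funsim("a", "c", net) == 0.0

    def test_minmax_normalization(self):
        net = make_net([("a", "b", 1.5), ("b", "c", 0.5), ("c", "d", 3.0)])
        assert gene_funsim("a", "b", net) == pytest.approx(0.4)  # (1.5-0.5)/2.5
        assert gene_funsim("b", "c", net) == 0.0
        assert gene_funsim("c", "d", net) == 1.0

    def test_degenerate_network_maps_edges_to_one(self):
        net = make_net([("a", "b", 2.0), ("b", "c", 2.0)])
        assert gene_funsim("a", "b", net) == 1.0
        assert gene_funsim("a", "c", net) == 0.0


class TestBMA:
    def test_identical_sets_score_one(self):
        net = make_net([("a", "b", 1.0)])
        sim = lambda g, h: gene_funsim(g, h, net)
        assert bma_setsim({"a", "b"}, {"a", "b"}, sim) == pytest.approx(1.0)

    def test_disjoint_unconnected_sets_score_zero(self):
        net = make_net([("a", "b", 1.0)])
        sim = lambda g, h: gene_funsim(g, h, net)
        assert bma_setsim({"a"}, {"c"}, sim) == 0.0

    def test_hand_value_two_thirds(self):
        # G1={a}, G2={b,c}; sim(a,b)=0.4, sim(a,c)=0.8
        table = {frozenset(("a", "b")): 0.4, frozenset(("a", "c")): 0.8}
        sim = lambda g, h: 1.0 if g == h else table.get(frozenset((g, h)), 0.0)
        value = bma_setsim({"a"}, {"b", "c"}, sim)
        assert value == pytest.approx((0.8 + (0.4 + 0.8)) / 3)
        assert value == pytest.approx(0.666667, abs=1e-6)

    def test_empty_set_yields_none(self):
        assert bma_setsim(set(), {"a"}, lambda g, h: 1.0) is None
        assert bma_setsim({"a"}, set(), lambda g, h: 1.0) is None

    def test_symmetry_random(self):
        rng = random.Random(7)
        genes = [f"g{i}" for i in range(12)]
        table = {
            frozenset(p): rng.random()
            for p in itertools.combinations(genes, 2)
        }
        sim = lambda g, h: 1.0 if g == h else table[frozenset((g, h))]
        for _ in range(50):
            G1 = set(rng.sample(genes, rng.randint(1, 6)))
            G2 = set(rng.sample(genes, rng.randint(1, 6)))
            assert bma_setsim(G1, G2, sim) == pytest.approx(
                bma_setsim(G2, G1, sim)
            )

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        g1=st.sets(st.integers(0, 9), min_size=1, max_size=5),
        g2=st.sets(st.integers(0, 9), min_size=1, max_size=5),
        extra=st.integers(10, 14),
        seed=st.integers(0, 2**16),
    )
    def test_adding_an_improving_gene_never_hurts_forward_sum(
        self, g1, g2, extra, seed
    ):
        # enlarging G2 can only raise each row max over G1, so the
        # sum_{g in G1} max_{h in G2} term is monotone
        def sim(a, b):
            if a == b:
                return 1.0
            return (hash((min(a, b), max(a, b), seed)) % 1000) / 1000.0

        fwd_before = sum(max(sim(g, h) for h in g2) for g in g1)
        g2_big = g2 | {extra}
        fwd_after = sum(max(sim(g, h) for h in g2_big) for g in g1)
        assert fwd_after >= fwd_before - 1e-12

    def test_brute_matrix_oracle_on_bundle(self, bundle):
        """BMA equals an explicit |G1|x|G2| pair-matrix computation."""
        b, manifest = bundle
        diseases = manifest["diseases"][:8]
        for d1, d2 in itertools.combinations(diseases, 2):
            G1, G2 = sorted(b.corpus.genes(d1)), sorted(b.corpus.genes(d2))
            matrix = [[gene_funsim(g, h, b.network) for h in G2] for g in G1]
            expected = (
                sum(max(row) for row in matrix)
                + sum(max(col) for col in zip(*matrix))
            ) / (len(G1) + len(G2))
            assert semfunsim(d1, d2, b.corpus, b.network) == pytest.approx(
                expected
            )


class TestDiseaseMeasures:
    def test_self_similarity_one(self, bundle):
        b, manifest = bundle
        for d in manifest["diseases"][:5]:
            assert semfunsim(d, d, b.corpus, b.network) == pytest.approx(1.0)
            assert psb(d, d, b.corpus, b.bp) == pytest.approx(1.0)

    def test_symmetry_and_range(self, bundle):
        b, manifest = bundle
        rng = random.Random(99)
        diseases = manifest["diseases"]
        for _ in range(100):
            d1, d2 = rng.choice(diseases), rng.choice(diseases)
            s = semfunsim(d1, d2, b.corpus, b.network)
            p = psb(d1, d2, b.corpus, b.bp)
            assert s == pytest.approx(semfunsim(d2, d1, b.corpus, b.network))
            assert p == pytest.approx(psb(d2, d1, b.corpus, b.bp))
            assert 0.0 <= s <= 1.0 and 0.0 <= p <= 1.0

    def test_missing_inputs_yield_null_not_zero(self, bundle):
        # a disease without genes gets an undefined (None) score, which
        # downstream becomes a null result cell rather than a zero
        b, manifest = bundle
        d = manifest["diseases"][0]
        empty_corpus_genes = set()
        assert bma_setsim(empty_corpus_genes, b.corpus.genes(d),
                          lambda a, c: 0.0) is None
        assert psb("DOID:9999998", d, b.corpus, b.bp) is None

    def test_psb_unit_weight_jaccard(self):
        # unit weights, |intersection| = 2, |union| = 5 -> 0.4
        from dsim.functional_sim import DiseaseBPProfile, weighted_jaccard

        p1 = DiseaseBPProfile("d1", {t: 1.0 for t in "abc"})
        p2 = DiseaseBPProfile("d2", {t: 1.0 for t in "bcde"})
        assert weighted_jaccard(p1, p2) == pytest.approx(2 / 5)

    def test_psb_disjoint_profiles_zero(self):
        from dsim.functional_sim import DiseaseBPProfile, weighted_jaccard

        p1 = DiseaseBPProfile("d1", {"a": 1.0})
        p2 = DiseaseBPProfile("d2", {"b": 1.0})
        assert weighted_jaccard(p1, p2) == 0.0

    def test_psb_scorer_idf_downweights_ubiquitous_terms(self, bundle):
        b, manifest = bundle
        diseases = manifest["diseases"]
        unit = PSBScorer(b.corpus, b.bp, diseases, weight="unit")
        idf = PSBScorer(b.corpus, b.bp, diseases, weight="idf")
        d1, d2 = manifest["similar_pairs"][0]
        u, i = unit(d1, d2), idf(d1, d2)
        assert 0.0 <= i <= 1.0 and 0.0 <= u <= 1.0
        assert unit(d1, d1) == pytest.approx(1.0)
        assert idf(d1, d1) == pytest.approx(1.0)

    def test_scorer_composition_matches_functions(self, bundle):
        b, manifest = bundle
        d1, d2 = manifest["similar_pairs"][0]
        assert SemFunSimScorer(b.corpus, b.network)(d1, d2) == pytest.approx(
            semfunsim(d1, d2, b.corpus, b.network)
        )
        assert PSBScorer(b.corpus, b.bp, manifest["diseases"])(
            d1, d2
        ) == pytest.approx(psb(d1, d2, b.corpus, b.bp))
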