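"""Seed-match prediction, tool consensus and gene-set enrichment."""

import numpy as np
import pytest

from srnakit.mapping import reverse_complement
from srnakit.targets import (
    PredictionSet, benjamini_hochberg, consensus_targets, enrich,
    hypergeom_upper_tail, make_synthetic_target_data, pseudo_tool_suite,
    seed_match_predict,
)
from oracles import brute_force_consensus, hypergeom_tail_by_enumeration


def test_seed_site_detected_and_absent():
    mature = "UAGCUUAUCAGACUGAUGUUGA"
    site = reverse_complement(mature[1:8].replace("U", "T"))
    utrs = {"hit": "AAAA" + site + "CCCC", "miss": "A" * 30}
    predicted = seed_match_predict({"mir": mature}, utrs)
    assert ("mir", "hit") in predicted.pairs
    assert all(gene != "miss" for _, gene in predicted.pairs)


def test_planted_sites_recovered_exactly():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    mature = "".join(bases[rng.integers(0, 4, 22)])
    site = reverse_complement(mature[1:8])
    utrs = {}
    for i in range(50):
        utr = "".join(bases[rng.integers(0, 4, 60)])
        # reject UTRs already containing the site by chance
        while site in utr:
            utr = "".join(bases[rng.integers(0, 4, 60)])
        pos = int(rng.integers(0, 54))
        utrs[f"g{i}"] = utr[:pos] + site + utr[pos + 7 :]
    for i in range(30):
        utr = "".join(bases[rng.integers(0, 4, 60)])
        while site in utr:
            utr = "".join(bases[rng.integers(0, 4, 60)])
        utrs[f"bg{i}"] = utr
    predicted = seed_match_predict({"mir": mature}, utrs)
    assert {g for _, g in predicted.pairs} == {f"g{i}" for i in range(50)}


def test_consensus_keeps_three_of_four_drops_two_of_four():
    sets = [
        PredictionSet.from_pairs("t1", {("m", "g1"), ("m", "g2")}),
        PredictionSet.from_pairs("t2", {("m", "g1"), ("m", "g2")}),
        PredictionSet.from_pairs("t3", {("m", "g1")}),
        PredictionSet.from_pairs("t4", set()),
    ]
    consensus = consensus_targets(sets)
    assert list(consensus["gene"]) == ["g1"]
    assert consensus.iloc[0]["support"] == 3


def test_duplicate_tool_labels_rejected():
    sets = [PredictionSet.from_pairs("t", set()), PredictionSet.from_pairs("t", set())]
    with pytest.raises(ValueError, match="duplicate"):
        consensus_targets(sets)


def test_consensus_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(1)
    mirnas = [f"m{i}" for i in range(6)]
    genes = [f"g{i}" for i in range(25)]
    for _ in range(10):
        sets = {}
        for t in range(4):
            n = int(rng.integers(5, 40))
            sets[f"tool{t}"] = {
                (mirnas[rng.integers(6)], genes[rng.integers(25)]) for _ in range(n)
            }
        expected = brute_force_consensus(sets, 3)
        got = consensus_targets(
            [PredictionSet.from_pairs(t, p) for t, p in sets.items()], 3
        )
        assert {(r.mirna, r.gene): r.support for r in got.itertuples()} == expected


def test_consensus_monotone_in_added_sets():
    rng = np.random.default_rng(2)
    base = [
        PredictionSet.from_pairs(f"tool{t}", {("m", f"g{rng.integers(8)}") for _ in range(10)})
        for t in range(3)
    ]
    before = consensus_targets(base, 3)
    extra = PredictionSet.from_pairs("tool3", {("m", f"g{i}") for i in range(8)})
    after = consensus_targets(base + [extra], 3)
    before_pairs = set(zip(before["mirna"], before["gene"]))
    after_pairs = set(zip(after["mirna"], after["gene"]))
    assert before_pairs <= after_pairs


def test_hypergeometric_example_and_enumeration_oracle():
    # N=20, K=4, n=5, k>=3: C(4,3)C(16,2)/C(20,5) + C(4,4)C(16,1)/C(20,5)
    p = hypergeom_upper_tail(3, 20, 4, 5)
    assert p == pytest.approx(496 / 15504, rel=1e-12)
    assert p == pytest.approx(0.03199, abs=5e-6)
    assert p == pytest.approx(hypergeom_tail_by_enumeration(3, 20, 4, 5), rel=1e-9)
    for k, N, K, n in [(2, 12, 5, 4), (1, 10, 3, 3), (4, 15, 6, 7)]:
        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
            hypergeom_tail_by_enumeration(k, N, K, n), rel=1e-9
        )


def test_zero_overlap_tail_probability_is_one():
    assert hypergeom_upper_tail(0, 20, 4, 5) == 1.0


def test_bh_adjustment_hand_example_and_properties():
    adjusted = benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
    assert adjusted == pytest.approx([0.03, 0.03, 0.03])
    rng = np.random.default_rng(3)
    p = rng.uniform(size=40)
    adj = benjamini_hochberg(p)
    assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()
    # step-up adjustment preserves the significance ordering
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
    # idempotent on fixed points (constant vectors, and any twice-adjusted
    # vector once the step-up has stabilised)
    assert benjamini_hochberg(adjusted) == pytest.approx(adjusted)
    stable = adj.copy()
    for _ in range(40):
        nxt = benjamini_hochberg(stable)
        if np.allclose(nxt, stable):
            break
        stable = nxt
    assert benjamini_hochberg(stable) == pytest.approx(stable)


def test_enrichment_flags_planted_pathway_only():
    rng = np.random.default_rng(4)
    bases = np.array(list("ACGT"))
    mirnas = {f"m{i}": "".join(bases[rng.integers(0, 4, 22)]) for i in range(30)}
    utrs, gene_sets = make_synthetic_target_data(mirnas, seed=4)
    consensus = consensus_targets(pseudo_tool_suite(mirnas, utrs))
    result = enrich(set(consensus["gene"]), gene_sets, set(utrs))
    significant = set(result.loc[result["significant"], "gene_set"])
    assert significant == {"pathway-planted"}
    assert (result["adjusted_p"] >= result["p_value"] - 1e-12).all()


def test_enrichment_requires_query_within_universe():
    with pytest.raises(ValueError, match="universe"):
        enrich({"x"}, {"s": {"a"}}, {"a", "b"})
    with pytest.raises(ValueError, match="empty"):
        enrich(set(), {"s": {"a"}}, set())
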