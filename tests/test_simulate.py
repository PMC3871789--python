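"""Birth–death simulator: reproducibility, pruning, calibration, Eq-style
event costs derived from true histories."""

import math
import random

import numpy as np
import pytest

from dtlrec.simulate import (SimulationParams, UndefinedCostsError,
                             derive_event_costs, perturb_nni, prune_extinct,
                             simulate_family)
from dtlrec.trees import Node, parse_dated_species_tree
from dtlrec.evaluate import clade_set, rf_distance
from helpers import node_from_nested, oracle_prune, random_topology

FIVE_SPECIES = "(((A:1,B:1):1,C:2):1,(D:2,E:2):1);"


def free_params(**kw):
    base = dict(height=None, size_bounds=(1, 10**6), max_dup_transfer=10**6,
                max_retries=0)
    base.update(kw)
    return SimulationParams(**base)


def species_clades(gene_tree):
    """Clades of a gene tree with leaves renamed to their species."""
    out = set()
    for n in gene_tree.postorder():
        if n.children and n.parent is not None:
            out.add(frozenset(gene_tree.species_of[l.name]
                              for l in n.leaves()))
    return out


class TestProcess:
    @pytest.mark.parametrize("seed", range(5))
    def test_zero_rates_reproduce_the_species_tree(self, seed):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = free_params(loss_rate=0.0, dup_rate=0.0, trans_rate=0.0)
        h = simulate_family(S, p, seed=seed)
        assert h.ok
        assert (h.n_duplications, h.n_transfers, h.n_losses) == (0, 0, 0)
        assert len(h.true_tree.leaves()) == len(S.leaves)
        # the gene tree, read at the species level, has the species topology
        want = {n.leaf_names() for n in S.nodes
                if n.children and n.parent is not None}
        assert species_clades(h.true_tree) == want
        assert all(e.kind == "speciation" for e in h.events)

    def test_overwhelming_loss_goes_extinct(self):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = free_params(loss_rate=20.0)
        flags = [simulate_family(S, p, seed=s).flags for s in range(10)]
        assert all("extinct" in f for f in flags)

    def test_reproducible_from_seed(self):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = free_params(loss_rate=0.1, dup_rate=0.1, trans_rate=0.05)
        a = simulate_family(S, p, seed=9)
        b = simulate_family(S, p, seed=9)
        assert a.events == b.events
        assert a.true_tree.newick() == b.true_tree.newick()
        assert a.rates == b.rates

    def test_transfer_receivers_are_contemporaneous(self):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = free_params(loss_rate=0.05, dup_rate=0.02, trans_rate=0.25)
        for seed in range(10):
            h = simulate_family(S, p, seed=seed)
            for e in h.events:
                if e.kind != "T":
                    continue
                donor = S.node_by_key[e.branch]
                recv = S.node_by_key[e.receiver]
                for n in (donor, recv):
                    assert n.time < e.time < n.parent.time
                assert donor is not recv

    def test_size_and_event_filters_flag(self):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = SimulationParams(height=None, loss_rate=0.0, dup_rate=1.2,
                             trans_rate=0.0, size_bounds=(1, 8),
                             max_dup_transfer=3, max_retries=0)
        flagged = 0
        for seed in range(10):
            h = simulate_family(S, p, seed=seed)
            if not h.ok:
                flagged += 1
                assert set(h.flags) <= {"too_large", "too_many_dup_transfer"}
        assert flagged > 0

    def test_spine_duplication_count_mean(self):
        # the first lineage never switches identity, so its duplication
        # count on one branch is Poisson(rate * length)
        S = parse_dated_species_tree("(A:2,B:2);")
        rate = 0.4
        p = free_params(loss_rate=0.0, dup_rate=rate, trans_rate=0.0)
        counts = [
            sum(1 for e in simulate_family(S, p, seed=s).events
                if e.kind == "D" and e.lineage == 0 and e.branch == "A")
            for s in range(2000)
        ]
        lam = rate * 2.0
        se = math.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se


class TestPruning:
    def test_identity_without_extinctions(self):
        root = node_from_nested((("a", "b"), "c"))
        out = prune_extinct(root, extinct=set())
        assert clade_set(out) == clade_set(root)

    def test_cherry_sibling_grafts_to_grandparent(self):
        root = node_from_nested((("a", "b"), "c"))
        out = prune_extinct(root, extinct={"b"})
        assert out.leaf_names() == {"a", "c"}
        assert [ch.name for ch in out.children] == ["a", "c"]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_flags_match_reference_filter(self, seed):
        rng = random.Random(seed)
        labels = [f"x{i}" for i in range(20)]
        root = node_from_nested(random_topology(labels, rng))
        extinct = {l for l in labels if rng.random() < 0.4}
        mine = prune_extinct(root, extinct=extinct)
        ref = oracle_prune(root, extinct)
        if mine is None:
            assert ref is None
            return
        assert mine.leaf_names() == set(labels) - extinct
        assert clade_set(mine) == clade_set(ref)
        for n in mine.postorder():
            assert len(n.children) in (0, 2)


class TestDerivedEventCosts:
    def test_direct_formula(self):
        h = type("H", (), {"n_duplications": 2, "n_transfers": 1,
                           "n_losses": 5})()
        c = derive_event_costs(h)
        assert c.dup == pytest.approx(math.log(4), abs=1e-9)
        assert c.trans == pytest.approx(math.log(8), abs=1e-9)
        assert c.loss == pytest.approx(math.log(1.6), abs=1e-9)

    def test_zero_count_branch(self):
        h = type("H", (), {"n_duplications": 2, "n_transfers": 0,
                           "n_losses": 7})()
        assert derive_event_costs(h).trans == \
            pytest.approx(math.log(90), abs=1e-9)

    def test_symmetric_counts(self):
        h = type("H", (), {"n_duplications": 3, "n_transfers": 3,
                           "n_losses": 3})()
        c = derive_event_costs(h)
        assert c.dup == c.trans == c.loss == pytest.approx(math.log(3))

    def test_all_zero_is_undefined(self):
        h = type("H", (), {"n_duplications": 0, "n_transfers": 0,
                           "n_losses": 0})()
        with pytest.raises(UndefinedCostsError):
            derive_event_costs(h)

    def test_configurable_base(self):
        h = type("H", (), {"n_duplications": 2, "n_transfers": 1,
                           "n_losses": 5})()
        assert derive_event_costs(h, base=2).dup == pytest.approx(2.0)


class TestPerturbation:
    def test_marks_moved_edges_weak(self):
        S = parse_dated_species_tree(FIVE_SPECIES)
        p = free_params(loss_rate=0.0, dup_rate=0.0, trans_rate=0.0)
        h = simulate_family(S, p, seed=0)
        rng = np.random.default_rng(5)
        noisy = perturb_nni(h.true_tree, 2, rng)
        assert noisy.leaf_names() == h.true_tree.leaf_names()
        assert 1 <= len(noisy.weak_edges(50)) <= 2
        # a single NNI always changes the clade of its edge
        one = perturb_nni(h.true_tree, 1, np.random.default_rng(6))
        assert rf_distance(one, h.true_tree) > 0
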