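"""Cohesive merging, permutation significance, and module selection."""

import numpy as np
import pytest

from activemod.merge import (Module, ModuleSet, empirical_significance,
                             finalize, merge_cohesive)
from activemod.scoring import module_z
from activemod.search import CandidateModule
from tests.conftest import make_attnet


def cand(att, seed, members):
    members = frozenset(members)
    return CandidateModule(seed=seed, members=members,
                           k=len(members) - 1, z=module_z(att, members))


def sorted_cands(att, specs):
    cands = [cand(att, s, m) for s, m in specs]
    return sorted(cands, key=lambda c: (-c.z, c.seed))


def random_candidate_problem(seed, n_nodes=25, n_cands=8):
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    att = make_attnet({v: float(rng.uniform(1e-6, 1 - 1e-6)) for v in nodes})
    seen = set()
    specs = []
    for _ in range(n_cands):
        size = int(rng.integers(1, 6))
        members = frozenset(rng.choice(nodes, size, replace=False))
        if members in seen:
            continue
        seen.add(members)
        specs.append((sorted(members)[0], members))
    return att, sorted_cands(att, specs)


class TestMergeCohesive:
    def test_overlapping_merge_decided_by_recomputation(self):
        # M1 = {a,b,c} strong, M2 = {c,d} with d strong: the union wins
        # exactly when its Stouffer z beats M1 alone — verified by hand
        att = make_attnet({"a": 0.001, "b": 0.001, "c": 0.001, "d": 0.001})
        cands = sorted_cands(att, [("a", {"a", "b", "c"}), ("c", {"c", "d"})])
        result = merge_cohesive(cands, att)
        z_union = module_z(att, {"a", "b", "c", "d"})
        z_base = module_z(att, {"a", "b", "c"})
        expected = {"a", "b", "c", "d"} if z_union > z_base else {"a", "b", "c"}
        assert set(result.modules[0].members) == expected

    def test_union_rejected_when_it_dilutes(self):
        att = make_attnet({"a": 0.001, "b": 0.001, "c": 0.001, "d": 0.9})
        cands = sorted_cands(att, [("a", {"a", "b", "c"}), ("c", {"c", "d"})])
        result = merge_cohesive(cands, att)
        assert result.modules[0].members == frozenset({"a", "b", "c"})

    def test_disjoint_candidates_pass_through(self):
        att = make_attnet({"a": 0.01, "b": 0.01, "c": 0.2, "d": 0.2})
        cands = sorted_cands(att, [("a", {"a", "b"}), ("c", {"c", "d"})])
        result = merge_cohesive(cands, att)
        assert sorted(result.member_sets(), key=sorted) == [
            frozenset({"a", "b"}), frozenset({"c", "d"})]

    @pytest.mark.parametrize("seed", range(20))
    def test_disjointness_and_z_floor(self, seed):
        att, cands = random_candidate_problem(seed)
        result = merge_cohesive(cands, att)
        sets = result.member_sets()
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])
        # every emitted module scores at least its best absorbed candidate
        for mod in result.modules:
            constituents = [c for c in cands if c.members <= mod.members]
            overlapping = [c for c in cands if c.members & mod.members]
            assert mod.z == pytest.approx(module_z(att, mod.members), abs=1e-9)
            if constituents:
                assert mod.z >= max(c.z for c in constituents) - 1e-9
            # consumption: nothing overlapping an emitted module survives
            for other in result.modules:
                if other is not mod:
                    for c in overlapping:
                        assert not (c.members <= other.members)

    def test_exact_enumeration_beats_any_single_union(self):
        for seed in range(10):
            att, cands = random_candidate_problem(seed, n_cands=6)
            result = merge_cohesive(cands, att)
            top = result.modules[0]
            base = cands[0]
            for other in cands[1:]:
                if other.members & base.members:
                    alt = module_z(att, base.members | other.members)
                    assert top.z >= alt - 1e-9


class TestEmpiricalSignificance:
    def make_mset(self, att, member_sets):
        modules = [Module(module_id=i + 1, members=frozenset(m),
                          z=module_z(att, m))
                   for i, m in enumerate(member_sets)]
        modules.sort(key=lambda m: -m.z)
        return ModuleSet(modules=modules)

    def test_pvalue_bounds_and_determinism(self, random_attnet_factory):
        att = random_attnet_factory(n=30, seed=2)
        nodes = sorted(att.graph.nodes())
        mset = self.make_mset(att, [nodes[:5], nodes[10:13]])
        out1 = empirical_significance(mset, att, n_perm=200, seed=9)
        out2 = empirical_significance(mset, att, n_perm=200, seed=9)
        for m1, m2 in zip(out1.modules, out2.modules):
            assert m1.empirical_p == m2.empirical_p
            assert 1 / 201 <= m1.empirical_p <= 1.0

    def test_random_module_on_null_scores_is_insignificant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for rep in range(20):
            nodes = [f"n{i:02d}" for i in range(40)]
            att = make_attnet({v: float(rng.uniform(0, 1)) for v in nodes})
            members = list(rng.choice(nodes, 6, replace=False))
            mset = self.make_mset(att, [members])
            out = empirical_significance(mset, att, n_perm=150,
                                         seed=100 + rep)
            hits += out.modules[0].empirical_p <= 0.05
        assert hits <= 3  # a typical random module is not significant

    def test_planted_module_is_significant(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i:02d}" for i in range(60)]
        pvals = {v: float(rng.uniform(0, 1)) for v in nodes}
        planted = nodes[:8]
        for v in planted:
            pvals[v] = 1e-6
        att = make_attnet(pvals)
        mset = self.make_mset(att, [planted])
        out = empirical_significance(mset, att, n_perm=1000, seed=5)
        assert out.modules[0].empirical_p <= 0.01

    def test_n_perm_floor(self, random_attnet_factory):
        att = random_attnet_factory(n=10, seed=0)
        mset = self.make_mset(att, [sorted(att.graph.nodes())[:3]])
        with pytest.raises(ValueError):
            empirical_significance(mset, att, n_perm=50)


class TestFinalize:
    def module(self, members, z, p, mid=1):
        return Module(module_id=mid, members=frozenset(members), z=z,
                      empirical_p=p)

    def test_selection_rules(self):
        mset = ModuleSet(modules=[
            self.module([f"m{i}" for i in range(5)], 8.0, 0.002, 1),
            self.module(["x", "y"], 9.0, 0.001, 2),          # too small
            self.module([f"q{i}" for i in range(4)], 5.0, 0.2, 3),  # weak
        ])
        out = finalize(mset, alpha=0.05, min_size=3)
        assert len(out) == 1
        assert out.modules[0].module_id == 1
        assert out.modules[0].size == 5

    def test_empty_result_allowed(self):
        mset = ModuleSet(modules=[
            self.module(["a", "b", "c"], 2.0, 0.5)])
        out = finalize(mset)
        assert len(out) == 0

    def test_renumbering_by_z(self):
        mset = ModuleSet(modules=[
            self.module(["a", "b", "c"], 4.0, 0.01, 7),
            self.module(["d", "e", "f"], 6.0, 0.01, 9),
        ])
        out = finalize(mset)
        assert [m.module_id for m in out.modules] == [1, 2]
        assert out.modules[0].z == 6.0

    def test_requires_empirical_p(self):
        mset = ModuleSet(modules=[Module(1, frozenset("abc"), 3.0)])
        with pytest.raises(ValueError):
            finalize(mset)
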