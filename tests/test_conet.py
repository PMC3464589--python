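"""Correlation pairs, threshold selection, networks and modules."""

import numpy as np
import pandas as pd
import pytest

from structatlas.conet import (CorrelationPair, build_network, correlate_pairs,
                               detect_modules, pearson, select_threshold)
from structatlas.expression import ExpressionVolume
from structatlas.synthetic import simulate_expression, simulate_ontology

from test_expression import grid_ontology


class TestPearson:
    def test_self_correlation(self, rng):
        u = rng.uniform(size=20)
        assert pearson(u, u) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_example(self):
        # cov*n = 6.5, var_u*n = 5, var_v*n = 8.75
        assert pearson([1, 2, 3, 4], [1, 2, 3, 5]) == \
            pytest.approx(6.5 / np.sqrt(5 * 8.75))

    def test_affine_invariance(self, rng):
        u = rng.uniform(size=30)
        v = rng.uniform(size=30)
        assert pearson(3 * u + 2, v) == pytest.approx(pearson(u, v))
        assert pearson(u, 0.5 * v - 4) == pytest.approx(pearson(u, v))

    def test_constant_vector_is_nan(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))


class TestCorrelatePairs:
    def test_three_probes_three_pairs(self, rng):
        ont = grid_ontology()
        vols = [ExpressionVolume(f"p{i}", rng.uniform(size=ont.lattice_shape))
                for i in range(3)]
        assert len(correlate_pairs(vols, ont, "brain")) == 3

    def test_domain_restriction_matches_masked_pearson(self, rng):
        ont = grid_ontology()
        vols = [ExpressionVolume(f"p{i}", rng.uniform(size=ont.lattice_shape))
                for i in range(4)]
        pairs = correlate_pairs(vols, ont, 2)
        mask = ont.mask(2)
        by_key = {(p.probe_a, p.probe_b): p.rho for p in pairs}
        for i in range(4):
            for j in range(i + 1, 4):
                want = pearson(vols[i].energy[mask], vols[j].energy[mask])
                assert by_key[(f"p{i}", f"p{j}")] == pytest.approx(want)

    def test_brain_domain_equals_unmasked_vectors(self, rng):
        ont = grid_ontology()
        vols = [ExpressionVolume(f"p{i}", rng.uniform(size=ont.lattice_shape))
                for i in range(3)]
        pairs = correlate_pairs(vols, ont, "brain")
        for p in pairs:
            i, j = int(p.probe_a[1:]), int(p.probe_b[1:])
            assert p.rho == pytest.approx(
                pearson(vols[i].energy.ravel(), vols[j].energy.ravel()))

    def test_planted_clique_correlates(self, tiny_config):
        ont = simulate_ontology(tiny_config)
        vols, manifest = simulate_expression(tiny_config, ont)
        clique = set(manifest["cliques"][0]["probes"])
        pairs = correlate_pairs(vols, ont, "brain")
        inside = [p.rho for p in pairs
                  if p.probe_a in clique and p.probe_b in clique]
        outside = [p.rho for p in pairs
                   if (p.probe_a in clique) != (p.probe_b in clique)]
        assert len(inside) == 10 and min(inside) > 0.8
        assert abs(np.median(outside)) < 0.2

    def test_constant_probe_dropped(self, rng):
        ont = grid_ontology()
        vols = [ExpressionVolume("p0", np.ones(ont.lattice_shape)),
                ExpressionVolume("p1", rng.uniform(size=ont.lattice_shape)),
                ExpressionVolume("p2", rng.uniform(size=ont.lattice_shape))]
        pairs = correlate_pairs(vols, ont, "brain")
        assert {p.probe_a for p in pairs} | {p.probe_b for p in pairs} == \
            {"p1", "p2"}


class TestSelectThreshold:
    def test_floor_rule_when_everything_is_weak(self):
        rho_t, curve = select_threshold([0.5] * 100, q_target=0.01)
        assert rho_t == 0.8
        assert curve[0] == (0.8, 0.0)

    def test_counting_example(self):
        rhos = [0.91, 0.92] + [0.86, 0.87, 0.88] + [0.5] * 195
        rho_t, _ = select_threshold(rhos, q_target=0.01)
        assert rho_t == pytest.approx(0.9)

    def test_uniform_rhos_fall_back_to_top_grid_value(self, rng):
        rhos = rng.uniform(0, 1, size=10_000)
        with pytest.warns(UserWarning):
            rho_t, _ = select_threshold(rhos, q_target=0.01)
        assert rho_t == pytest.approx(0.95)
        assert np.mean(rhos >= rho_t) <= 0.06

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_threshold([])


def _pairs_from_matrix(r):
    out = []
    n = r.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            out.append(CorrelationPair(f"p{i}", f"p{j}", float(r[i, j])))
    return out


class TestBuildNetwork:
    def test_no_edges_above_threshold(self):
        pairs = [CorrelationPair("a", "b", 0.5)]
        g, comps, cliques = build_network(pairs, 0.8)
        assert g.number_of_nodes() == 0 and comps == [] and cliques == []

    def test_strict_inequality_at_threshold(self):
        pairs = [CorrelationPair("a", "b", 0.8), CorrelationPair("a", "c", 0.81)]
        g, _, _ = build_network(pairs, 0.8)
        assert set(g.edges) == {("a", "c")}

    def test_planted_five_clique_is_maximal(self, rng):
        r = np.eye(8)
        for i in range(5):
            for j in range(5):
                if i != j:
                    r[i, j] = 0.9 + 0.01 * rng.uniform()
        g, comps, cliques = build_network(_pairs_from_matrix(r), 0.8)
        assert cliques == [[f"p{i}" for i in range(5)]]

    def test_edge_set_equals_filter_oracle(self, rng):
        pairs = [CorrelationPair(f"p{i}", f"q{i}", rho)
                 for i, rho in enumerate(rng.uniform(-1, 1, size=200))]
        g, _, _ = build_network(pairs, 0.3)
        want = {(p.probe_a, p.probe_b) for p in pairs if p.rho > 0.3}
        assert {tuple(sorted(e)) for e in g.edges} == want


class TestDetectModules:
    def test_two_orthogonal_groups(self, rng):
        a = rng.uniform(size=12)
        b = rng.uniform(size=12)
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = a + rng.normal(0, 0.01, 12)
        for i in range(5):
            rows[f"b{i}"] = b + rng.normal(0, 0.01, 12)
        profiles = pd.DataFrame(rows).T
        mods = detect_modules(profiles, cut_k=2)
        got = {frozenset(m.probe_ids) for m in mods}
        assert got == {frozenset(f"a{i}" for i in range(5)),
                       frozenset(f"b{i}" for i in range(5))}

    def test_identical_profiles_form_one_module(self, rng):
        prof = rng.uniform(size=10)
        profiles = pd.DataFrame([prof] * 6, index=[f"p{i}" for i in range(6)])
        mods = detect_modules(profiles, cut_height=0.5)
        assert len(mods) == 1 and len(mods[0].probe_ids) == 6

    def test_focal_regions_match_planted_peaks(self, rng):
        regions = list(range(9))
        rows, truth = {}, {}
        for m, focal in enumerate([2, 5, 7]):
            for i in range(4):
                prof = rng.normal(1.0, 0.05, len(regions))
                prof[focal] += 3.0
                rows[f"m{m}_{i}"] = prof
                truth[f"m{m}_{i}"] = focal
        profiles = pd.DataFrame(rows).T
        profiles.columns = regions
        mods = detect_modules(profiles, cut_k=3)
        assert len(mods) == 3
        for m in mods:
            assert m.focal_regions == [truth[m.probe_ids[0]]]
            assert len({truth[p] for p in m.probe_ids}) == 1

    def test_constant_profiles_excluded(self, rng):
        profiles = pd.DataFrame({
            "const": np.ones(8),
            "v1": rng.uniform(size=8),
            "v2": rng.uniform(size=8)}).T
        mods = detect_modules(profiles, cut_k=2)
        assert "const" not in {p for m in mods for p in m.probe_ids}
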