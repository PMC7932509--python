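"""Species enumeration, reaction inventory and compiled RHS."""

import numpy as np
import pytest

import shhagg as sa
from shhagg.network import (CELL, DISPERSED, FREE_MULTIMER, HSPG_BOUND,
                            LIPO_BOUND, Species)

from conftest import naive_rhs


def brute_force_species(config: sa.ModelConfig) -> set[Species]:
    """Independent explicit enumeration straight from the rules."""
    out: set[Species] = set()
    for n in range(1, config.max_size + 1):
        out.add(Species(FREE_MULTIMER, n, CELL))
    if "hspg" in config.mechanisms_enabled:
        cap = config.max_size if config.hspg_capacity is None else min(
            config.hspg_capacity, config.max_size)
        lo = 1 if config.hspg_recruits_monomers else config.hspg_recruit_min
        for j in [0] + list(range(lo, cap + 1)):
            out.add(Species(HSPG_BOUND, j, CELL))
    if "lipoprotein" in config.mechanisms_enabled:
        for k in range(0, config.max_size + 1):
            out.add(Species(LIPO_BOUND, k, CELL))
    for s in list(out):
        if s.shh_count > 0 or config.free_carriers_disperse:
            out.add(Species(s.mechanism_class, s.shh_count, DISPERSED))
    return out


class TestEnumerateSpecies:
    def test_multimerisation_only_small(self):
        cfg = sa.ModelConfig(max_size=3, report_size=3,
                             mechanisms_enabled=frozenset({"multimerisation"}))
        idx = sa.enumerate_species(cfg)
        labels = {s.label() for s in idx.species}
        assert labels == {"M1", "M2", "M3", "M1*", "M2*", "M3*"}

    def test_hspg_window_boundary(self):
        cfg = sa.ModelConfig(max_size=2, report_size=2, hspg_recruit_min=2,
                             hspg_recruit_max=2)
        sizes = {s.shh_count for s in sa.enumerate_species(cfg).species
                 if s.mechanism_class == HSPG_BOUND}
        assert sizes == {0, 2}

    @pytest.mark.parametrize("cfg", [
        sa.ModelConfig(),
        sa.ModelConfig(max_size=50, report_size=40, hspg_capacity=10),
        sa.ModelConfig(max_size=12, report_size=10, hspg_recruits_monomers=True,
                       free_carriers_disperse=False),
        sa.ModelConfig(max_size=8, report_size=8,
                       mechanisms_enabled=frozenset({"multimerisation", "lipoprotein"})),
    ])
    def test_matches_brute_force_enumeration(self, cfg):
        idx = sa.enumerate_species(cfg)
        assert set(idx.species) == brute_force_species(cfg)
        assert len(idx.species) == len(set(idx.species))

    def test_default_network_size(self):
        # 601 cell species (200 multimers + 200 hspg + 201 lipo), mirrored
        idx = sa.enumerate_species(sa.ModelConfig())
        assert len(idx) == 1202

    def test_rejects_tiny_max_size(self):
        with pytest.raises(ValueError):
            sa.ModelConfig(max_size=1)


class TestReactionInventory:
    def test_small_coagulation_exhaustive(self):
        cfg = sa.ModelConfig(max_size=3, report_size=3,
                             mechanisms_enabled=frozenset({"multimerisation"}))
        par = sa.ParameterSet(r_H=0, r_L=0)
        coag = [r for r in sa.reaction_inventory(cfg, par) if r.kind == "coagulation"]
        got = {(tuple(sorted(s.shh_count for s in r.reactants)), r.symmetry_factor)
               for r in coag}
        assert got == {((1, 1), 0.5), ((1, 2), 1.0)}

    def test_no_cross_mechanism_reactions(self, default_params):
        bound = {HSPG_BOUND, LIPO_BOUND}
        for r in sa.reaction_inventory(sa.ModelConfig(max_size=20, report_size=10),
                                       default_params):
            classes = [s.mechanism_class for s in r.reactants]
            assert sum(c in bound for c in classes) <= 1

    def test_no_reactions_among_dispersed(self, default_params):
        for r in sa.reaction_inventory(sa.ModelConfig(max_size=10, report_size=5),
                                       default_params):
            assert not any(s.pool == DISPERSED for s in r.reactants)
            if r.kind == "dispersal":
                assert len(r.reactants) == 1 and len(r.products) == 1
                assert r.reactants[0]._replace(pool=DISPERSED) == r.products[0]

    @pytest.mark.parametrize("monomer_variant,expect", [(False, False), (True, True)])
    def test_hspg_monomer_recruitment_flag(self, monomer_variant, expect):
        cfg = sa.ModelConfig(max_size=12, report_size=10,
                             hspg_recruits_monomers=monomer_variant)
        rxns = sa.reaction_inventory(cfg, sa.ParameterSet())
        has_h_plus_m1 = any(
            r.kind == "hspg_recruit"
            and any(s.mechanism_class == FREE_MULTIMER and s.shh_count == 1
                    for s in r.reactants)
            for r in rxns)
        assert has_h_plus_m1 is expect

    @pytest.mark.parametrize("cfg", [
        sa.ModelConfig(max_size=6, report_size=6),
        sa.ModelConfig(max_size=6, report_size=6, lipo_recruit_max=3),
        sa.ModelConfig(max_size=6, report_size=6, hspg_capacity=4),
    ])
    def test_boundary_absorption(self, cfg, default_params):
        cap = cfg.max_size
        for r in sa.reaction_inventory(cfg, default_params):
            for s in r.products:
                assert s.shh_count <= cap
                if s.mechanism_class == HSPG_BOUND and cfg.hspg_capacity:
                    assert s.shh_count <= cfg.hspg_capacity

    def test_shh_conserved_in_binding_reactions(self, default_params):
        for r in sa.reaction_inventory(sa.ModelConfig(max_size=15, report_size=10),
                                       default_params):
            if r.kind in ("coagulation", "hspg_recruit", "lipo_recruit"):
                assert (sum(s.shh_count for s in r.reactants)
                        == sum(s.shh_count for s in r.products))

    def test_source_rates(self):
        par = sa.ParameterSet()
        rxns = sa.reaction_inventory(sa.ModelConfig(max_size=5, report_size=5), par)
        sources = {r.products[0].mechanism_class: r.rate_constant
                   for r in rxns if r.kind == "source"}
        assert sources[FREE_MULTIMER] == par.s_M
        assert sources[HSPG_BOUND] == pytest.approx(par.r_H * par.s_M)
        assert sources[LIPO_BOUND] == pytest.approx(par.r_L * par.s_M)

    def test_format_inventory_lists_every_reaction(self, default_params):
        rxns = sa.reaction_inventory(sa.ModelConfig(max_size=4, report_size=4),
                                     default_params)
        text = sa.format_inventory(rxns)
        assert len(text.splitlines()) == len(rxns)
        assert "M1 + M1 -> M2" in text


class TestBuildRHS:
    def test_zero_state_gives_sources_only(self):
        cfg = sa.ModelConfig(max_size=10, report_size=10)
        par = sa.ParameterSet()
        idx = sa.enumerate_species(cfg)
        rhs = sa.build_rhs(cfg, par, idx)
        dy = rhs(0.0, np.zeros(len(idx)))
        expected = np.zeros(len(idx))
        expected[idx.idx(FREE_MULTIMER, 1)] = par.s_M
        expected[idx.idx(HSPG_BOUND, 0)] = par.r_H * par.s_M
        expected[idx.idx(LIPO_BOUND, 0)] = par.r_L * par.s_M
        np.testing.assert_allclose(dy, expected)

    def test_identical_partner_dimer_flux(self):
        cfg = sa.ModelConfig(max_size=5, report_size=5,
                             mechanisms_enabled=frozenset({"multimerisation"}))
        par = sa.ParameterSet(s_M=0, r_H=0, r_L=0, k_mult=2.0, d_monomer=0,
                              d_multimer=0, d_hspg=0, d_lipo=0)
        idx = sa.enumerate_species(cfg)
        rhs = sa.build_rhs(cfg, par, idx)
        y = np.zeros(len(idx))
        m = 7.0
        y[idx.idx(FREE_MULTIMER, 1)] = m
        dy = rhs(0.0, y)
        assert dy[idx.idx(FREE_MULTIMER, 2)] == pytest.approx(0.5 * par.k_mult * m**2)
        assert dy[idx.idx(FREE_MULTIMER, 1)] == pytest.approx(-par.k_mult * m**2)

    @pytest.mark.parametrize("cfg", [
        sa.ModelConfig(max_size=5, report_size=5),
        sa.ModelConfig(max_size=6, report_size=6, lipo_recruit_max=2),
        sa.ModelConfig(max_size=6, report_size=6, hspg_recruits_monomers=True),
        sa.ModelConfig(max_size=4, report_size=4, free_carriers_disperse=False),
    ])
    def test_matches_naive_flux_oracle(self, cfg, default_params):
        idx = sa.enumerate_species(cfg)
        rxns = sa.reaction_inventory(cfg, default_params)
        rhs = sa.build_rhs(cfg, default_params, idx)
        rng = np.random.default_rng(42)
        for _ in range(5):
            y = rng.uniform(0, 100, size=len(idx))
            np.testing.assert_allclose(rhs(0.0, y), naive_rhs(idx, rxns, y),
                                       rtol=1e-12, atol=1e-9)

    def test_jacobian_matches_finite_differences(self, default_params):
        cfg = sa.ModelConfig(max_size=5, report_size=5)
        rhs = sa.build_rhs(cfg, default_params)
        rng = np.random.default_rng(7)
        y = rng.uniform(0, 50, size=rhs.n)
        J = rhs.jac(0.0, y).toarray()
        eps = 1e-6
        for j in range(rhs.n):
            dy = np.zeros(rhs.n)
            dy[j] = eps
            col = (rhs(0.0, y + dy) - rhs(0.0, y - dy)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, rtol=1e-5, atol=1e-6)

    def test_state_length_mismatch_raises(self, default_params):
        rhs = sa.build_rhs(sa.ModelConfig(max_size=4, report_size=4), default_params)
        with pytest.raises(ValueError):
            rhs(0.0, np.zeros(3))


class TestTotalShh:
    def test_zero_state(self):
        idx = sa.enumerate_species(sa.ModelConfig(max_size=4, report_size=4))
        assert sa.total_shh(np.zeros(len(idx)), idx) == 0.0

    def test_counts_monomer_equivalents_over_both_pools(self):
        idx = sa.enumerate_species(sa.ModelConfig(max_size=4, report_size=4))
        y = np.zeros(len(idx))
        y[idx.idx(FREE_MULTIMER, 3, CELL)] = 2
        y[idx.idx(LIPO_BOUND, 2, DISPERSED)] = 1
        assert sa.total_shh(y, idx) == pytest.approx(8.0)

    def test_empty_carriers_carry_no_shh(self):
        idx = sa.enumerate_species(sa.ModelConfig(max_size=4, report_size=4))
        y = np.zeros(len(idx))
        y[idx.idx(HSPG_BOUND, 0)] = 1000
        y[idx.idx(LIPO_BOUND, 0)] = 1000
        assert sa.total_shh(y, idx) == 0.0


def test_carrier_knockout_reduces_to_pure_coagulation():
    """With zero carrier sources the multimer dynamics equal the pure
    source+dispersal Smoluchowski system."""
    full_cfg = sa.ModelConfig(max_size=15, report_size=10)
    pure_cfg = sa.ModelConfig(max_size=15, report_size=10,
                              mechanisms_enabled=frozenset({"multimerisation"}))
    par = sa.ParameterSet(r_H=0.0, r_L=0.0, k_mult=1e-4)
    t_end = 240.0
    full = sa.integrate(full_cfg, par, t_end, grid_dt=60.0)
    pure = sa.integrate(pure_cfg, par, t_end, grid_dt=60.0)
    for t in full.times:
        sf, sp = full.snapshot(t), pure.snapshot(t)
        for n in range(1, 16):
            for pool in (CELL, DISPERSED):
                i_f = full.index.idx(FREE_MULTIMER, n, pool)
                i_p = pure.index.idx(FREE_MULTIMER, n, pool)
                assert sf[i_f] == pytest.approx(sp[i_p], rel=1e-6, abs=1e-6)
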