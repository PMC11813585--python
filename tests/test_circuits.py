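"""Circuit blocks: switch regulation, gene/excision/chloramphenicol ODEs,
topology assembly and the simulated circuit-level signatures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from punisher_sim import circuits as cir
from punisher_sim import scenarios_io as sio
from punisher_sim.circuits import (
    DnaState,
    GeneSpec,
    InducerPulse,
    MutationEvent,
    PunisherParams,
    chloramphenicol_rhs,
    excision_rhs,
    switch_regulation,
    synthetic_gene_rhs,
)
from punisher_sim.host_cell import RateBundle


def _pp(**kw):
    base = dict(I=0.8, eta_s=2.0, K_s=8600.0, F_sb=0.05, K_bI=2.4e4,
                k_sx_plus=3.6, k_sx_minus=0.36, k_conf=1.8, K_C=60.0,
                kappa=10.0, h_ext=4000.0)
    base.update(kw)
    return PunisherParams(**base)


class TestSwitchRegulation:
    def test_baseline_at_zero_protein(self):
        assert switch_regulation(0.0, _pp()) == pytest.approx(0.05)

    def test_half_saturation(self):
        """I*p_s = K_s sits exactly halfway up the Hill curve."""
        pp = _pp()
        p = pp.K_s / pp.I
        assert switch_regulation(p, pp) == pytest.approx(0.05 + 0.95 / 2)

    def test_saturation_limit(self):
        pp = _pp()
        p = 1e3 * pp.K_s / pp.I
        assert switch_regulation(p, pp) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_zero_over_zero_is_baseline(self):
        pp = _pp(K_s=0.0)
        assert switch_regulation(0.0, pp) == pytest.approx(pp.F_sb)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p=st.floats(0, 1e7), I=st.floats(0, 1), eta=st.floats(1, 4))
    def test_bounded_unit_interval(self, p, I, eta):
        pp = _pp(I=I, eta_s=eta)
        f = switch_regulation(p, pp)
        assert pp.F_sb - 1e-12 <= f <= 1.0 + 1e-12


class TestSyntheticGeneRhs:
    GENE = GeneSpec(name="x", c=10, alpha=100, n=300, beta=6.0, k=500, delta=0.0)

    def test_only_degradation_without_rates(self):
        rates = RateBundle(lam=0, eps=0, F_r=0, psi=0, nu=0, B=0, D=1.0, R=0)
        dm, dp = synthetic_gene_rhs(self.GENE, 1.0, 1.0, 1.0, rates, 0.0)
        assert dm == pytest.approx(-6.0)
        assert dp == 0.0

    def test_protease_and_dilution_removal(self):
        gene = GeneSpec(name="x", c=10, alpha=100, n=300, beta=6.0, k=500,
                        delta=2e-4)
        rates = RateBundle(lam=0.5, eps=0, F_r=0, psi=0, nu=0, B=0, D=1.0, R=0)
        _, dp = synthetic_gene_rhs(gene, 0.0, 1.0, 0.0, rates, 1e4)
        assert dp == pytest.approx(-(2e-4 * 1e4 + 0.5))

    def test_coexpressed_integrase_uses_scaled_switch_transcript(self, registry):
        """The integrase has no mRNA of its own: its translation reads the
        switch transcript scaled by the length ratio n_i/n_s."""
        sc = sio.build_scenario("single_burdensome_gene_with_punisher", None,
                                registry)
        y = cir.initial_state(sc)
        lay = sc.layout
        y[lay["m_s"]] = 123.0
        s, i = sc.gene("s"), sc.gene("i")
        mrnas = sc.effective_mrnas(y)
        assert mrnas["i"] == pytest.approx(123.0 * i.n / s.n)
        # and the rhs protein-synthesis term for i uses exactly that transcript
        rates = sc.rates_at(y)
        dy = sc.rhs(0.0, y)
        expect_dp_i = rates.eps / i.n * (mrnas["i"] / i.k) / rates.D * y[lay["R"]]
        assert dy[lay["p_i"]] == pytest.approx(expect_dp_i, rel=1e-9)


class TestExcision:
    def test_inert_without_integrase(self):
        d = excision_rhs(DnaState(5.0, 0.0), 0.0, _pp(), 1.0)
        assert d == (0.0, 0.0)

    def test_hill_half_saturation(self):
        pp = _pp()
        dc, _ = excision_rhs(DnaState(4.0, 0.0), pp.K_bI, pp, 0.0)
        assert dc == pytest.approx(-pp.k_sx_plus * 4.0 / 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0, 10), l=st.floats(0, 10), p=st.floats(0, 1e6),
           lam=st.floats(0, 3))
    def test_total_dna_decays_via_conformation_only(self, c, l, p, lam):
        """d(c_cat + c_LRi)/dt = -(k_conf + lambda) c_LRi for any input."""
        pp = _pp()
        dc, dl = excision_rhs(DnaState(c, l), p, pp, lam)
        assert dc + dl == pytest.approx(-(pp.k_conf + lam) * l, rel=1e-9, abs=1e-12)

    def test_trajectory_conservation_matches_quadrature(self, fig1_trajectory):
        """Along the full simulation, the drop in c_cat + c_LRi equals the
        integral of (k_conf + lambda) * c_LRi."""
        tab = fig1_trajectory.table
        total = (tab.c_cat + tab.c_LRi).to_numpy()
        lam = tab.lam.to_numpy()
        pp = fig1_trajectory.scenario.punisher
        flux = (pp.k_conf + lam) * tab.c_LRi.to_numpy()
        t = tab.time.to_numpy()
        lost = np.trapezoid(flux, t)
        assert total[0] - total[-1] == pytest.approx(lost, rel=2e-2)

    def test_irreversibility_after_commitment(self, fig1_trajectory):
        """Once excision has run (c_cat < 1% of initial) and the integrase
        has decayed again, c_cat never recovers."""
        tab = fig1_trajectory.table
        c0 = tab.c_cat.iloc[0]
        done = np.nonzero(tab.c_cat.to_numpy() < 0.01 * c0)[0]
        assert len(done) > 0, "excision never completed"
        after = tab.c_cat.to_numpy()[done[0]:]
        # never re-rises: each value stays within tolerance of the running minimum
        running_min = np.minimum.accumulate(after)
        assert np.all(after - running_min <= 1e-6 * c0)


class TestChloramphenicol:
    def test_diffusion_equilibrium(self):
        pp = _pp()
        assert chloramphenicol_rhs(pp.h_ext, 0.0, pp, 0.0) == pytest.approx(0.0)

    def test_influx_from_empty_cell(self):
        pp = _pp()
        assert chloramphenicol_rhs(0.0, 0.0, pp, 1.0) == pytest.approx(pp.kappa * pp.h_ext)

    def test_linear_balance_steady_state(self):
        pp = _pp()
        lam = 1.3
        h_star = pp.kappa * pp.h_ext / (pp.kappa + lam)
        assert chloramphenicol_rhs(h_star, 0.0, pp, lam) == pytest.approx(0.0, abs=1e-9)


class TestScenarioAssembly:
    def test_unknown_topology_rejected(self, registry):
        with pytest.raises(ValueError, match="unknown topology"):
            sio.build_scenario("not_a_topology", None, registry)

    def test_host_reduction_when_synthetic_genes_zeroed(self, registry):
        """Zeroing every synthetic gene reproduces the host-only derivatives
        exactly (given identical host state and no synthetic protein)."""
        sc_full = sio.build_scenario("single_burdensome_gene_with_punisher",
                                     None, registry, overrides={"h_ext": 0.0})
        sc_full = sc_full.with_genes_mutated([g.name for g in sc_full.genes])
        sc_host = sio.build_scenario("host_only", None, registry)
        y_full = cir.initial_state(sc_full)
        y_full[sc_full.layout["c_cat"]] = 0.0
        y_host = cir.initial_state(sc_host)
        d_full = sc_full.rhs(0.0, y_full)
        d_host = sc_host.rhs(0.0, y_host)
        np.testing.assert_allclose(d_full[:6], d_host[:6], rtol=0, atol=0)

    def test_mutation_event_zeroes_transcription_only(self, registry):
        """After a mutation event the gene's mRNA decays rather than being
        deleted: m_b is still positive just after the event and near zero
        a few hours later."""
        sc = sio.build_scenario(
            "single_burdensome_gene_with_punisher", None, registry,
            mutations=[MutationEvent(5.0, ("b",))])
        tr = cir.simulate(sc, (0.0, 10.0), n_samples=200)
        tab = tr.table
        just_after = tab[tab.time.between(5.01, 5.2)]["m_b"].iloc[0]
        later = tab["m_b"].iloc[-1]
        assert just_after > 100.0 and later < 1.0


class TestCircuitSignatures:
    def test_growth_rises_then_collapses_without_recovery(self, fig1_trajectory):
        """Mutation of the burdensome gene first accelerates growth, then
        CAT excision depresses it below the pre-mutation level for good."""
        tab = fig1_trajectory.table
        t_mut = 25.0
        lam_pre = tab[tab.time.between(t_mut - 2, t_mut - 0.1)].lam.iloc[-1]
        post = tab[tab.time > t_mut]
        lam_peak = post.lam.max()
        lam_final = tab.lam.iloc[-1]
        assert lam_peak > lam_pre * 1.05           # transient growth advantage
        assert lam_final < lam_pre * 0.95          # punished below original
        # no recovery: growth stays near its floor after excision completes
        t_done = post[post.c_cat < 0.01 * tab.c_cat.iloc[0]].time.iloc[0]
        tail = tab[tab.time > t_done + 5.0].lam
        assert tail.max() < lam_pre

    def test_single_toggle_gene_mutant_grows_slower(self, registry):
        """Losing one toggle gene de-represses its partner, raising burden:
        the mutant grows slower than the unmutated cell."""
        base = sio.build_scenario("two_toggles_with_punisher", None, registry)
        y0_ss, rates0, _ = cir.steady_state(base)
        mut = base.with_genes_mutated(("t11",))
        y1_ss, rates1, _ = cir.steady_state(mut, y0=y0_ss)
        assert rates1.lam < rates0.lam
        # partner de-repression: t12 rises above its repressed level
        p12_before = y0_ss[base.layout["p_t12"]]
        p12_after = y1_ss[mut.layout["p_t12"]]
        assert p12_after > 3.0 * p12_before

    def test_toggle_loss_triggers_punishment(self, registry):
        sc = sio.build_scenario(
            "two_toggles_with_punisher", None, registry,
            mutations=[MutationEvent(30.0, ("t11", "t12"))])
        tr = cir.simulate(sc, (0.0, 80.0), n_samples=400)
        tab = tr.table
        lam_pre = tab[tab.time.between(28, 29.9)].lam.iloc[-1]
        assert tab.c_cat.iloc[-1] < 0.05 * tab.c_cat.iloc[0]
        assert tab.lam.iloc[-1] < lam_pre

    def test_simultaneous_flip_pulse_is_rejected(self, registry):
        """A transient inducer pulse flips both toggles; the switch never
        leaves its low basin and CAT is retained within 1%."""
        fx = sio.make_fixture("fig3_flip_pulse")
        cfg = fx["config"]
        sc = sio.build_scenario(cfg.topology, None, registry, pulses=cfg.pulses)
        tr = cir.simulate(sc, (0.0, cfg.horizon), n_samples=400)
        tab = tr.table
        assert tab.c_cat.iloc[-1] > 0.99 * tab.c_cat.iloc[0]
        # and the flip actually happened
        assert tab.p_t12.iloc[-1] > tab.p_t11.iloc[-1]
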