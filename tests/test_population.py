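"""48-state turbidostat population model."""

import numpy as np
import pytest
from scipy.linalg import expm

from punisher_sim import population as pop


class TestStateIndexing:
    def test_forty_eight_states_sixteen_genetic(self):
        states = pop.enumerate_states()
        assert len(states) == 48
        assert len({s.genetic for s in states}) == 16

    def test_linear_index_is_bijective_and_canonical(self):
        states = pop.enumerate_states()
        assert [s.linear for s in states] == list(range(48))
        assert states[0].label == "BSPC:0"
        assert states[-1].label == "B′S′P′C′:H"

    def test_label_round_trip(self):
        st = pop.parse_label("B′SPC:H")
        assert st.genetic == (False, True, True, True)
        assert st.punisher == "H"
        assert pop.parse_label(st.label) == st
        # ASCII primes accepted too
        assert pop.parse_label("B'SPC:H") == st

    def test_malformed_labels_rejected(self):
        for bad in ("BSPC", "XSPC:L", "BSPC:Q", "BSPCC:L"):
            with pytest.raises(ValueError):
                pop.parse_label(bad)


def _uniform_library(d=1.0, p_b=2.0, excision=0.0):
    lib = {}
    for s in pop.enumerate_states():
        lib[s.linear] = pop.CellProperties(
            d=d, p_b=p_b, p_s=0.0, p_i=0.0, p_prot=0.0,
            excision_rate=excision, source=s.label, equilibrium_exists=True)
    return lib


class TestMatrixAssembly:
    def test_no_mutation_gives_diagonal_division(self):
        model = pop.build_matrices(_uniform_library(), {}, mu=0.0)
        assert np.allclose(model.D, np.diag(model.d))

    @pytest.mark.parametrize("mu", [0.0, 1e-12, 1e-3, 0.1])
    def test_column_sums_conserve_division_flux(self, mu, cell_library,
                                                transition_rates):
        model = pop.build_matrices(cell_library, transition_rates, mu=mu)
        np.testing.assert_allclose(model.D.sum(axis=0), model.d, rtol=1e-12)

    def test_excision_moves_only_c_to_c_prime(self, cell_library,
                                              transition_rates):
        model = pop.build_matrices(cell_library, transition_rates, mu=0.0)
        states = pop.enumerate_states()
        for j, sj in enumerate(states):
            for k, sk in enumerate(states):
                if j == k or model.A[k, j] == 0.0:
                    continue
                assert sj.functional("C") and not sk.functional("C")
                assert sk.genetic[:3] == sj.genetic[:3]
                assert sk.punisher == sj.punisher

    def test_transitions_change_only_punisher_coordinate(self, cell_library,
                                                         transition_rates):
        model = pop.build_matrices(cell_library, transition_rates, mu=0.0)
        states = pop.enumerate_states()
        for j, sj in enumerate(states):
            for k, sk in enumerate(states):
                if j == k or model.T[k, j] == 0.0:
                    continue
                assert sk.genetic == sj.genetic
                assert sk.punisher != sj.punisher

    def test_functional_gene_marginal_matches_closed_form(self):
        """Pure division+mutation chain: with uniform division rate d the
        count of cells with a functional B follows N e^{d(1-2mu)t} exactly
        (two-state closed form), checked against the matrix exponential of
        the assembled D."""
        mu, d, t = 0.1, 1.0, 2.0
        model = pop.build_matrices(_uniform_library(d=d), {}, mu=mu)
        x0 = np.zeros(48)
        x0[pop.parse_label("BSPC:L").linear] = 1000.0
        x = expm(model.D * t) @ x0
        b_functional = sum(x[s.linear] for s in pop.enumerate_states()
                           if s.functional("B"))
        assert b_functional == pytest.approx(1000.0 * np.exp(d * (1 - 2 * mu) * t),
                                             rel=1e-10)
        # total population grows at the uniform rate regardless of mu
        assert x.sum() == pytest.approx(1000.0 * np.exp(d * t), rel=1e-10)


class TestDilution:
    def test_uniform_rates(self):
        assert pop.dilution(np.ones(4), np.full(4, 1.7)) == pytest.approx(1.7)

    def test_concentrated_population(self):
        x = np.zeros(4); x[2] = 5.0
        d = np.array([1.0, 2.0, 3.0, 4.0])
        assert pop.dilution(x, d) == pytest.approx(3.0)

    def test_empty_reactor_rejected(self):
        with pytest.raises(ValueError):
            pop.dilution(np.zeros(3), np.ones(3))


class TestPopulationDynamics:
    def test_uniform_growth_is_exactly_cancelled_by_dilution(self):
        model = pop.build_matrices(_uniform_library(d=1.3), {}, mu=0.0)
        x0 = np.full(48, 10.0)
        tab = pop.simulate_population(model, x0, t_cult=20.0, n_samples=30)
        final = tab[model.labels].iloc[-1].to_numpy()
        np.testing.assert_allclose(final, x0, rtol=1e-6)

    def test_turbidostat_conserves_total_abundance(self, population_runs):
        (mp, x0p, tp), _ = population_runs
        totals = tp[mp.labels].sum(axis=1).to_numpy()
        np.testing.assert_allclose(totals, totals[0], rtol=1e-6)

    def test_matches_normalized_matrix_exponential(self, population_runs):
        """The turbidostat ODE has the closed-form solution
        x(t) = N * y(t)/sum(y(t)) with y' = (D+A+T) y: an independent
        oracle for the integrator."""
        (mp, x0p, tp), _ = population_runs
        M = mp.D + mp.A + mp.T
        for t_check in (50.0, 200.0):
            row = tp.iloc[(tp["time"] - t_check).abs().idxmin()]
            y = expm(M * row["time"]) @ x0p
            want = y / y.sum() * x0p.sum()
            got = row[mp.labels].to_numpy(dtype=float)
            np.testing.assert_allclose(got, want, atol=x0p.sum() * 1e-6)

    def test_control_mutant_takeover_is_monotone(self, population_runs):
        """Without the Punisher the burden-free mutant fraction only grows."""
        _, (mc, x0c, tc) = population_runs
        frac = sum(tc[s.label] for s in pop.enumerate_states()
                   if not s.functional("B")) / tc[mc.labels].sum(axis=1)
        d = np.diff(frac.to_numpy())
        assert np.all(d > -1e-9)
        assert frac.iloc[-1] > 0.99

    def test_punisher_keeps_fresh_mutant_fraction_below_control(self, population_runs):
        """Punished B' cells are excised and diluted away, so the
        B'-with-circuit-intact fraction stays below the control's
        corresponding mutant fraction at all times."""
        (mp, _, tp), (mc, _, tc) = population_runs
        f_pun = sum(tp[s.label] for s in pop.enumerate_states()
                    if not s.functional("B") and s.functional("S")
                    and s.functional("C")) / tp[mp.labels].sum(axis=1)
        f_ctl = sum(tc[s.label] for s in pop.enumerate_states()
                    if not s.functional("B")) / tc[mc.labels].sum(axis=1)
        late = tp["time"] > 5.0
        assert np.all(f_pun.to_numpy()[late] <= f_ctl.to_numpy()[late] + 1e-12)

    def test_punisher_prolongs_function_duration(self, registry, cell_library,
                                                 transition_rates):
        """tau(Punisher) > tau(control) across the scanned mutation rates."""
        for mu in (1e-13, 1e-12, 1e-11):
            mp, x0p = pop.punisher_population_model(
                registry, mu=mu, library=cell_library,
                transition_rates=transition_rates)
            mc, x0c = pop.control_population_model(
                registry, mu=mu, library=cell_library,
                transition_rates=transition_rates)
            _, _, tau_p = pop.productivity_metrics(
                pop.simulate_population(mp, x0p, n_samples=300), mp)
            _, _, tau_c = pop.productivity_metrics(
                pop.simulate_population(mc, x0c, n_samples=300), mc)
            assert tau_p > tau_c


class TestCellPropertyResolution:
    def test_every_state_resolves(self, cell_library):
        assert set(cell_library) == set(range(48))
        assert all(p.d >= 0 for p in cell_library.values())

    def test_unmutated_low_state_is_its_own_source(self, cell_library):
        props = cell_library[pop.parse_label("BSPC:L").linear]
        assert props.source == "BSPC:L"
        assert props.equilibrium_exists
        assert 1.0 < props.d < 2.0

    def test_nonexistent_low_equilibrium_inherits_progenitor(self, cell_library):
        """A fresh burdensome-gene mutant has no low equilibrium of its own
        and inherits the unmutated progenitor's properties — except the
        burdensome protein content, which is zero once B is lost."""
        props = cell_library[pop.parse_label("B'SPC:L").linear]
        parent = cell_library[pop.parse_label("BSPC:L").linear]
        assert not props.equilibrium_exists
        assert props.source == "BSPC:L"
        assert props.d == parent.d
        assert props.p_b == 0.0 and parent.p_b > 0.0

    def test_punished_mutant_grows_slowest_of_mutant_lineage(self, cell_library):
        """Excising CAT in a B' mutant makes it the slowest-dividing member
        of its (switch-functional) mutant lineage."""
        d_of = lambda lbl: cell_library[pop.parse_label(lbl).linear].d
        punished = d_of("B'SPC':L")
        others = [d_of(l) for l in ("B'SPC:0", "B'SPC:H", "B'SP'C:0",
                                    "B'SP'C:H", "BSPC:L")]
        assert all(punished < o for o in others)

    def test_mutant_without_punisher_outgrows_original(self, cell_library):
        d_escape = cell_library[pop.parse_label("B'S'P'C:0").linear].d
        d_orig = cell_library[pop.parse_label("BS'P'C:0").linear].d
        assert d_escape > 1.2 * d_orig


class TestProductivityMetrics:
    def test_single_state_theta(self):
        model = pop.build_matrices(_uniform_library(d=1.5, p_b=4.0), {}, mu=0.0)
        x0 = np.zeros(48); x0[3] = 100.0
        tab = pop.simulate_population(model, x0, t_cult=5.0, n_samples=10)
        assert tab["Theta"].iloc[-1] == pytest.approx(1.5 * 4.0)

    def test_no_burdensome_protein_no_yield(self):
        model = pop.build_matrices(_uniform_library(p_b=0.0), {}, mu=0.0)
        x0 = np.full(48, 1.0)
        tab = pop.simulate_population(model, x0, t_cult=5.0, n_samples=10)
        theta, Y, tau = pop.productivity_metrics(tab, model)
        assert Y == 0.0 and tau == 0.0

    def test_constant_productivity_never_expires(self):
        model = pop.build_matrices(_uniform_library(d=1.0, p_b=1.0), {}, mu=0.0)
        x0 = np.full(48, 1.0)
        tab = pop.simulate_population(model, x0, t_cult=30.0, n_samples=20)
        _, _, tau = pop.productivity_metrics(tab, model)
        assert tau == pytest.approx(30.0)
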