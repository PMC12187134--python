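"""Mass-action speciation of the trimer/bridged-complex ladder."""

import math

import numpy as np
import pytest

from lc8bridge import (
    DomainError,
    LadderModel,
    MassTable,
    SpeciesComposition,
    assign_composition,
    complex_mass,
    enumerate_species,
    mass_profile,
    max_occupancy,
    speciate,
    titration_profile,
)
from lc8bridge.speciation import _ladder_weights


def speciate_grid_oracle(total_trimer, total_lc8, model, n_refine=10):
    """Brute-force nested grid minimization of the two mass-balance residuals.

    Independent of the production solver (no closed-form quadratic): for each
    candidate free-LC8 value the free trimer is located by refining a grid on
    the trimer balance, then the LC8 balance residual selects the free-LC8
    grid cell; both grids are refined around their minima.
    """

    def weights(ell):
        x = ell / model.kd_intra
        y = ell / model.kd_bridge if math.isfinite(model.kd_bridge) else 0.0
        return _ladder_weights(model, x, y)

    def solve_t(ell):
        single, bridged = weights(ell)
        s1, s2 = sum(single.values()), sum(bridged.values())
        lo, hi = 0.0, total_trimer
        for _ in range(n_refine):
            ts = np.linspace(lo, hi, 81)
            resid = np.abs(ts * s1 + 2 * ts * ts * s2 - total_trimer)
            i = int(np.argmin(resid))
            lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, 80)]
        return 0.5 * (lo + hi)

    def lc8_resid(ell):
        t = solve_t(ell)
        single, bridged = weights(ell)
        lig = ell + t * sum(j * w for j, w in single.items())
        lig += t * t * sum((i + b) * w for (i, b), w in bridged.items())
        return abs(lig - total_lc8)

    lo, hi = 0.0, total_lc8
    for _ in range(n_refine):
        ls = np.linspace(lo, hi, 81)
        vals = [lc8_resid(ell) for ell in ls]
        i = int(np.argmin(vals))
        lo, hi = ls[max(i - 1, 0)], ls[min(i + 1, 80)]
    ell = 0.5 * (lo + hi)
    return solve_t(ell), ell


class TestEnumerate:
    def test_q3_bridged_span_three_to_nine(self):
        comps = enumerate_species(3)
        bridged = sorted(c.n_lc8_dimers for c in comps if c.n_trimers == 2)
        assert bridged == list(range(3, 10))

    def test_q1_bounds(self):
        comps = enumerate_species(1)
        assert max(c.n_lc8_dimers for c in comps if c.n_trimers == 1) == 1
        assert max(c.n_lc8_dimers for c in comps if c.n_trimers == 2) == 3

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_maxima_agree_with_max_occupancy(self, q):
        comps = enumerate_species(q)
        trimer_max, bridged_max = max_occupancy(q)
        assert max(c.n_lc8_dimers for c in comps if c.n_trimers == 1) == trimer_max
        assert max(c.n_lc8_dimers for c in comps if c.n_trimers == 2) == bridged_max
        # constructive guarantee: every composition satisfies its invariants
        assert all(isinstance(c, SpeciesComposition) for c in comps)

    def test_partial_ladder_option(self):
        comps = enumerate_species(3, min_occupancy=1)
        assert min(c.n_lc8_dimers for c in comps if c.n_trimers == 2) == 1

    def test_invalid_q(self):
        with pytest.raises(DomainError):
            enumerate_species(4)


class TestSpeciate:
    @pytest.fixture
    def q1_model(self):
        return LadderModel(q=1, kd_intra=0.3e-6, kd_bridge=1.1e-6)

    def test_no_lc8_all_free(self, q1_model):
        st = speciate(10e-6, 0.0, q1_model)
        assert st.free_trimer == pytest.approx(10e-6)
        assert all(c == 0 for _, c in st.species)

    def test_bridging_off_removes_two_trimer_species(self):
        model = LadderModel(q=2, kd_intra=0.3e-6, kd_bridge=math.inf)
        st = speciate(10e-6, 20e-6, model)
        assert all(c == 0 for comp, c in st.species if comp.n_trimers == 2)

    def test_matches_grid_oracle(self, q1_model):
        st = speciate(10e-6, 20e-6, q1_model)
        t_ref, l_ref = speciate_grid_oracle(10e-6, 20e-6, q1_model)
        assert st.free_trimer == pytest.approx(t_ref, rel=1e-4)
        assert st.free_lc8 == pytest.approx(l_ref, rel=1e-4)

    def test_conservation_on_random_scenarios(self):
        """Both totals conserved to 1e-9 relative on 1,000 random draws."""
        rng = np.random.default_rng(13)
        for _ in range(1000):
            q = int(rng.integers(1, 4))
            model = LadderModel(
                q=q,
                kd_intra=10 ** rng.uniform(-8, -5),
                kd_bridge=10 ** rng.uniform(-8, -4),
                degeneracy=bool(rng.integers(0, 2)),
            )
            t_tot = 10 ** rng.uniform(-7, -4)
            l_tot = 10 ** rng.uniform(-7, -3.5)
            st = speciate(t_tot, l_tot, model)
            trim = st.free_trimer + sum(c.n_trimers * x for c, x in st.species)
            lig = st.free_lc8 + sum(c.n_lc8_dimers * x for c, x in st.species)
            assert trim == pytest.approx(t_tot, rel=1e-9)
            assert lig == pytest.approx(l_tot, rel=1e-9)

    def test_bridged_fraction_monotone_in_kd_bridge(self):
        fractions = [
            speciate(
                10e-6, 30e-6,
                LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=kdb),
            ).bridged_fraction()
            for kdb in (0.1e-6, 1e-6, 10e-6, 100e-6)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_detailed_balance_q1(self, q1_model):
        """Species ratios reproduce the input dissociation constants."""
        st = speciate(10e-6, 20e-6, q1_model)
        t, ell = st.free_trimer, st.free_lc8
        c_t1 = st.concentration(1, 1)
        c_d1 = st.concentration(2, 1)  # pure single-bridge species
        # degeneracy on: [T.L] = 3 [T] L / kd_intra and the bimolecular
        # bridge [T2.L] = 9 [T]^2 L / kd_bridge^2
        assert 3 * t * ell / c_t1 == pytest.approx(q1_model.kd_intra, rel=1e-6)
        assert math.sqrt(9 * t * t * ell / c_d1) == pytest.approx(
            q1_model.kd_bridge, rel=1e-6
        )

    def test_detailed_balance_consecutive_bridges(self):
        """Each additional bridging LC8 beyond the first enters with the
        dimensionless factor L/kd_bridge: consecutive pure-bridge species
        ratios recover kd_bridge."""
        model = LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        st = speciate(10e-6, 30e-6, model)
        ell = st.free_lc8
        x = ell / model.kd_intra
        y = ell / model.kd_bridge
        single, bridged = _ladder_weights(model, x, y)
        for b in (1, 2):
            n_b = bridged[(0, b)] / (y**b)
            n_b1 = bridged[(0, b + 1)] / (y ** (b + 1))
            ratio = bridged[(0, b + 1)] / bridged[(0, b)]
            assert ell * (n_b1 / n_b) / ratio == pytest.approx(
                model.kd_bridge, rel=1e-9
            )

    def test_no_degeneracy_detailed_balance(self):
        model = LadderModel(q=1, kd_intra=0.3e-6, kd_bridge=1.1e-6, degeneracy=False)
        st = speciate(10e-6, 20e-6, model)
        t, ell = st.free_trimer, st.free_lc8
        assert t * ell / st.concentration(1, 1) == pytest.approx(
            model.kd_intra, rel=1e-6
        )

    def test_bridging_disabled_reduces_to_independent_registers(self):
        """With bridging off and degeneracy off, each register binds
        independently: bound fraction matches the closed-form single-site
        solution per register."""
        q = 3
        model = LadderModel(q=q, kd_intra=0.5e-6, kd_bridge=math.inf, degeneracy=False)
        t_tot, l_tot = 8e-6, 12e-6
        st = speciate(t_tot, l_tot, model)
        ell = st.free_lc8
        # closed form: each register independently bound with theta = L/(L+Kd)
        theta = ell / (ell + model.kd_intra)
        bound_pred = q * t_tot * theta
        bound = l_tot - ell
        assert bound == pytest.approx(bound_pred, rel=1e-9)

    def test_negative_totals_rejected(self, q1_model):
        with pytest.raises(DomainError):
            speciate(-1e-6, 1e-6, q1_model)


class TestMassProfile:
    def test_single_species_average(self):
        model = LadderModel(q=3, kd_intra=1e-10, kd_bridge=math.inf)
        # excess saturating LC8, no bridging: only the 1:3 trimer complex
        st = speciate(5e-6, 30e-6, model)
        rows, mw = mass_profile(st, include_free=False)
        populated = [(c, w) for c, m, w in rows if w > 1e-4]
        assert len(populated) == 1
        assert populated[0][0].ratio == "1:3"
        assert mw == pytest.approx(114.6, rel=1e-3)

    def test_two_species_average_between_bounds(self):
        comp_a = SpeciesComposition(1, 3, 3)
        comp_b = SpeciesComposition(2, 9, 3)
        model = LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        st = speciate(10e-6, 40e-6, model)
        _, mw = mass_profile(st, include_free=False)
        assert complex_mass(comp_a) < mw < complex_mass(comp_b)

    def test_scale_invariance(self):
        model = LadderModel(q=2, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        rows1, mw1 = mass_profile(speciate(5e-6, 10e-6, model))
        # doubling both totals shifts equilibria, so compare a constructed
        # state scaled by hand instead
        st = speciate(5e-6, 10e-6, model)
        st2 = type(st)(
            species=[(c, 2 * x) for c, x in st.species],
            free_trimer=2 * st.free_trimer,
            free_lc8=2 * st.free_lc8,
            total_trimer=2 * st.total_trimer,
            total_lc8=2 * st.total_lc8,
            model=st.model,
        )
        rows2, mw2 = mass_profile(st2)
        assert mw2 == pytest.approx(mw1, rel=1e-12)
        for (c1, m1, w1), (c2, m2, w2) in zip(rows1, rows2):
            assert w2 == pytest.approx(w1, rel=1e-12)


class TestTitrationProfile:
    def test_zero_equivalents_all_free(self):
        model = LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        states = titration_profile([0.0], 10e-6, model)
        assert states[0].free_trimer == pytest.approx(10e-6)

    def test_occupancy_bound(self):
        model = LadderModel(q=3, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        for st in titration_profile([0.25, 0.5, 1, 2, 3, 4], 10e-6, model):
            bound = st.total_lc8 - st.free_lc8
            trimers = st.total_trimer
            assert bound <= 3 * 3 * trimers / 2 + 1e-15

    def test_intermediate_plateau_orders_by_bridging_affinity(self):
        """A QT3-like model (bridging much weaker than intratrimer) keeps a
        larger trimer-complex population at intermediate equivalents than a
        QT2-like model (similar affinities)."""
        eq = [0.25, 0.5, 1, 2, 3, 4]
        t_tot = 10e-6
        qt2 = LadderModel(q=1, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        qt3 = LadderModel(q=1, kd_intra=0.3e-6, kd_bridge=50e-6)
        for m in (qt2, qt3):
            states = titration_profile(eq, t_tot, m)
            fracs = [st.bridged_fraction() for st in states]
            # bridged fraction rises with added LC8 until saturation
            assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))
        mid = 2  # 1 equivalent
        trimer_complex = lambda st: st.concentration(1, 1) / t_tot
        assert trimer_complex(titration_profile(eq, t_tot, qt3)[mid]) > trimer_complex(
            titration_profile(eq, t_tot, qt2)[mid]
        )

    def test_decreasing_equivalents_rejected(self):
        model = LadderModel(q=1, kd_intra=0.3e-6, kd_bridge=1.1e-6)
        with pytest.raises(DomainError):
            titration_profile([1.0, 0.5], 10e-6, model)


class TestAssignComposition:
    @pytest.mark.parametrize(
        "mass,q,expected",
        [(296.0, 3, "2:9"), (114.6, 3, "1:3"), (69.0, 1, "1:1"), (51.0, 3, "1:0")],
    )
    def test_nearest_assignment(self, mass, q, expected):
        assert assign_composition(mass, q).ratio == expected

    def test_tie_breaks_toward_fewer_lc8(self):
        masses = MassTable(lbd_od_monomer=10.0, lc8_dimer=10.0, od_monomer=10.0)
        # 1:1 (40) and 1:2 (50) straddle 45 equally; fewer LC8 wins
        assert assign_composition(45.0, 2, masses).ratio == "1:1"

    def test_invalid_mass(self):
        with pytest.raises(DomainError):
            assign_composition(0.0, 3)
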