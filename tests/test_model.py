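"""Unit and property tests for the pipeline engine."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p2i import (
    P2I_V2_PARAMS,
    ArchetypeParams,
    Candidate,
    Phase,
    PHASES,
    ValidationError,
    aggregate_portfolio,
    annual_cost_accrual,
    candidate_trajectory,
    entry_probability,
    launch_probability,
    launch_schedule,
    phase_timeline,
    remaining_phases,
    risk_adjusted_phase_costs,
)
from p2i.synth import SynthSpec, generate_portfolio, jitter_params


class TestPhases:
    def test_total_order(self):
        assert Phase.PRECLINICAL < Phase.PHASE1 < Phase.PHASE2 < Phase.PHASE3
        assert len(PHASES) == 4

    @pytest.mark.parametrize(
        "entry, expected",
        [
            (Phase.PHASE3, (Phase.PHASE3,)),
            (Phase.PRECLINICAL, PHASES),
            (Phase.PHASE1, (Phase.PHASE1, Phase.PHASE2, Phase.PHASE3)),
        ],
    )
    def test_remaining_phases(self, entry, expected):
        assert remaining_phases(entry) == expected

    def test_parse_rejects_unknown_label(self):
        with pytest.raises(ValueError, match="phase4"):
            Phase.parse("phase4")


class TestLaunchProbability:
    def test_simple_phase1_product(self, simple_phase1, params):
        # 0.68 * 0.46 * 0.71
        lam = launch_probability(simple_phase1, params["simple"])
        assert lam == pytest.approx(0.222088, abs=1e-12)
        assert round(lam, 2) == 0.22

    def test_unprecedented_preclinical_product(self, unprecedented_preclinical, params):
        # 0.41 * 0.50 * 0.05 * 0.40
        lam = launch_probability(unprecedented_preclinical, params["unprecedented"])
        assert lam == pytest.approx(0.0041, abs=1e-12)

    def test_certainty_when_all_probs_one(self):
        ap = ArchetypeParams(
            "sure",
            cost={p: 1.0 for p in PHASES},
            length={p: 1.0 for p in PHASES},
            prob_success={p: 1.0 for p in PHASES},
        )
        cand = Candidate("c", "d", "sure", Phase.PRECLINICAL)
        assert launch_probability(cand, ap) == 1.0

    def test_archetype_mismatch_is_an_error(self, simple_phase1, params):
        with pytest.raises(ValidationError, match="archetype"):
            launch_probability(simple_phase1, params["complex"])


class TestEntryProbability:
    def test_entry_phase_has_probability_one(self, simple_phase1, params):
        assert entry_probability(simple_phase1, params["simple"], Phase.PHASE1) == 1.0

    @pytest.mark.parametrize(
        "archetype, expected",
        [("unprecedented", 0.50 * 0.05), ("simple", 0.68 * 0.46)],
    )
    def test_phase3_entry_from_phase1(self, archetype, expected, params):
        cand = Candidate("c", "d", archetype, Phase.PHASE1)
        pi = entry_probability(cand, params[archetype], Phase.PHASE3)
        assert pi == pytest.approx(expected, abs=1e-12)

    def test_query_before_entry_rejected(self, simple_phase1, params):
        with pytest.raises(ValidationError, match="precedes"):
            entry_probability(simple_phase1, params["simple"], Phase.PRECLINICAL)

    def test_non_increasing_across_phases(self, unprecedented_preclinical, params):
        ap = params["unprecedented"]
        pis = [
            entry_probability(unprecedented_preclinical, ap, p) for p in PHASES
        ]
        assert all(a >= b for a, b in zip(pis, pis[1:]))


class TestRiskAdjustedCosts:
    def test_unprecedented_phase2_closed_form(self, unprecedented_phase2, params):
        costs = risk_adjusted_phase_costs(unprecedented_phase2, params["unprecedented"])
        assert costs[Phase.PHASE2] == pytest.approx(13.9)
        assert costs[Phase.PHASE3] == pytest.approx(0.05 * 223.0)
        assert sum(costs.values()) == pytest.approx(25.05)

    def test_simple_phase1_closed_form(self, simple_phase1, params):
        costs = risk_adjusted_phase_costs(simple_phase1, params["simple"])
        assert costs[Phase.PHASE1] == pytest.approx(2.2)
        assert costs[Phase.PHASE2] == pytest.approx(0.68 * 13.2)
        assert costs[Phase.PHASE3] == pytest.approx(0.68 * 0.46 * 201.0)
        assert sum(costs.values()) == pytest.approx(74.0488)

    def test_zero_costs_stay_zero(self):
        ap = ArchetypeParams(
            "free",
            cost={p: 0.0 for p in PHASES},
            length={p: 1.0 for p in PHASES},
            prob_success={p: 0.5 for p in PHASES},
        )
        cand = Candidate("c", "d", "free", Phase.PRECLINICAL)
        assert all(v == 0.0 for v in risk_adjusted_phase_costs(cand, ap).values())


class TestPhaseTimeline:
    def test_simple_phase1_boundaries(self, simple_phase1, params):
        tl = phase_timeline(simple_phase1, params["simple"])
        assert tl[Phase.PHASE1] == pytest.approx((0.0, 1.6))
        assert tl[Phase.PHASE2] == pytest.approx((1.6, 3.8))
        assert tl[Phase.PHASE3] == pytest.approx((3.8, 6.1))

    def test_unprecedented_preclinical_boundaries(self, unprecedented_preclinical, params):
        tl = phase_timeline(unprecedented_preclinical, params["unprecedented"])
        ends = [tl[p][1] for p in PHASES]
        assert ends == pytest.approx([3.3, 5.3, 9.0, 12.5])

    def test_single_phase(self, params):
        cand = Candidate("c", "d", "simple", Phase.PHASE3)
        tl = phase_timeline(cand, params["simple"])
        assert tl == {Phase.PHASE3: pytest.approx((0.0, 2.3))}

    def test_intervals_contiguous(self, unprecedented_preclinical, params):
        tl = phase_timeline(unprecedented_preclinical, params["unprecedented"])
        spans = [tl[p] for p in PHASES]
        for (_, end), (start, _) in zip(spans, spans[1:]):
            assert end == start


class TestAnnualAccrual:
    def test_second_year_straddles_phase_boundary(self, simple_phase1, params):
        # 0.6 yr of phase 1 at 2.2/1.6 per yr + 0.4 yr of phase 2 at 0.68*13.2/2.2
        acc = annual_cost_accrual(simple_phase1, params["simple"], 2019, 2031)
        assert acc[2020] == pytest.approx((2.2 / 1.6) * 0.6 + (13.2 / 2.2) * 0.68 * 0.4)
        assert acc[2020] == pytest.approx(2.457)

    def test_full_overlap_single_phase(self):
        ap = ArchetypeParams(
            "unit",
            cost={p: 0.0 for p in PHASES} | {Phase.PHASE3: 7.5},
            length={p: 0.0 for p in PHASES} | {Phase.PHASE3: 1.0},
            prob_success={p: 1.0 for p in PHASES},
        )
        cand = Candidate("c", "d", "unit", Phase.PHASE3)
        acc = annual_cost_accrual(cand, ap, 2019, 2020)
        assert acc[2019] == pytest.approx(7.5)
        assert acc[2020] == 0.0

    def test_truncation_at_horizon_end(self, simple_phase1, params):
        # One-year horizon: only the phase-1 rate for one year accrues.
        acc = annual_cost_accrual(simple_phase1, params["simple"], 2019, 2019)
        assert sum(acc.values()) == pytest.approx(2.2 / 1.6)

    def test_zero_length_phase_accrues_at_start(self):
        ap = ArchetypeParams(
            "burst",
            cost={Phase.PRECLINICAL: 0, Phase.PHASE1: 4.0, Phase.PHASE2: 9.0, Phase.PHASE3: 0},
            length={Phase.PRECLINICAL: 0, Phase.PHASE1: 1.5, Phase.PHASE2: 0.0, Phase.PHASE3: 1.0},
            prob_success={p: 1.0 for p in PHASES},
        )
        cand = Candidate("c", "d", "burst", Phase.PHASE1)
        acc = annual_cost_accrual(cand, ap, 2019, 2025)
        # phase 2 has zero length: its full cost lands in the year containing t=1.5
        assert acc[2020] == pytest.approx(4.0 / 1.5 * 0.5 + 9.0)

    def test_closed_form_equivalence_on_reference_portfolio(self, evi_portfolio):
        for cand in evi_portfolio.candidates:
            ap = evi_portfolio.params_for(cand)
            acc = annual_cost_accrual(cand, ap, 2019, 2031)
            closed = sum(risk_adjusted_phase_costs(cand, ap).values())
            assert sum(acc.values()) == pytest.approx(closed, abs=1e-9)


class TestLaunchSchedule:
    @pytest.mark.parametrize(
        "archetype, entry, expected_year",
        [
            ("simple", Phase.PHASE1, 2025),  # launch time 6.1
            ("unprecedented", Phase.PHASE2, 2026),  # launch time 7.2
            ("unprecedented", Phase.PRECLINICAL, 2031),  # launch time 12.5
        ],
    )
    def test_launch_year_from_fixture_params(self, archetype, entry, expected_year, params):
        cand = Candidate("c", "d", archetype, entry)
        year, lam = launch_schedule(cand, params[archetype], 2019)
        assert year == expected_year
        assert lam == pytest.approx(launch_probability(cand, params[archetype]))

    def test_all_zero_lengths_launch_in_start_year(self):
        ap = ArchetypeParams(
            "instant",
            cost={p: 0.0 for p in PHASES},
            length={p: 0.0 for p in PHASES},
            prob_success={p: 1.0 for p in PHASES},
        )
        cand = Candidate("c", "d", "instant", Phase.PRECLINICAL)
        assert launch_schedule(cand, ap, 2019) == (2019, 1.0)

    def test_exact_year_boundary_counts_in_earlier_year(self):
        ap = ArchetypeParams(
            "round",
            cost={p: 1.0 for p in PHASES},
            length={p: 0.0 for p in PHASES} | {Phase.PHASE3: 3.0},
            prob_success={p: 1.0 for p in PHASES},
        )
        cand = Candidate("c", "d", "round", Phase.PHASE3)
        year, _ = launch_schedule(cand, ap, 2019)
        assert year == 2021  # [0, 3) ends at Jan 1 2022 => booked in 2021


class TestAggregate:
    def test_singleton_portfolio_equals_candidate(self, params, simple_phase1):
        from p2i import Portfolio

        pf = Portfolio((simple_phase1,), params, 2019, 2031)
        res = aggregate_portfolio(pf)
        assert res.total_cost == pytest.approx(74.0488)
        assert res.total_launches == pytest.approx(0.222088)

    def test_empty_portfolio_is_all_zero(self, params):
        from p2i import Portfolio

        res = aggregate_portfolio(Portfolio((), params, 2019, 2021))
        assert res.total_cost == 0.0
        assert res.total_launches == 0.0
        assert (res.schedule == 0).all().all()

    def test_per_disease_sums_equal_totals(self, baseline_result):
        assert baseline_result.by_disease["cost"].sum() == pytest.approx(
            baseline_result.total_cost
        )
        assert baseline_result.by_disease["expected_launches"].sum() == pytest.approx(
            baseline_result.total_launches
        )

    def test_cumulative_series_non_decreasing(self, baseline_result):
        sched = baseline_result.schedule
        assert sched["cost_cumulative"].is_monotonic_increasing
        assert sched["launch_probability_cumulative"].is_monotonic_increasing

    def test_cumulative_cost_is_running_sum(self, baseline_result):
        sched = baseline_result.schedule
        assert sched["cost_cumulative"].iloc[-1] == pytest.approx(
            sched["cost_accrued"].sum()
        )


# --- property tests on synthetic portfolios -------------------------------

_seeds = st.integers(min_value=0, max_value=2**31 - 1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=_seeds, n=st.integers(min_value=1, max_value=40))
def test_closed_form_equals_accrual_sum_over_full_horizon(seed, n):
    """With the horizon covering every timeline, yearly accruals sum to the
    closed-form risk-adjusted cost (independent oracle: direct product-sum)."""
    pf = generate_portfolio(
        SynthSpec(n_candidates=n, seed=seed),
        params=jitter_params(P2I_V2_PARAMS, rel=0.2, seed=seed),
        start_year=2019,
        end_year=2019 + 40,  # far beyond any jittered timeline (<= ~15 yr)
    )
    res = aggregate_portfolio(pf)
    closed = sum(
        sum(risk_adjusted_phase_costs(c, pf.params_for(c)).values())
        for c in pf.candidates
    )
    assert res.total_cost == pytest.approx(closed, abs=1e-9)
    assert res.schedule["cost_cumulative"].is_monotonic_increasing
    assert res.schedule["launch_probability_cumulative"].is_monotonic_increasing
    assert 0.0 <= res.total_launches <= n


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=_seeds,
    m=st.floats(min_value=0.1, max_value=1.0),
    k_cost=st.floats(min_value=0.1, max_value=10.0),
)
def test_probability_and_cost_scaling_laws(seed, m, k_cost):
    """Scaling every success probability by m (<=1, so no clamping) scales a
    candidate's launch probability by m^k with k remaining phases; scaling
    every cost by k_cost scales cost outputs by exactly k_cost and leaves
    launch outputs unchanged."""
    pf = generate_portfolio(SynthSpec(n_candidates=8, seed=seed))
    scaled = {
        name: ArchetypeParams(
            name,
            cost={p: ap.cost[p] * k_cost for p in PHASES},
            length=dict(ap.length),
            prob_success={p: ap.prob_success[p] * m for p in PHASES},
        )
        for name, ap in pf.params.items()
    }
    for cand in pf.candidates:
        base_ap, new_ap = pf.params_for(cand), scaled[cand.archetype]
        k = len(remaining_phases(cand.entry_phase))
        lam0 = launch_probability(cand, base_ap)
        lam1 = launch_probability(cand, new_ap)
        assert lam1 == pytest.approx(lam0 * m**k, rel=1e-12)
        assert 0.0 <= lam1 <= 1.0
        year0, _ = launch_schedule(cand, base_ap, 2019)
        year1, _ = launch_schedule(cand, new_ap, 2019)
        assert year0 == year1
    cost_only = {
        name: ArchetypeParams(
            name,
            cost={p: ap.cost[p] * k_cost for p in PHASES},
            length=dict(ap.length),
            prob_success=dict(ap.prob_success),
        )
        for name, ap in pf.params.items()
    }
    res0 = aggregate_portfolio(pf)
    res_cost = aggregate_portfolio(pf.with_params(cost_only))
    assert res_cost.total_cost == pytest.approx(res0.total_cost * k_cost, rel=1e-12)
    assert res_cost.total_launches == res0.total_launches
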