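"""CAT engine: selection rule, stopping rules, combined SF administration."""

import numpy as np
import pytest

from probank.cat import (CatConfig, CatSession, PatternResponder,
                         SimulatedResponder, StopReason, administer,
                         complete_short_form, next_item, simulate_cat_study)
from probank.grm import (ItemBank, ItemParameters, eap_score, item_information,
                         to_t_metric)
from probank.simulate import make_bank


def uniform_bank(slope: float, n_items: int = 30) -> ItemBank:
    items = tuple(
        ItemParameters(f"i{j:02d}", slope,
                       tuple(np.linspace(-2, 2, 4) + 0.01 * j))
        for j in range(n_items))
    return ItemBank(items)


class TestNextItem:
    def test_first_item_maximises_information_at_prior_mean(self, default_bank):
        chosen = next_item(CatSession(), default_bank)
        infos = {it.item_id: item_information(0.0, it) for it in default_bank}
        assert chosen == max(sorted(infos), key=lambda i: infos[i])

    def test_matches_brute_force_argmax_each_step(self, default_bank):
        responder = SimulatedResponder(0.5, seed=3)
        session = CatSession()
        cfg = CatConfig()
        for _ in range(6):
            chosen = next_item(session, default_bank, cfg)
            theta = session.current_theta
            infos = {it.item_id: item_information(theta, it)
                     for it in default_bank if it.item_id not in session.responses}
            best = max(infos.values())
            assert infos[chosen] == pytest.approx(best)
            session.administered.append(chosen)
            session.responses[chosen] = responder(default_bank.item(chosen))
            session.trajectory.append(eap_score(session.responses, default_bank))

    def test_all_high_responses_shift_selection_upward(self, default_bank):
        session = CatSession()
        for _ in range(5):
            iid = next_item(session, default_bank)
            session.administered.append(iid)
            session.responses[iid] = default_bank.item(iid).n_categories
            session.trajectory.append(eap_score(session.responses, default_bank))
        later = default_bank.item(next_item(session, default_bank))
        first = default_bank.item(session.administered[0])
        assert np.mean(later.thresholds) > np.mean(first.thresholds)

    def test_exhausted_bank_raises(self, small_bank):
        session = CatSession()
        for it in small_bank:
            session.responses[it.item_id] = 1
        with pytest.raises(LookupError):
            next_item(session, small_bank)

    def test_ties_broken_by_lowest_item_id(self):
        twin = ItemBank((
            ItemParameters("b", 1.5, (-1.0, 0.0, 1.0)),
            ItemParameters("a", 1.5, (-1.0, 0.0, 1.0)),
            ItemParameters("c", 0.5, (-1.0, 0.0, 1.0)),
            ItemParameters("d", 0.5, (-1.0, 0.0, 1.0)),
        ))
        assert next_item(CatSession(), twin) == "a"


class TestAdminister:
    def test_floor_binds_on_maximally_informative_bank(self):
        """Slopes of 4.0 meet the precision target at the first check."""
        session = administer(SimulatedResponder(0.0, seed=1),
                             uniform_bank(4.0))
        assert session.n_items == 4
        assert session.stop_reason is StopReason.precision

    def test_cap_binds_on_uninformative_bank(self):
        session = administer(SimulatedResponder(0.0, seed=1),
                             uniform_bank(0.2))
        assert session.n_items == 12
        assert session.stop_reason is StopReason.item_cap

    def test_precision_stops_end_below_threshold(self, default_bank):
        cfg = CatConfig()
        for seed in range(30):
            session = administer(SimulatedResponder(
                np.random.default_rng(seed).normal(), seed=seed),
                default_bank, cfg)
            assert cfg.min_items <= session.n_items <= cfg.max_items
            assert len(set(session.administered)) == session.n_items
            if session.stop_reason is StopReason.precision:
                assert session.final.se < cfg.se_threshold

    def test_no_stop_check_before_min_items(self):
        """Even a perfect bank never stops before the 4-item floor."""
        session = administer(SimulatedResponder(0.0, seed=2),
                             uniform_bank(8.0))
        assert session.n_items >= 4

    def test_raising_se_threshold_never_lengthens(self, default_bank, rng):
        """Dominance on fixed patterns: looser precision => shorter or equal."""
        pattern = {it.item_id: int(rng.integers(1, it.n_categories + 1))
                   for it in default_bank}
        lengths = []
        for thr in (0.2, 0.3, 0.45):
            session = administer(PatternResponder(pattern), default_bank,
                                 CatConfig(se_threshold=thr))
            lengths.append(session.n_items)
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_failing_responder_aborts_with_partial_trace(self, default_bank):
        calls = {"n": 0}

        def flaky(item):
            calls["n"] += 1
            if calls["n"] > 2:
                raise RuntimeError("respondent walked away")
            return 3

        session = administer(flaky, default_bank)
        assert session.stop_reason is StopReason.aborted
        assert session.n_items == 2

    def test_bank_smaller_than_min_items_rejected(self):
        tiny = uniform_bank(1.0, n_items=3)
        with pytest.raises(ValueError, match="min_items"):
            administer(SimulatedResponder(0.0), tiny)


class TestCompleteShortForm:
    def test_subset_adds_nothing(self, default_bank):
        session = administer(SimulatedResponder(0.0, seed=4), default_bank)
        sf = session.administered[:3]
        combined = complete_short_form(session, sf, SimulatedResponder(0.0, 5),
                                       default_bank)
        assert set(combined) == set(session.administered)

    def test_disjoint_short_form_fully_added(self, default_bank):
        session = administer(SimulatedResponder(0.0, seed=4), default_bank)
        sf = [i for i in default_bank.item_ids
              if i not in session.responses][:8]
        combined = complete_short_form(session, sf, SimulatedResponder(0.0, 5),
                                       default_bank)
        assert set(sf) <= set(combined)
        assert len(combined) == len(session.administered) + 8

    def test_sf_score_equals_fixed_form_administration(self, default_bank, rng):
        """Scoring SF items from a combined run equals a fresh fixed form."""
        pattern = {it.item_id: int(rng.integers(1, 6)) for it in default_bank}
        session = administer(PatternResponder(pattern), default_bank)
        sf = list(default_bank.item_ids[5:13])
        combined = complete_short_form(session, sf, PatternResponder(pattern),
                                       default_bank)
        sf_from_combined = eap_score({i: combined[i] for i in sf}, default_bank)
        sf_fresh = eap_score({i: pattern[i] for i in sf}, default_bank)
        assert sf_from_combined.theta == pytest.approx(sf_fresh.theta)


class TestSimulateCatStudy:
    def test_identical_seeds_identical_summaries(self, default_bank):
        sf = list(default_bank.item_ids[:8])
        _t1, s1 = simulate_cat_study(default_bank, sf, n_simulees=40, seed=9)
        _t2, s2 = simulate_cat_study(default_bank, sf, n_simulees=40, seed=9)
        assert s1 == s2

    def test_full_bank_score_correlates_at_least_as_well(self, default_bank):
        from probank.shortform import select_short_form
        sf, _ = select_short_form(default_bank)
        table, summary = simulate_cat_study(default_bank, sf,
                                            n_simulees=150, seed=10)
        assert summary["r_cat_full"] >= summary["r_cat_sf"] - 0.005
        assert (table["length"].between(4, 12)).all()

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            CatConfig(min_items=0)
        with pytest.raises(ValueError):
            CatConfig(se_threshold=-0.1)
        with pytest.raises(ValueError):
            CatConfig(selection_rule="roulette")
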