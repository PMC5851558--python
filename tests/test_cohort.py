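import copy

import numpy as np
import pytest

from conftest import null_effect
from ecignet.cohort import (BranchResult, Outcome, additional_initiators,
                            additional_quitters, benefit_years, evaluate,
                            harm_years, point_estimate, realize_point)


def single_adult_realization(pop=1e6, s=0.2, q=0.5, e=0.1, or_=None,
                             p_ref_parts=(0.5, 0.15, 0.05), p1=0.8, p6=0.6):
    """One-stratum realization with directly controllable chain factors."""
    from ecignet.cohort import Realization
    w, pa, pn = p_ref_parts
    return Realization(
        adult_age_groups=["25-29"],
        adult_population=np.array([pop]),
        prev_smoking=np.array([s]), prev_attempt=np.array([q]),
        prev_ecig=np.array([e]), ylg=np.array([5.0]),
        youth_ages=[16], youth_population=np.array([1e6]),
        prev_never=np.array([0.8]), prev_ever_ecig=np.array([0.25]),
        p_init=np.array([0.10]), p_daily=np.array([0.3]),
        yll=np.array([10.0]),
        or_cessation=or_ if or_ is not None else 1.0,
        w_pharma_aid=w, p_cess_aid=pa, p_cess_noaid=pn,
        p_abst_1y_given_6m=p1, p_abst_6y_given_1y=p6,
        or_initiation=3.5, relative_harm=0.05)


class TestQuitterChain:
    def test_hand_product(self):
        """Pop 1e6, s=.2, q=.5, e=.1, delta=.01, p1=.8, p6=.6 -> 48.

        An OR is chosen so the cessation delta is exactly +0.01 above
        the mixture reference."""
        r = single_adult_realization()
        # choose p_ref parts giving p_ref = 0.0821; pick OR whose exposed
        # probability is p_ref + 0.01
        r.w_pharma_aid, r.p_cess_aid, r.p_cess_noaid = 0.321, 0.15, 0.05
        p_ref = 0.321 * 0.15 + 0.679 * 0.05
        p_exp = p_ref + 0.01
        r.or_cessation = (p_exp / (1 - p_exp)) / (p_ref / (1 - p_ref))
        dq, q0 = additional_quitters(r)
        assert dq.total == pytest.approx(1e6 * 0.2 * 0.5 * 0.1 * 0.01 * 0.8 * 0.6,
                                         rel=1e-9)
        assert q0.total == pytest.approx(1e6 * 0.2 * 0.5 * 0.1 * p_ref * 0.48,
                                         rel=1e-9)

    def test_zero_delta_zero_quitters(self):
        dq, _ = additional_quitters(single_adult_realization(or_=1.0))
        assert dq.total == pytest.approx(0.0, abs=1e-9)

    def test_linearity_in_population(self, fixture_ps):
        r = realize_point(fixture_ps)
        r2 = copy.deepcopy(r)
        r2.adult_population = 2 * r.adult_population
        dq, q0 = additional_quitters(r)
        dq2, q02 = additional_quitters(r2)
        assert dq2.total == pytest.approx(2 * dq.total, rel=1e-12)
        assert q02.total == pytest.approx(2 * q0.total, rel=1e-12)


class TestInitiatorChain:
    def test_hand_product(self):
        r = single_adult_realization()
        # p_init=0.10, OR=3.5 -> p_exposed=0.28, delta=0.18
        di = additional_initiators(r)
        assert di.total == pytest.approx(1e6 * 0.8 * 0.25 * 0.18 * 0.3, rel=1e-9)

    def test_unit_or_gives_zero(self):
        r = single_adult_realization()
        r.or_initiation = 1.0
        assert additional_initiators(r).total == pytest.approx(0.0, abs=1e-9)

    def test_zero_ecig_prevalence_gives_zero(self):
        r = single_adult_realization()
        r.prev_ever_ecig = np.array([0.0])
        assert additional_initiators(r).total == 0.0


class TestLifeYears:
    def test_benefit_without_penalty(self):
        dq = BranchResult(per_stratum={"25-29": 1000.0})
        q0 = BranchResult(per_stratum={"25-29": 0.0})
        b = benefit_years(dq, q0, np.array([5.0]), 0.05,
                          include_dilution_penalty=True)
        assert b == pytest.approx(4750.0)

    def test_full_harm_no_gain(self):
        dq = BranchResult(per_stratum={"25-29": 1000.0})
        q0 = BranchResult(per_stratum={"25-29": 0.0})
        assert benefit_years(dq, q0, np.array([5.0]), 1.0) == pytest.approx(0.0)

    def test_dilution_penalty_can_dominate(self):
        """Large baseline quitter pool + small excess -> net negative
        benefit branch."""
        dq = BranchResult(per_stratum={"25-29": 2070.0})
        q0 = BranchResult(per_stratum={"25-29": 81000.0})
        b = benefit_years(dq, q0, np.array([5.0]), 0.05)
        assert b == pytest.approx(-10417.5)

    def test_invalid_harm_rejected(self):
        dq = BranchResult(per_stratum={"a": 1.0})
        with pytest.raises(ValueError):
            benefit_years(dq, dq, np.array([5.0]), 1.5)

    def test_harm_years_product_and_additivity(self):
        one = BranchResult(per_stratum={"16": 10800.0})
        assert harm_years(one, np.array([10.0])) == pytest.approx(-108000.0)
        assert harm_years(BranchResult(per_stratum={"16": 0.0}),
                          np.array([10.0])) == 0.0
        two = BranchResult(per_stratum={"16": 10800.0, "17": 500.0})
        parts = (harm_years(one, np.array([10.0]))
                 + harm_years(BranchResult(per_stratum={"17": 500.0}),
                              np.array([4.0])))
        assert harm_years(two, np.array([10.0, 4.0])) == pytest.approx(parts)


class TestPointEstimate:
    def test_null_model_identities(self, fixture_ps):
        ps = null_effect(fixture_ps)
        ps.cessation = __import__("dataclasses").replace(
            ps.cessation, relative_harm=0.0)
        out = point_estimate(ps, include_dilution_penalty=False)
        for name in Outcome.FIELDS:
            assert abs(np.asarray(getattr(out, name))).max() < 1e-9

    def test_decomposition_identity(self, fixture_ps):
        out = point_estimate(fixture_ps)
        assert out.net_years == out.benefit_years + out.harm_years

    def test_spreadsheet_oracle_recomputation(self, fixture_ps):
        """Recompute the full chain with straight loops over strata and
        compare to the vectorized engine."""
        ps = fixture_ps
        c = ps.cessation
        p_ref = (c.w_pharma_aid.mean * c.p_cess_aid.mean
                 + (1 - c.w_pharma_aid.mean) * c.p_cess_noaid.mean)
        odds = p_ref / (1 - p_ref) * c.or_cessation.mean
        p_exp = odds / (1 + odds)
        pers = c.p_abst_1y_given_6m.mean * c.p_abst_6y_given_1y.mean
        h = c.relative_harm
        benefit = 0.0
        dq_tot = 0.0
        for st in ps.adult_strata:
            base = (st.population * st.prev_current_smoking.mean
                    * st.prev_quit_attempt.mean * st.prev_current_ecig.mean)
            dq = base * (p_exp - p_ref) * pers
            q0 = base * p_ref * pers
            dq_tot += dq
            benefit += st.yl_gained_per_quitter.mean * ((1 - h) * dq - h * q0)
        harm = 0.0
        di_tot = 0.0
        orr = ps.initiation.or_initiation.mean
        for st in ps.youth_strata:
            p0 = st.p_init_baseline.mean
            pe = (p0 / (1 - p0) * orr) / (1 + p0 / (1 - p0) * orr)
            di = (st.population * st.prev_never_smoking.mean
                  * st.prev_ever_ecig.mean * (pe - p0) * st.p_daily_35_39.mean)
            di_tot += di
            harm -= di * st.yl_lost_per_daily_smoker.mean
        out = point_estimate(ps)
        assert out.additional_quitters == pytest.approx(dq_tot, rel=1e-9)
        assert out.additional_initiators == pytest.approx(di_tot, rel=1e-9)
        assert out.benefit_years == pytest.approx(benefit, rel=1e-9)
        assert out.harm_years == pytest.approx(harm, rel=1e-9)
        assert out.net_years == pytest.approx(benefit + harm, rel=1e-9)

    def test_stratum_additivity(self, fixture_ps):
        """Evaluating strata separately and summing equals the joint run."""
        import dataclasses
        totals = np.zeros(2)
        for st in fixture_ps.adult_strata:
            ps_one = copy.deepcopy(fixture_ps)
            ps_one.adult_strata = [st]
            out = point_estimate(ps_one)
            totals += [out.additional_quitters, out.benefit_years]
        joint = point_estimate(fixture_ps)
        assert totals[0] == pytest.approx(joint.additional_quitters, rel=1e-9)
        assert totals[1] == pytest.approx(joint.benefit_years, rel=1e-9)

    def test_global_linearity_in_population(self, fixture_ps):
        k = 3.0
        ps2 = copy.deepcopy(fixture_ps)
        ps2.adult_strata = [__import__("dataclasses").replace(
            st, population=st.population * k) for st in fixture_ps.adult_strata]
        ps2.youth_strata = [__import__("dataclasses").replace(
            st, population=st.population * k) for st in fixture_ps.youth_strata]
        a, b = point_estimate(fixture_ps), point_estimate(ps2)
        for name in Outcome.FIELDS:
            assert getattr(b, name) == pytest.approx(k * getattr(a, name),
                                                     rel=1e-12)
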