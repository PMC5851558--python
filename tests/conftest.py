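import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from ecignet.parameters import SimConfig, UncertainQuantity
from ecignet.synthetic import GeneratorConfig, calibration_fixture, \
    generate_parameter_set

settings.register_profile(
    "repro", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_ps():
    """The deterministic calibration parameter set."""
    return calibration_fixture()


@pytest.fixture(scope="session")
def random_ps():
    """A randomly generated (but fixed-seed) parameter set."""
    return generate_parameter_set(GeneratorConfig(seed=7))


@pytest.fixture
def small_cfg():
    return SimConfig(n_iterations=2000, seed=11)


def zero_se(ps):
    """Copy of ``ps`` with every standard error set to zero."""
    import copy
    out = copy.deepcopy(ps)

    def z(uq):
        return UncertainQuantity(mean=uq.mean, se=0.0)

    out.adult_strata = [
        dataclasses.replace(
            st,
            prev_current_smoking=z(st.prev_current_smoking),
            prev_quit_attempt=z(st.prev_quit_attempt),
            prev_current_ecig=z(st.prev_current_ecig),
            yl_gained_per_quitter=z(st.yl_gained_per_quitter))
        for st in ps.adult_strata
    ]
    out.youth_strata = [
        dataclasses.replace(
            st,
            prev_never_smoking=z(st.prev_never_smoking),
            prev_ever_ecig=z(st.prev_ever_ecig),
            p_init_baseline=z(st.p_init_baseline),
            p_daily_35_39=z(st.p_daily_35_39),
            yl_lost_per_daily_smoker=z(st.yl_lost_per_daily_smoker))
        for st in ps.youth_strata
    ]
    out.cessation = dataclasses.replace(
        ps.cessation,
        or_cessation=z(ps.cessation.or_cessation),
        w_pharma_aid=z(ps.cessation.w_pharma_aid),
        p_cess_aid=z(ps.cessation.p_cess_aid),
        p_cess_noaid=z(ps.cessation.p_cess_noaid),
        p_abst_1y_given_6m=z(ps.cessation.p_abst_1y_given_6m),
        p_abst_6y_given_1y=z(ps.cessation.p_abst_6y_given_1y))
    out.initiation = dataclasses.replace(
        ps.initiation, or_initiation=z(ps.initiation.or_initiation))
    return out


def null_effect(ps):
    """Copy of ``ps`` with both odds ratios fixed at 1 (no e-cigarette
    effect, zero SE)."""
    import copy
    out = copy.deepcopy(ps)
    out.cessation = dataclasses.replace(
        ps.cessation, or_cessation=UncertainQuantity(1.0, 0.0))
    out.initiation = dataclasses.replace(
        ps.initiation, or_initiation=UncertainQuantity(1.0, 0.0))
    return out
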