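import pytest
from hypothesis import HealthCheck, settings

from copriss import AccuracyParams, DesignSpec, PairedDependence

settings.register_profile(
    "copriss",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("copriss")


@pytest.fixture
def example_params() -> AccuracyParams:
    """Accuracy assumptions of the PET/CT example study."""
    return AccuracyParams(se_c=0.81, se_e=0.90, sp_c=0.66, sp_e=0.80, prevalence=0.47)


@pytest.fixture
def example_dep() -> PairedDependence:
    """Minimal discordance proportions of the example study."""
    return PairedDependence(psi_d=0.09, psi_nd=0.14)


@pytest.fixture
def paired_spec() -> DesignSpec:
    return DesignSpec(design_kind="paired", alpha=0.05, power_overall=0.8)


@pytest.fixture
def unpaired_spec() -> DesignSpec:
    return DesignSpec(design_kind="unpaired", alpha=0.05, power_overall=0.8)
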