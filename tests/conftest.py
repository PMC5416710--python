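import pytest

from telomr.published import TRAITS
from telomr.synthetic_data import (CohortConfig, DEFAULT_SNPS,
                                   default_true_params)

ZEROS = dict.fromkeys(TRAITS, 0.0)


@pytest.fixture(scope="session")
def snps():
    return DEFAULT_SNPS


@pytest.fixture
def null_truth():
    """Global null: no causal effect, no confounding, no covariate effects."""
    return default_true_params(gamma_u_tl=0.0, lambda_u_trait=0.0,
                               age_tl_slope=0.0,
                               trait_age_effects=dict(ZEROS),
                               trait_sex_effects=dict(ZEROS),
                               apoe_trait_shift=dict(ZEROS))


@pytest.fixture
def confounded_null_truth():
    """No causal effect but a shared confounder on TL and trait."""
    return default_true_params(gamma_u_tl=0.5, lambda_u_trait=0.5)


@pytest.fixture
def small_config():
    def make(n=500, seed_offset=0, **kw):
        kw.setdefault("traits_available", ("GENERAL",))
        kw.setdefault("has_apoe", False)
        return CohortConfig(name=kw.pop("name", "SIM"), n=n,
                            seed_offset=seed_offset, **kw)
    return make
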