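import pytest
from hypothesis import settings

from rateshift import FilterPolicy, RateParams, SpeciesTree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tree() -> SpeciesTree:
    return SpeciesTree(t_mr=0.05, t_hr=0.2, t_hd=0.25)


@pytest.fixture(scope="session")
def shift_params() -> RateParams:
    """Study conditions: rate doubled before the inversion, halved after
    gene birth, relative to the reference."""
    return RateParams(r0=2.0, r1=1.0, r2=0.5, r_ref=1.0, k1=0.5, k2=0.5)


@pytest.fixture(scope="session")
def no_curation() -> FilterPolicy:
    """Filter policy that keeps every gap-free column — simulated
    alignments carry real divergence, not misalignment, so the
    low-identity window proxy for manual curation must stay off."""
    return FilterPolicy(drop_gap_columns=True, window_len=10, min_window_identity=0.0)
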