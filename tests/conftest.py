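"""Shared fixtures.

The expensive sampled computations (toy-fluid reference data, the full
inversion recovery, the IMC Jacobian check, the dilute effective-pair
closure, MC/LD cross-validation) live in :mod:`ncpcg.benchmarks` and
are session-scoped here, so unit tests and acceptance tests reuse one
computation each.
"""

import pytest

from ncpcg import benchmarks
from ncpcg.fixtures import MiniNCPSpec, make_mini_ncp


@pytest.fixture(scope="session")
def toy_fluid():
    """One-type LJ-like fluid with ground-truth potential and its
    MC-sampled reference RDF."""
    return benchmarks.toy_fluid_bundle(seed=3)


@pytest.fixture(scope="session")
def inversion_recovery_report(toy_fluid):
    """Full IBI-then-IMC recovery of the toy-fluid potential from
    zero."""
    return benchmarks.inversion_recovery(toy_fluid, seed=11)


@pytest.fixture(scope="session")
def imc_jacobian_hit_fraction(toy_fluid):
    return benchmarks.imc_jacobian_fraction(toy_fluid, seed=31)


@pytest.fixture(scope="session")
def mc_ld_deviation():
    return benchmarks.mc_ld_rdf_deviation(seed=11)


@pytest.fixture(scope="session")
def double_well_report():
    return benchmarks.double_well_occupancies(seed=21)


@pytest.fixture(scope="session")
def harmonic_variance_ratio():
    return benchmarks.harmonic_variance_mc(seed=5)


@pytest.fixture(scope="session")
def closure_report():
    """Dilute-limit effective pair potential recovery and resampling
    closure."""
    return benchmarks.dilute_closure(seed=5)


@pytest.fixture(scope="session")
def mini_ncp():
    return make_mini_ncp(MiniNCPSpec(seed=0))
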