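import pytest

from damlm.phantom import DomainStyle, PhantomSpec, generate_anatomy, render_domain


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return PhantomSpec(grid_shape=(16, 16, 16), tumor_radii=(2.0, 3.2, 5.0),
                       class_count=2, noise_sigma=0.05, seed=0)


@pytest.fixture(scope="session")
def identity_style() -> DomainStyle:
    return DomainStyle(domain_id=0, contrast_gain=1.0, bias_field_amplitude=0.0,
                       noise_sigma=0.0)


@pytest.fixture(scope="session")
def anatomy(tiny_spec):
    return generate_anatomy(tiny_spec, anatomy_seed=7)


@pytest.fixture(scope="session")
def rendered(anatomy, identity_style):
    return render_domain(anatomy, identity_style, render_seed=1)


@pytest.fixture(scope="session")
def benchmark_results():
    """Desk-scale two-domain adaptation benchmark, shared across the
    acceptance tests (cross-domain recovery, covariance alignment, and
    the robustness harness reuse its trained models)."""
    from damlm.benchmark import BenchmarkConfig, run_benchmark

    return BenchmarkConfig(), run_benchmark(BenchmarkConfig(), seeds=(0, 1, 2))
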