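import pytest

from fticrdom.cli import run_pipeline
from fticrdom.synthetic import SyntheticDesign, render_study


@pytest.fixture(scope="session")
def benchmark_study():
    """The standard synthetic benchmark: 100 formulas, 2 x 6 samples,
    0.5 ppm mass jitter, exact isotope ratios."""
    return render_study(SyntheticDesign(seed=2024))


@pytest.fixture(scope="session")
def benchmark_result(benchmark_study):
    """Benchmark run through the full pipeline (filter -> cluster ->
    annotate); returns (units, annotations, qc)."""
    return run_pipeline(benchmark_study.samples, benchmark_study.blanks)
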