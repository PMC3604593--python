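import numpy as np
import pytest
from hypothesis import settings

from cdclassify.evaluate import benchmark_scenarios, replicate_fdrs

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_files(tmp_path):
    """A tiny matrix + design pair written as TSV."""
    matrix = tmp_path / "m.tsv"
    design = tmp_path / "d.tsv"
    matrix.write_text(
        "gene_id\tr1\tr2\tr3\tr4\n"
        "g1\t1.0\t1.1\t5.0\t5.2\n"
        "g2\t2.0\t2.2\t2.1\t1.9\n"
        "g3\t4.0\t4.1\t0.5\t0.4\n"
    )
    design.write_text(
        "replicate_id\tcondition\nr1\tA\nr2\tA\nr3\tB\nr4\tB\n"
    )
    return matrix, design


# -- heavy shared simulation studies (computed once per session) -----------

@pytest.fixture(scope="session")
def scenario_benchmarks():
    """Best-threshold mean FDR of all four strategies, both modes, 20 reps."""
    return {
        mode: benchmark_scenarios(mode, reps=20, seed=11)
        for mode in ("sim1", "sim2")
    }


@pytest.fixture(scope="session")
def sim1_worst_case_fdrs():
    """Cd-with-DAPC at threshold 0.998 on 'very bad' Sim1, 50 replicates."""
    return replicate_fdrs("sim1", "B", "cd+dapc", 0.998, reps=50, seed=1)


@pytest.fixture(scope="session")
def sim2_worst_case_fdrs():
    """Cd alone at threshold 0.987 on 'very bad' Sim2, 50 replicates."""
    return replicate_fdrs("sim2", "B", "cd", 0.987, reps=50, seed=1)
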