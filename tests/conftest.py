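from __future__ import annotations

import pytest

from hsreg.synthetic_cohort import SimulationConfig, SyntheticCohort, simulate_cohort


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A compact cohort config used by fast unit/recovery tests."""
    defaults = dict(
        seed=seed,
        genome_length_bp=800_000,
        te_insertions={
            "human": {"L1": 5, "LTR7": 4, "LTR5": 3},
            "primate": {"L1": 4, "LTR7": 3, "LTR5": 2},
            "ancestral": {"L1": 3, "LTR7": 2, "LTR5": 1},
        },
        n_sites_per_tf={"NANOG": 40, "CTCF": 30, "POU5F1": 30},
        n_fast_genes=8,
        n_slow_genes=8,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def cohort() -> SyntheticCohort:
    """One shared synthetic cohort for read-only tests."""
    return simulate_cohort(small_config(seed=1))


@pytest.fixture(scope="session")
def fixtures_dir(cohort, tmp_path_factory):
    """The shared cohort written to disk as plain-text fixture files."""
    outdir = tmp_path_factory.mktemp("fixtures")
    cohort.write(str(outdir))
    return outdir
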