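import logging

import pytest

from methaplo.report import run_pipeline
from methaplo.simulate import SampleSpec, SimulationSpec  # noqa: F401

logging.getLogger("methaplo").setLevel(logging.WARNING)


def small_spec(seed: int = 3, **overrides) -> SimulationSpec:
    """A 1 x 200 kb study with two controls and two epimutants.

    Small enough for module tests; the full default spec is exercised by
    the acceptance suite.
    """
    kwargs = dict(
        n_chroms=1,
        chrom_length=200_000,
        n_genes=30,
        sv_counts={"INS": 3, "DEL": 3, "INV": 1, "TRANS": 1, "INVTR": 1,
                   "DUP": 1, "INVDP": 1, "CPL": 1, "CPG": 1},
        n_short_indels=8,
        n_allele_svs=14,
        samples=[
            SampleSpec("AZA0-3", "control"),
            SampleSpec("AZA0-7", "control"),
            SampleSpec("E1", "epimutant", {"CG": 6.0, "CHG": 3.0, "CHH": 1.0}),
            SampleSpec("E2", "epimutant", {"CG": 3.0, "CHG": 2.0, "CHH": 0.5}),
        ],
        n_implants={"CG": 8, "CHG": 4, "CHH": 3},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on the small study, shared across tests."""
    outdir = tmp_path_factory.mktemp("small_run")
    return run_pipeline(small_spec(), outdir)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """The default study conditions (2 x 1 Mb, 6 samples, depth 20, 2 reps).

    Shared by the acceptance suite and the full-scale integration checks;
    takes a few minutes, so it is built once per session.
    """
    outdir = tmp_path_factory.mktemp("full_run")
    return run_pipeline(SimulationSpec(seed=1), outdir)
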