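"""Shared fixtures.

The two end-to-end pipeline runs (noise-free and noisy) are expensive,
so they are session-scoped and shared between the unit and acceptance
tests.  Both use the standard synthetic study design: 60 accessions from
3 populations at fst 0.3, clone groups of sizes 2/3/5/8/10, 3 technical
replicate pairs, a 300-fragment PstI–NspI library with a high-copy
chloroplast decoy, read depth 20.
"""

from __future__ import annotations

import numpy as np
import pytest

from gbscore import pipeline as pl


def _base_config(tmp_path, seed: int, **overrides) -> pl.PipelineConfig:
    sim_kwargs = overrides.pop("simulate", {})
    return pl.PipelineConfig(
        seed=seed,
        out_dir=str(tmp_path),
        simulate=pl.SimulateParams(**sim_kwargs),
        diversity=pl.DiversityParams(**overrides.pop("diversity", {})),
        structure=pl.StructureParams(**overrides.pop("structure", {})),
        **overrides,
    )


@pytest.fixture(scope="session")
def noiseless_report(tmp_path_factory):
    """Error-free end-to-end run with a K = 1..5 structure sweep
    (reduced MCMC: burnin 2,000, 5,000 reps, 3 runs per K)."""
    cfg = _base_config(
        tmp_path_factory.mktemp("noiseless"), seed=7,
        diversity={"n_boot": 100},
        structure={"k_min": 1, "k_max": 5, "n_runs": 3,
                   "burnin": 2000, "reps": 5000},
    )
    return pl.run_all(cfg)


@pytest.fixture(scope="session")
def noiseless_eval(noiseless_report):
    return pl.evaluate_truth(noiseless_report)


@pytest.fixture(scope="session")
def noisy_report(tmp_path_factory):
    """Same design with 0.5% sequencing error and somatic rate 0.002;
    the structure sweep is skipped (it is exercised by the error-free
    run)."""
    cfg = _base_config(
        tmp_path_factory.mktemp("noisy"), seed=7,
        simulate={"error_rate": 0.005, "somatic_rate": 0.002},
        diversity={"n_boot": 0},
        structure={"enabled": False},
    )
    return pl.run_all(cfg)


@pytest.fixture(scope="session")
def noisy_eval(noisy_report):
    return pl.evaluate_truth(noisy_report)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
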