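"""Shared synthetic fixtures.

All imagery is generated at test time from the simulator with fixed seeds;
population renders and their analyses are session-scoped because they are
reused by many recovery and ordering tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import toroquant as tq

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def wt_cell():
    """One wildtype-preset cell, PSF-blurred with Poisson noise."""
    return tq.render_cell(tq.strain_spec("wildtype", seed=1))


@pytest.fixture(scope="session")
def clean_cell():
    """One wildtype-preset cell, no noise, no blur."""
    return tq.render_cell(
        tq.strain_spec("wildtype", seed=1, noise_model="none", psf_sigma_um=0.0)
    )


@pytest.fixture(scope="session")
def fig8_cell():
    spec = tq.SyntheticSpec(
        topology="figure_eight",
        ring_radius_um=0.55,
        image_size=(160, 160),
        ori_angles_deg=(180.0, 0.0),
        ter_angles_deg=(300.0, 240.0),
        chromosome_multiplicity=2,
        dna_total_intensity=4.0e5,
        seed=3,
    )
    return tq.render_cell(spec)


def _analyzed_population(strain: str, n: int, seed: int, **kw):
    specs = tq.sample_population_specs(strain, n, seed=seed, **kw)
    stack, truths = tq.render_population(specs, seed=seed)
    df = tq.analyze_population(stack, truths, strain_label=strain)
    return df[~df["discarded"].eq(True)].reset_index(drop=True)


@pytest.fixture(scope="session")
def wt_population():
    """50 analyzed wildtype cells at fixture SNR, with truth columns."""
    return _analyzed_population("wildtype", 50, seed=101)


@pytest.fixture(scope="session")
def wt_population_noiseless():
    return _analyzed_population("wildtype", 50, seed=102, noise_model="none")


@pytest.fixture(scope="session")
def eq_population():
    """50 analyzed ATPase-deficient (EQ) preset cells (compaction 1.2)."""
    return _analyzed_population("mukb_eq", 50, seed=103)


@pytest.fixture(scope="session")
def matp_population():
    """50 analyzed MatP-deletion preset cells."""
    return _analyzed_population("delta_matp", 50, seed=104)
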