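import numpy as np
import pandas as pd
import pytest

from nanopotency.synthetic import ExposureDesign, PotencyTruth, generate_cytotox_plate


def make_plate_row(particle="NP", cell_line="A549", assay="LDH", dose=0.0,
                   experiment=1, technical_rep=1, cell_free=False, signal=100.0):
    return dict(particle=particle, cell_line=cell_line, assay=assay, dose=dose,
                experiment=experiment, technical_rep=technical_rep,
                cell_free=cell_free, signal=signal)


def plate_from_rows(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def small_design():
    return ExposureDesign(
        particles=("NP-A", "NP-B"),
        cell_lines=("A549",),
        assays=("LDH", "ATP", "CTB"),
        doses=(0.0, 12.5, 25.0, 50.0, 100.0),
        n_experiments=3,
        n_technical=2,
        mechanistic_dose=25.0,
    )


@pytest.fixture
def noiseless_plate(small_design):
    truth = PotencyTruth.uniform(small_design, beta_magnitude=0.03, noise_cv=0.0)
    return generate_cytotox_plate(small_design, truth, seed=0), truth


@pytest.fixture
def noisy_plate(small_design):
    truth = PotencyTruth.uniform(small_design, beta_magnitude=0.03, noise_cv=0.1)
    return generate_cytotox_plate(small_design, truth, seed=42), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
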