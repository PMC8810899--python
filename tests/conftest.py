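"""Shared fixtures: synthetic retina, segmentation products, classifier run.

Expensive artefacts are session-scoped so unit and acceptance tests
share one segmentation and one cross-validated training run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from retimorph.classifier import train_svm
from retimorph.imaging_core import Image, PreprocessConfig, segment
from retimorph.morphotype import label_frame
from retimorph.particle_analysis import find_particles, measure_all, records_to_frame
from retimorph.synth_data import make_feature_table, make_retina

EASY_SEED = 5
TABLE_SEED = 42


@pytest.fixture(scope="session")
def easy_retina():
    """Low-noise synthetic retina: (image, truth table, vessel mask)."""
    return make_retina(n_per_type=10, shape=(512, 512), noise_sd=0.01, seed=EASY_SEED)


@pytest.fixture(scope="session")
def easy_segmentation(easy_retina):
    """Segmentation products of the easy retina (default config)."""
    img, truth, vessels = easy_retina
    binary = segment(img, PreprocessConfig())
    particles = find_particles(binary, min_area=20)
    records = measure_all(particles, img)
    table = records_to_frame(records)
    labels = label_frame(table)
    return {
        "binary": binary,
        "particles": particles,
        "records": records,
        "table": table,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def feature_table():
    """Balanced 5-class synthetic feature table, 240 cells per class."""
    return make_feature_table(n_per_type=240, seed=TABLE_SEED)


@pytest.fixture(scope="session")
def cv_run(feature_table):
    """(model, CVReport) of the linear SVM on the feature table."""
    return train_svm(feature_table, folds=5, seed=TABLE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
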