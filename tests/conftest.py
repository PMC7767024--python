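import logging

import pandas as pd
import pytest

from riverchem.io import PeakTable, load_bundled_transformations
from riverchem.simulate import GeneratorConfig, generate_study

logging.getLogger("riverchem").setLevel(logging.ERROR)


def make_table(rows, sample_ids=("s1", "s2")):
    """Build a PeakTable from (mass, c, h, n, o, s, p, is_c13, *intensities) tuples."""
    peaks = pd.DataFrame(
        [r[:8] for r in rows],
        columns=["mass", "c", "h", "n", "o", "s", "p", "is_c13"],
    )
    detections = pd.DataFrame([r[8:] for r in rows], columns=list(sample_ids))
    return PeakTable.from_frames(peaks, detections)


@pytest.fixture
def tiny_table():
    """Three formula-assigned peaks x two samples."""
    return make_table([
        (200.1, 10, 16, 0, 5, 0, 0, False, 1.0, 0.0),
        (300.2, 15, 22, 1, 7, 0, 0, False, 1.0, 1.0),
        (400.3, 20, 28, 0, 9, 1, 0, False, 0.0, 1.0),
    ])


@pytest.fixture(scope="session")
def bundled_refs():
    return load_bundled_transformations()


@pytest.fixture(scope="session")
def small_refs():
    """Hand-built reference list with one entry per category."""
    return pd.DataFrame({
        "name": ["water", "alanine", "sulfonation", "phosphate", "taurine"],
        "mass": [18.010565, 71.037114, 79.956815, 79.9662, 125.014664],
        "composition": ["H2O", "C3H5NO", "SO3", "HO3P", "C2H7NO3S"],
        "contains_n": [False, True, False, False, True],
        "contains_s": [False, False, True, False, True],
        "contains_p": [False, False, False, True, False],
    })


@pytest.fixture(scope="session")
def default_study(bundled_refs):
    """One synthetic study at the default (contrast-planting) conditions."""
    return generate_study(GeneratorConfig(seed=11), refs=bundled_refs)
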