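"""Shared fixtures: hand-written molfiles and small synthetic studies."""

import pytest

from pathassoc.chemio import parse_molfile
from pathassoc.pipeline import build_pair_dataset
from pathassoc.synthetic import SynthConfig, generate

METHANE_MOLFILE = """methane


  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
"""

ETHANOL_MOLFILE = """ethanol


  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
"""

WATER_MOLFILE = """water


  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
M  END
"""

# acetate-like fragment with an explicit M  CHG charge and a type-4 bond
CHARGED_MOLFILE = """charged


  4  3  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  4  0
  2  4  4  0
M  CHG  1   4  -1
M  END
"""

BENZENE_HEAVY_MOLFILE = """benzene


  6  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  4  0
  2  3  4  0
  3  4  4  0
  4  5  4  0
  5  6  4  0
  1  6  4  0
M  END
"""


@pytest.fixture
def methane():
    return parse_molfile(METHANE_MOLFILE)


@pytest.fixture
def ethanol():
    return parse_molfile(ETHANOL_MOLFILE)


@pytest.fixture
def water():
    return parse_molfile(WATER_MOLFILE)


@pytest.fixture
def benzene():
    return parse_molfile(BENZENE_HEAVY_MOLFILE)


TINY_CONFIG = SynthConfig(
    n_compounds=60,
    n_l1=2,
    n_l2=4,
    n_l3=8,
    n_classes=8,
    size_range=(6, 16),
    annotation_rate=1.11,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_study():
    """A small generated study used across dataset/model/evaluation tests."""
    return generate(TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_study):
    ds, _ = build_pair_dataset(
        tiny_study.molecules,
        tiny_study.hierarchy,
        tiny_study.direct_annotations,
        max_depth=1,
    )
    return ds
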