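import numpy as np
import pandas as pd
import pytest

from mixshrink.chemicals import ChemicalSpec
from mixshrink.cohort import CohortConfig


def make_specs(
    n_urine: int = 2,
    n_serum: int = 3,
    detection: float = 1.0,
    gm: float = 5.0,
    gsd: float = 2.0,
) -> list[ChemicalSpec]:
    """Small mixed panel: urinary phthalates plus serum PCBs."""
    specs = []
    for i in range(n_urine):
        specs.append(
            ChemicalSpec(
                name=f"U{i}", chem_class="phthalate", matrix="urine",
                geometric_mean=gm, geometric_sd=gsd, detection_target=detection,
            )
        )
    for i in range(n_serum):
        specs.append(
            ChemicalSpec(
                name=f"S{i}", chem_class="PCB", matrix="serum",
                geometric_mean=gm, geometric_sd=gsd, detection_target=detection,
            )
        )
    return specs


def small_config(seed: int, n: int = 200, **kw) -> CohortConfig:
    defaults = dict(
        n_subjects=n,
        chemicals=make_specs(),
        confounder_effects={},
        dropout_model={"intercept": 20.0},
        seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no true effects, full follow-up, small panel."""
    from mixshrink.cohort import generate_cohort

    return generate_cohort(small_config(seed=42, n=250))
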