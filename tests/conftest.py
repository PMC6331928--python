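from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from megamet.data_model import CovariateSpec, IPDDataset, validate_for_analysis
from megamet.synthetic import ScenarioConfig, generate_cohorts


@pytest.fixture
def nocov_spec() -> CovariateSpec:
    """Unadjusted two-group comparison (no covariates in the design)."""
    return CovariateSpec("thickness", covariates_override=())


@pytest.fixture
def thickness_spec() -> CovariateSpec:
    return CovariateSpec("thickness")


def make_dataset(
    rows: list[tuple], rois: list[tuple[str, str]] | None = None
) -> IPDDataset:
    """Dataset from (cohort, dx, age, sex, icv, roi...) tuples."""
    rois = rois or [("roi", "thickness")]
    cols = ["cohort", "dx", "age", "sex", "icv"] + [n for n, _ in rois]
    return IPDDataset(pd.DataFrame(rows, columns=cols), rois)


def simulated_subset(
    spec: CovariateSpec,
    cohort_sizes=((10, 10),) * 5,
    seed: int = 0,
    min_cohort_n: int = 2,
    **cfg_kw,
):
    """Generate a scenario and return its analysis-ready subset."""
    cfg = ScenarioConfig(cohort_sizes=tuple(cohort_sizes), seed=seed, **cfg_kw)
    ds = generate_cohorts(cfg)
    return validate_for_analysis(ds, "roi", spec, min_cohort_n=min_cohort_n)
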