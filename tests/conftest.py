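import numpy as np
import pandas as pd
import pytest

from heatattr import (
    GeneratorConfig,
    add_calendar_covariates,
    build_design,
    compute_rate,
    fit_smooth,
    generate_dataset,
    impute_suppressed,
)


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(config):
    return generate_dataset(config)


@pytest.fixture(scope="session")
def records(dataset):
    """Imputed factual table with calendar covariates."""
    return add_calendar_covariates(impute_suppressed(dataset["factual"]))


@pytest.fixture(scope="session")
def rates(records):
    return compute_rate(records["hri_count"].to_numpy(), records["population"].to_numpy())


@pytest.fixture(scope="session")
def gamma_fit(records, rates):
    """Full exposure-response fit (spline + dow/month/year)."""
    design = build_design(
        records["tmax"].to_numpy(), n_basis=4,
        covariates=records[["dow", "month", "year"]],
    )
    return fit_smooth(rates, design, family="gamma")


@pytest.fixture(scope="session")
def reduced_fit(records, rates):
    """Covariate-free (projection) fit."""
    design = build_design(records["tmax"].to_numpy(), n_basis=3)
    return fit_smooth(rates, design, family="gamma")


@pytest.fixture()
def daily_csv(tmp_path):
    """A small handwritten daily-series CSV with one suppressed day."""
    p = tmp_path / "daily.csv"
    p.write_text(
        "date,region,tmax_c,tmin_c,tmean_c,tdew_c,hri_count,population\n"
        "2015-06-12,coastal,33.1,24.1,28.6,22.0,7,4000000\n"
        "2015-06-13,coastal,30.5,21.5,26.0,21.0,,4000000\n"
        "2015-06-14,coastal,35.0,26.0,30.5,23.5,12,4000000\n"
    )
    return p
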