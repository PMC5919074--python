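"""Shared fixtures for the engine-vs-reference SEM agreement checks."""

import pandas as pd
import pytest

from ecoimmune.sem import default_models, fit_ml
from ecoimmune.simulate import SyntheticConfig, gen_cohort
from reference_sem import reference_fit

#: five fixed seeded datasets spanning the three compartment models
CASES = [
    (101, "adaptive"),
    (102, "adaptive"),
    (103, "innate"),
    (104, "humoral"),
    (105, "adaptive"),
]


def dataset(seed: int, model_name: str) -> pd.DataFrame:
    cfg = SyntheticConfig(seed=seed, site_sizes={"HW": 500},
                          site_sd={"adaptive": 0, "innate": 0, "humoral": 0})
    records, truth = gen_cohort(cfg)
    indicators = default_models()[model_name].latents["immune_state"]
    rows = []
    for r in records:
        row = {
            "season": r.day_length / 100.0,
            "age": r.age,
            "infection": r.infection_burden(),
            "condition": truth.condition[r.mouse_id],
        }
        for ind in indicators:
            row[ind] = truth.indicator_core[ind][r.mouse_id]
        rows.append(row)
    return pd.DataFrame(rows)


def assert_engine_matches_reference(seed: int, model_name: str,
                                    tol: float = 1e-3) -> None:
    spec = default_models()[model_name]
    data = dataset(seed, model_name)
    fit = fit_ml(spec, data, rescale=False, seed=0, n_starts=2)
    ref = reference_fit(spec, data, seed=0, n_starts=2)
    est = {e.name: e.estimate for e in fit.estimates}
    for name, value in zip(ref["names"], ref["theta"]):
        assert est[name] == pytest.approx(value, abs=tol), name
    assert fit.chi2 == pytest.approx(ref["chi2"], abs=tol)
    assert fit.cfi == pytest.approx(ref["cfi"], abs=tol)
    assert fit.srmr == pytest.approx(ref["srmr"], abs=tol)
    assert fit.rmsea == pytest.approx(ref["rmsea"], abs=tol)
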