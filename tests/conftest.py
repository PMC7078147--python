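import numpy as np
import pytest

from lesiondyn import (LesionRecord, LesionSeries, PatientCovariates,
                       SimConfig, build_series, preprocess, simulate_trial)


def series(pid, lid, times, sizes, organ="LIVER", ltype="metastatic"):
    return LesionSeries(pid, lid, np.asarray(times, float),
                        np.asarray(sizes, float), organ, ltype)


@pytest.fixture
def small_trial():
    """One deterministic synthetic trial, preprocessed."""
    cfg = SimConfig(n_patients=120, seed=3)
    records, covariates, truth = simulate_trial(cfg)
    kept, _ = preprocess(records, covariates)
    return {
        "config": cfg,
        "records": records,
        "kept": kept,
        "covariates": covariates,
        "truth": truth,
        "series": build_series(kept),
    }


@pytest.fixture
def toy_records():
    """Two patients, hand-sized records."""
    rows = [
        ("P1", "L1", "LIVER", "metastatic", 0.0, 30.0),
        ("P1", "L1", "LIVER", "metastatic", 8.0, 20.0),
        ("P1", "L2", "LUNG", "metastatic", 0.0, 10.0),
        ("P1", "L2", "LUNG", "metastatic", 8.0, 5.0),
        ("P2", "L1", "PARA-AORTIC LYMPH NODE", "node", 0.0, 15.0),
        ("P2", "L1", "PARA-AORTIC LYMPH NODE", "node", 8.0, 12.0),
        ("P2", "L1", "PARA-AORTIC LYMPH NODE", "node", 16.0, 10.0),
    ]
    return [LesionRecord(p, l, o, t, tt, s, "SLD")
            for p, l, o, t, tt, s in rows]


@pytest.fixture
def toy_covariates():
    return [
        PatientCovariates("P1", "cetuximab", "wt", "fully_active", 80.0, 1),
        PatientCovariates("P2", "control", "mut", "not_fully_active", 60.0, 0),
    ]
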