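from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nicheshift.pipeline import CohortSpec, RunConfig, _window_mean_env, analyse_species, derive_seed
from nicheshift.preprocess import clean_pipeline, extract_env
from nicheshift.synthetic import VirtualSpeciesTruth, generate_climate_stack, generate_virtual_species


@pytest.fixture(scope="session")
def small_stack():
    """A modest 5-layer stack for unit tests."""
    return generate_climate_stack(5, 30, 30, correlation=0.4, seed=11)


@pytest.fixture(scope="session")
def cohort_stack():
    """The stack used by the default simulated cohort (seed 0)."""
    spec = CohortSpec()
    return generate_climate_stack(
        n_layers=spec.n_layers,
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        x_origin=spec.extent[0],
        y_origin=spec.extent[3],
        correlation=spec.correlation,
        seed=derive_seed(spec.seed, "stack"),
    )


@pytest.fixture(scope="session")
def cohort_geometry(cohort_stack):
    """(native window, non-native window, native-mean centre, shift direction)."""
    spec = CohortSpec()
    nat_mean = _window_mean_env(cohort_stack, spec.native_window)
    non_mean = _window_mean_env(cohort_stack, spec.nonnative_window)
    u = non_mean - nat_mean
    u = u / np.linalg.norm(u)
    return spec.native_window, spec.nonnative_window, nat_mean, u


def run_virtual_species(
    stack,
    geometry,
    shift_mag: float,
    target_expansion: float,
    seed: int,
    n_native: int = 200,
    n_nonnative: int = 100,
    equivalency_reps: int = 0,
) -> dict:
    """Generate one virtual species and push it through the niche-shift stage."""
    native_window, nonnative_window, center, direction = geometry
    truth = VirtualSpeciesTruth(
        niche_center=center,
        niche_breadth=np.ones(stack.n_layers),
        shift_delta=shift_mag * direction,
        target_expansion=target_expansion,
        seed=seed,
    )
    occ = generate_virtual_species(
        stack, truth, native_window, nonnative_window, n_native, n_nonnative,
        species_id="sp",
    )
    cleaned, _ = clean_pipeline(occ, stack)
    occ_nat = cleaned[cleaned["status"] == "native"]
    occ_non = cleaned[cleaned["status"] == "nonnative"]
    env_nat, occ_nat = extract_env(occ_nat, stack)
    env_non, occ_non = extract_env(occ_non, stack)
    cfg = RunConfig(equivalency_reps=equivalency_reps, seed=seed)
    row, _ = analyse_species("sp", env_nat, env_non, occ_nat, occ_non, stack, cfg)
    return row


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def occ_table():
    """A tiny hand-built occurrence table."""
    return pd.DataFrame(
        {
            "species": ["a"] * 3 + ["b"] * 2,
            "status": ["native", "native", "nonnative", "native", "nonnative"],
            "lon": [1.2, 3.4, 5.6, 7.8, 9.1],
            "lat": [2.1, 4.3, 6.5, 8.7, 1.9],
        }
    )
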