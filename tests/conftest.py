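import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from nichecast import maxent, synthetic  # noqa: E402


@pytest.fixture(scope="session")
def small_scenario():
    """An 80×80 synthetic landscape with a fitted lqh model.

    Shared by every test that needs a realistic fitted model but not the
    full-size recovery scenario; all seeds fixed.
    """
    cfg = synthetic.LandscapeConfig(n_rows=80, n_cols=80, smoothness=5.0, seed=11)
    stack, truth = synthetic.make_landscape(cfg)
    truth_raster = synthetic.true_suitability(truth, stack)
    occ = synthetic.sample_occurrences(truth_raster, 250, seed=12)
    rows, cols = stack.grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    presence_env = stack.env_table(rows, cols)
    background_env, _, _ = maxent.sample_background(stack, 2000, seed=13)
    model = maxent.fit(presence_env, background_env, maxent.FeatureSpec("lqh", 1.0))
    return {
        "config": cfg, "stack": stack, "truth": truth,
        "truth_raster": truth_raster, "occurrences": occ,
        "presence_env": presence_env, "background_env": background_env,
        "model": model,
    }


@pytest.fixture(scope="session")
def standard_scenario():
    """The full-size (200×200, 500 presences, 10k background) scenario."""
    cfg = synthetic.LandscapeConfig(seed=42)
    stack, truth = synthetic.make_landscape(cfg)
    truth_raster = synthetic.true_suitability(truth, stack)
    occ = synthetic.sample_occurrences(truth_raster, 500, seed=7)
    rows, cols = stack.grid.cell_index(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    presence_env = stack.env_table(rows, cols)
    background_env, _, _ = maxent.sample_background(stack, 10000, seed=3)
    model = maxent.fit(presence_env, background_env, maxent.FeatureSpec("lqh", 1.0))
    all_rows, all_cols = stack.data_cells()
    return {
        "config": cfg, "stack": stack, "truth": truth,
        "truth_raster": truth_raster, "occurrences": occ,
        "presence_env": presence_env, "background_env": background_env,
        "model": model, "all_rows": all_rows, "all_cols": all_cols,
        "all_env": stack.env_table(all_rows, all_cols),
    }
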