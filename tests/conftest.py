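import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_frame(sessions, player_id="p1", stake_cents=None, rt=None, latency=5000.0):
    """Build a tracking frame from per-session outcome strings.

    *sessions* is a list of strings over {"W", "L"}; optional parallel
    lists *stake_cents* / *rt* give per-round stakes and first-column RTs.
    """
    rows = []
    for s_idx, outcomes in enumerate(sessions):
        for r_idx, oc in enumerate(outcomes):
            k = len(rows)
            rows.append(
                {
                    "player_id": player_id,
                    "session_id": f"{player_id}-s{s_idx + 1}",
                    "round_id": f"{player_id}-r{k + 1}",
                    "round_index": r_idx + 1,
                    "stake_cents": stake_cents[s_idx][r_idx] if stake_cents else 100,
                    "win_cents": 200 if oc == "W" else 0,
                    "start_latency_ms": np.nan if r_idx == 0 else latency,
                    "first_column_rt_ms": rt[s_idx][r_idx] if rt else 1000.0,
                    "bonus": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def make_tracking_frame():
    return make_frame


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    from chasekit.simulate import default_sim_config, generate_dataset

    cfg = default_sim_config(seed=42, n_high=40, n_low=40)
    tracking, truth = generate_dataset(cfg)
    groups = truth.set_index("player_id")["group"]
    return tracking, truth, groups
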