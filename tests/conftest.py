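import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def prescribing_frame(rows):
    """Rows of (org, group, month, product, dose, quantity, cost)."""
    return pd.DataFrame(
        rows,
        columns=[
            "org_id", "group_id", "month", "product_id", "dose_id",
            "quantity", "actual_cost",
        ],
    )


def listsize_frame(rows):
    """Rows of (org, month, list_size)."""
    return pd.DataFrame(rows, columns=["org_id", "month", "list_size"])


def pageview_frame(rows):
    """Rows of (org_kind, org_id, month, feature, views)."""
    return pd.DataFrame(
        rows, columns=["org_kind", "org_id", "month", "feature", "views"]
    )


@pytest.fixture
def two_org_records():
    return prescribing_frame(
        [
            ("A", "G1", "2017-01", "P1", "d0", 100, 20.0),
            ("A", "G1", "2017-01", "P2", "d0", 50, 100.0),
            ("B", "G1", "2017-01", "P1", "d0", 200, 80.0),
            ("B", "G1", "2017-01", "P2", "d0", 10, 15.0),
        ]
    )


@pytest.fixture
def tiny_sim_config():
    """Small but structurally complete simulated study."""
    from rxpanel import SimulationConfig

    return SimulationConfig(
        n_groups=4,
        practices_per_group=5,
        n_months=10,
        n_products=10,
        view_start_month=4,
        seed=11,
    )
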