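"""Shared fixtures: small synthetic studies and a reference network table."""

import numpy as np
import pandas as pd
import pytest

import wandernet as wn

# Reference sensorimotor network: a published 26-connection network over 19
# cortical regions (atlas label, hemisphere, MNI mm), used as a known-answer
# fixture for component extraction and file round-trips.
REFERENCE_NODES = [
    # (label, hemisphere, x, y, z)
    ("Postcentral gyrus 02", "L", -14.58, -39.62, 65.78),
    ("Postcentral gyrus 05", "L", -7.87, -39.27, 74.46),
    ("Precentral Gyrus 15", "L", -5.52, -19.86, 71.55),
    ("Superior Parietal Lobule 08", "L", -27.92, -34.42, 53.87),
    ("Superior Parietal Lobule 09", "L", -15.42, -34.39, 75.06),
    ("Superior Parietal Lobule 14", "L", -17.66, -51.44, 65.96),
    ("Juxtapositional Lobule Cortex (Supplementary Motor Cortex) 01", "R",
     6.69, -4.86, 52.19),
    ("Postcentral gyrus 02", "R", 15.39, -39.74, 65.79),
    ("Postcentral gyrus 04", "R", 26.43, -34.79, 65.50),
    ("Postcentral gyrus 05", "R", 8.60, -39.46, 74.54),
    ("Postcentral gyrus 15", "R", 16.36, -34.54, 74.80),
    ("Precentral Gyrus 02", "R", 25.84, -20.87, 53.10),
    ("Precentral Gyrus 04", "R", 11.02, -27.78, 60.74),
    ("Precentral Gyrus 06", "R", 15.00, -23.75, 73.83),
    ("Precentral Gyrus 07", "R", 5.18, -22.09, 53.40),
    ("Precentral Gyrus 12", "R", 25.82, -19.77, 65.74),
    ("Precentral Gyrus 13", "R", 36.76, -14.45, 62.96),
    ("Superior Frontal Gyrus 02", "R", 19.68, -5.47, 68.98),
    ("Superior Parietal Lobule 04", "R", 18.76, -51.26, 65.97),
]

REFERENCE_CONNECTIONS = [
    (("R", "Precentral Gyrus 02"), ("R", "Precentral Gyrus 13")),
    (("R", "Superior Frontal Gyrus 02"), ("R", "Postcentral gyrus 05")),
    (("R", "Precentral Gyrus 06"), ("R", "Postcentral gyrus 05")),
    (("R", "Postcentral gyrus 02"), ("R", "Postcentral gyrus 05")),
    (("R", "Superior Frontal Gyrus 02"), ("R", "Postcentral gyrus 15")),
    (("R", "Postcentral gyrus 05"), ("R", "Postcentral gyrus 15")),
    (("R", "Precentral Gyrus 02"), ("R", "Superior Parietal Lobule 04")),
    (("R", "Postcentral gyrus 04"), ("R", "Superior Parietal Lobule 04")),
    (("R", "Precentral Gyrus 02"),
     ("R", "Juxtapositional Lobule Cortex (Supplementary Motor Cortex) 01")),
    (("R", "Precentral Gyrus 04"),
     ("R", "Juxtapositional Lobule Cortex (Supplementary Motor Cortex) 01")),
    (("R", "Precentral Gyrus 07"),
     ("R", "Juxtapositional Lobule Cortex (Supplementary Motor Cortex) 01")),
    (("R", "Postcentral gyrus 02"),
     ("R", "Juxtapositional Lobule Cortex (Supplementary Motor Cortex) 01")),
    (("R", "Postcentral gyrus 02"), ("L", "Precentral Gyrus 15")),
    (("R", "Postcentral gyrus 05"), ("L", "Precentral Gyrus 15")),
    (("R", "Postcentral gyrus 15"), ("L", "Precentral Gyrus 15")),
    (("R", "Postcentral gyrus 05"), ("L", "Postcentral gyrus 02")),
    (("R", "Postcentral gyrus 05"), ("L", "Postcentral gyrus 05")),
    (("R", "Precentral Gyrus 02"), ("L", "Superior Parietal Lobule 08")),
    (("R", "Postcentral gyrus 05"), ("L", "Superior Parietal Lobule 09")),
    (("L", "Precentral Gyrus 15"), ("L", "Superior Parietal Lobule 09")),
    (("R", "Precentral Gyrus 04"), ("L", "Superior Parietal Lobule 14")),
    (("R", "Precentral Gyrus 12"), ("L", "Superior Parietal Lobule 14")),
    (("R", "Postcentral gyrus 02"), ("L", "Superior Parietal Lobule 14")),
    (("R", "Postcentral gyrus 04"), ("L", "Superior Parietal Lobule 14")),
    (("R", "Postcentral gyrus 05"), ("L", "Superior Parietal Lobule 14")),
    (("R", "Postcentral gyrus 15"), ("L", "Superior Parietal Lobule 14")),
]


@pytest.fixture(scope="session")
def reference_node_table() -> pd.DataFrame:
    return pd.DataFrame(
        REFERENCE_NODES, columns=["label", "hemisphere", "x", "y", "z"]
    )


@pytest.fixture(scope="session")
def reference_edges(reference_node_table) -> list:
    """The 26 reference connections as canonical 0-based index pairs."""
    key = {
        (h, l): i
        for i, (l, h) in enumerate(
            zip(reference_node_table["label"], reference_node_table["hemisphere"])
        )
    }
    return sorted(
        tuple(sorted((key[a], key[b]))) for a, b in REFERENCE_CONNECTIONS
    )


@pytest.fixture(scope="session")
def small_study():
    """One deterministic 19-subject study with a planted 6-node clique."""
    params = wn.SimParams(n_subjects=19, n_nodes=24, seed=11, beta=0.25)
    truth, table, stack = wn.simulate_study(params, score_component=1)
    return params, truth, table, stack


@pytest.fixture(scope="session")
def fitted_mfa(small_study):
    _, _, table, _ = small_study
    return wn.MFA(n_components=3).fit(table)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
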