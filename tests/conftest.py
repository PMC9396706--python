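"""Shared fixtures: reference sigmoid parameter sets and small synthetic
tracks.

The reference parameter tables are published single- and double-sigmoid fits
for individual satellite-tracked cormorants (asymptote delta in km^2,
midpoints theta in day-of-year, time scales phi in days); curves generated
from them are the recovery targets of the fitting tests.
"""

import numpy as np
import pandas as pd
import pytest

# single-sigmoid (spring-only) reference fits: id -> (delta, theta, phi)
SPRING_SIGMOID_PARAMS = {
    5: (5355946.16, 125.77, 3.64),
    16: (4721621.13, 128.40, 8.43),
    17: (2429528.95, 131.06, 5.58),
    18: (2093731.29, 130.27, 3.02),
    20: (2718863.72, 108.66, 6.02),
    21: (2433822.63, 112.55, 2.98),
    26: (2090535.46, 140.29, 7.60),
    27: (1622824.09, 129.27, 0.67),
    28: (3176429.01, 112.09, 2.30),
    33: (2658532.82, 112.02, 1.28),
    36: (1979773.66, 102.57, 1.18),
    46: (1260050.02, 114.85, 2.53),
}

# double-sigmoid (annual) reference fits:
# id -> (delta, theta_s, theta_a, phi_s, phi_a)
ANNUAL_SIGMOID_PARAMS = {
    22: (2542838.60, 135.28, 237.15, 6.14, 13.01),
    34: (1488701.72, 96.66, 295.36, 0.08, 0.45),
    47: (1861991.00, 131.11, 167.39, 0.83, 1.93),
    48: (2598861.00, 114.57, 274.45, 0.41, 6.96),
    49: (1934719.44, 96.54, 272.86, 0.27, 2.23),
    51: (2958255.99, 110.30, 262.93, 2.88, 6.92),
    52: (2376075.74, 137.44, 301.32, 1.42, 1.53),
    53: (3329986.49, 128.87, 301.01, 7.24, 5.64),
    54: (3857982.16, 122.42, 282.24, 3.37, 4.85),
}

SPRING_GRID = np.arange(1.0, 250.0 + 1e-9, 0.1)
ANNUAL_GRID = np.arange(1.0, 366.0)


@pytest.fixture(scope="session")
def spring_grid():
    return SPRING_GRID


@pytest.fixture(scope="session")
def annual_grid():
    return ANNUAL_GRID


def make_track(lonlat, start="2001-01-01", step_h=1.0, animal_id="t01"):
    """Small trajectory frame from a list of (lon, lat)."""
    lonlat = np.asarray(lonlat, dtype=float)
    ts = (pd.Timestamp(start, tz="UTC")
          + pd.to_timedelta(np.arange(len(lonlat)) * step_h, unit="h"))
    return pd.DataFrame({
        "animal_id": animal_id, "timestamp": ts,
        "lon": lonlat[:, 0], "lat": lonlat[:, 1], "lc_class": pd.NA,
    })


@pytest.fixture
def small_track():
    return make_track([(-90.0, 30.0), (-90.0, 30.5), (-90.2, 31.0),
                       (-90.4, 31.6), (-90.4, 32.0)])
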