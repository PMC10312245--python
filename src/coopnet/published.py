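"""Published yearly cooperation indicators for the Kinzig valley network.

Reference values for the 2004–2017 regional patient-sharing network
(network density, mean distance, transformed mean distance, active
practices, integrated practices, total patients), used to validate the
average-percentage-change summary against a published benchmark.  The
underlying claims data are proprietary; only these yearly aggregates are
public, so they serve as fixed reference inputs, not as test fixtures
derived from this package.

Note the density column: the published average change (1.40%) was computed
on unrounded densities, while recomputation from the 3-decimal printed
values gives ~1.44%; the density average is therefore only reproducible
approximately.  The 2017 transformed mean distance is 14.73 per the
published table (narrative text elsewhere cites 14.03; the table is treated
as authoritative).
"""

import pandas as pd

__all__ = ["reference_network_summary", "REFERENCE_AVERAGE_CHANGE"]

_YEARS = list(range(2004, 2018))

_DATA = {
    "density": [0.136, 0.151, 0.137, 0.139, 0.144, 0.151, 0.161,
                0.157, 0.144, 0.150, 0.153, 0.162, 0.152, 0.160],
    "mean_distance": [2.089, 2.020, 2.007, 1.995, 1.922, 1.933, 1.893,
                      1.879, 1.923, 1.888, 1.877, 1.881, 1.890, 1.884],
    "transformed_mean_distance": [35.03, 36.60, 29.00, 25.73, 16.81, 24.77,
                                  17.30, 10.61, 18.19, 10.97, 8.82, 14.25,
                                  13.86, 14.73],
    "n_nodes": [197, 192, 217, 209, 225, 221, 218, 222, 229, 228, 230,
                220, 234, 225],
    "n_ip_nodes": [28, 29, 37, 33, 37, 35, 35, 35, 34, 34, 36, 35, 36, 36],
    "n_patients": [25979, 26491, 27360, 27621, 27209, 27408, 27306, 27804,
                   28032, 28612, 28151, 28487, 28999, 29421],
}

#: Published average-percentage-change row (percent per year).  The density
#: figure was computed on unrounded data (see module docstring).
REFERENCE_AVERAGE_CHANGE = {
    "density": 1.40,
    "mean_distance": -0.78,
    "transformed_mean_distance": -0.50,
    "n_nodes": 1.15,
    "n_ip_nodes": 2.32,
    "n_patients": 0.97,
}


def reference_network_summary() -> pd.DataFrame:
    """The published per-year network-level indicator table (2004–2017)."""
    return pd.DataFrame(_DATA, index=pd.Index(_YEARS, name="year"))
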