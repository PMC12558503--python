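"""Packaged benchmark lifetime datasets and plain-text sample readers.

Five classical engineering reliability datasets ship with the package,
stored as exact decimal strings (parsed at load time, so no float
transcription drift):

- ``service_time`` — 63 recorded service times of aircraft windshields;
- ``carbon_fiber_stress`` — 100 breaking stresses of carbon fibres (GPa);
- ``tensile_strength`` — 69 tensile strengths of carbon fibres;
- ``gauge20`` — 69 strengths of single fibres at 20 mm gauge length;
- ``gauge50`` — 69 strengths of single fibres at 50 mm gauge length.

Note ``gauge50``: the final value 2.262 appears after 2.835, 2.835 in the
original listing, i.e. out of sort order; it is retained verbatim (samples
are sorted on ingestion, so ordering of the source listing is immaterial).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distribution import LifetimeSample

__all__ = ["DATASETS", "load_dataset", "read_sample", "write_sample", "dataset_keys"]

_SERVICE_TIME = """
0.046 1.436 2.592 0.140 1.492 2.600 0.150 1.580 2.670 0.248 1.719 2.717
0.280 1.794 2.819 0.313 1.915 2.820 0.389 1.920 2.878 0.487 1.963 2.950
0.622 1.978 3.003 0.900 2.053 3.102 0.952 2.065 3.304 0.996 2.117 3.483
1.003 2.137 3.500 1.010 2.141 3.622 1.085 2.163 3.665 1.092 2.183 3.695
1.152 2.240 4.015 1.183 2.341 4.628 1.244 2.435 4.806 1.249 2.464 4.881
1.262 2.543 5.140
"""

_CARBON_FIBER = """
3.70 2.74 2.73 2.50 3.60 3.11 3.27 2.87 1.47 3.11 4.42 2.41 3.19
3.22 1.69 3.28 3.09 1.87 3.15 4.90 3.75 2.43 2.95 2.97 3.39 2.96
2.53 2.67 2.93 3.22 3.39 2.81 4.20 3.33 2.55 3.31 3.31 2.85 2.56
3.56 3.15 2.35 2.55 2.59 2.38 2.81 2.77 2.17 2.83 1.92 1.41 3.68
2.97 1.36 0.98 2.76 4.91 3.68 1.84 1.59 3.19 1.57 0.81 5.56 1.73
1.59 2.00 1.22 1.12 1.71 2.17 1.17 5.08 2.48 1.18 3.51 2.17 1.69
1.25 4.38 1.84 0.39 3.68 2.48 0.85 1.61 2.79 4.70 2.03 1.80 1.57
1.08 2.03 1.61 2.12 1.89 2.88 2.82 2.05 3.65
"""

_TENSILE_STRENGTH = """
0.312 0.314 0.479 0.552 0.700 0.803 0.861 0.865 0.944 0.958 0.966 0.997
1.006 1.021 1.027 1.055 1.063 1.098 1.140 1.179 1.224 1.240 1.253 1.270
1.272 1.274 1.301 1.301 1.359 1.382 1.382 1.426 1.434 1.435 1.478 1.490
1.511 1.514 1.535 1.554 1.566 1.570 1.586 1.629 1.633 1.642 1.648 1.684
1.697 1.726 1.770 1.773 1.800 1.809 1.818 1.821 1.848 1.880 1.954 2.012
2.067 2.084 2.090 2.096 2.128 2.233 2.433 2.585 2.585
"""

_GAUGE20 = """
1.312 1.314 1.479 1.552 1.7 1.803 1.861 1.865 1.944 1.958 1.966 1.997
2.006 2.021 2.027 2.055 2.063 2.098 2.14 2.179 2.224 2.24 2.253 2.27
2.272 2.274 2.301 2.301 2.359 2.382 2.382 2.426 2.434 2.435 2.478 2.49
2.511 2.514 2.535 2.554 2.566 2.57 2.586 2.629 2.633 2.642 2.648 2.684
2.697 2.726 2.77 2.773 2.8 2.809 2.818 2.821 2.848 2.88 2.954 3.012
3.067 3.084 3.09 3.096 3.128 3.233 3.433 3.585 3.858
"""

_GAUGE50 = """
0.562 0.564 0.729 0.802 0.95 1.053 1.111 1.115 1.194 1.208 1.216 1.247
1.256 1.271 1.277 1.305 1.313 1.348 1.39 1.429 1.474 1.49 1.503 1.52
1.522 1.524 1.551 1.551 1.609 1.632 1.632 1.676 1.684 1.685 1.728 1.74
1.761 1.764 1.785 1.804 1.816 1.824 1.836 1.879 1.883 1.892 1.898 1.934
1.947 1.976 2.02 2.023 2.05 2.059 2.068 2.071 2.098 2.13 2.204 2.317
2.334 2.34 2.346 2.378 2.483 2.683 2.835 2.835 2.262
"""


@dataclass(frozen=True)
class DatasetRegistryEntry:
    key: str
    description: str
    expected_n: int
    raw: str

    def values(self) -> np.ndarray:
        vals = np.array([float(tok) for tok in self.raw.split()])
        if vals.size != self.expected_n:
            raise RuntimeError(
                f"dataset {self.key!r}: packaged listing has {vals.size} "
                f"values, expected {self.expected_n}"
            )
        if np.any(vals <= 0):
            raise RuntimeError(f"dataset {self.key!r}: nonpositive value in listing")
        return vals


DATASETS = {
    "service_time": DatasetRegistryEntry(
        "service_time", "service times of 63 aircraft windshields", 63, _SERVICE_TIME
    ),
    "carbon_fiber_stress": DatasetRegistryEntry(
        "carbon_fiber_stress", "breaking stress of 100 carbon fibres", 100, _CARBON_FIBER
    ),
    "tensile_strength": DatasetRegistryEntry(
        "tensile_strength", "tensile strength of 69 carbon fibres", 69, _TENSILE_STRENGTH
    ),
    "gauge20": DatasetRegistryEntry(
        "gauge20", "strength of 69 single fibres, 20 mm gauge length", 69, _GAUGE20
    ),
    "gauge50": DatasetRegistryEntry(
        "gauge50", "strength of 69 single fibres, 50 mm gauge length", 69, _GAUGE50
    ),
}


def dataset_keys():
    return list(DATASETS)


def load_dataset(key: str) -> LifetimeSample:
    """Return a packaged benchmark dataset as a validated LifetimeSample."""
    try:
        entry = DATASETS[key]
    except KeyError:
        raise KeyError(
            f"unknown dataset {key!r}; available: {', '.join(DATASETS)}"
        ) from None
    return LifetimeSample(entry.values(), name=key)


def read_sample(path, column=None, name=None) -> LifetimeSample:
    """Read a univariate sample from a single-column text or CSV file.

    ``column`` may be a header name or integer position; headerless
    whitespace/comma separated files work with the default.  Blank and NA
    rows are dropped; nonpositive or nonnumeric entries raise with the
    offending rows listed.
    """
    df = pd.read_csv(path)
    # single unnamed numeric column files get read with the first value as
    # header; re-read headerless if the inferred header parses as a number
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, header=None)
    except ValueError:
        pass
    if column is None:
        col = df.columns[0]
    elif isinstance(column, int):
        col = df.columns[column]
    else:
        col = column
    ser = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[ser.isna() & df[col].notna()]
    if len(bad):
        raise ValueError(f"nonnumeric entries at rows {list(bad)}")
    ser = ser.dropna()
    neg = ser.index[ser <= 0]
    if len(neg):
        raise ValueError(f"nonpositive entries at rows {list(neg)}")
    return LifetimeSample(ser.to_numpy(), name=name or str(path))


def write_sample(sample: LifetimeSample, path) -> None:
    """Write a sample as a single-column CSV with header ``time``."""
    pd.DataFrame({"time": sample.values}).to_csv(path, index=False)
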