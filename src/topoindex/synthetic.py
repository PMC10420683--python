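"""Synthetic descriptor/property data with known ground truth.

The experimental property inputs of the source study (chromatographic R_MW
and calculator logP values) were published elsewhere and are not printed in
the study itself, so the regression pipeline is validated on generated data
carrying the statistical structure the analysis assumes: one property column
exactly linear in a descriptor plus homoscedastic Gaussian noise, alongside
independent noise columns.  Default planted parameters echo the magnitude of
the study's printed logP-W equation (slope 0.00599, intercept -1.060) and the
descriptor range defaults to the span of the published Wiener column
(76.8-1749.2), so recovery tests run at realistic conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: span of the published Wiener index column across the ten study compounds
DEFAULT_X_RANGE = (76.8, 1749.2)


@dataclass
class SyntheticQSPRDataset:
    descriptors: pd.DataFrame  # one descriptor column "x"
    properties: pd.DataFrame  # planted column "y" + noise columns
    truth: dict  # {"slope","intercept","noise_sd"} of the planted column
    seed: int


def generate_qspr(n_compounds: int = 10, slope: float = 0.00599,
                  intercept: float = -1.060, noise_sd: float = 0.1,
                  n_noise_columns: int = 10, seed: int = 0,
                  x_range: tuple[float, float] = DEFAULT_X_RANGE,
                  ) -> SyntheticQSPRDataset:
    """One planted linear property plus independent noise properties.

    The descriptor is drawn uniformly over ``x_range``; the planted property
    is ``intercept + slope*x + Normal(0, noise_sd)``; noise columns are
    standard normal, independent of the descriptor.
    """
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_noise_columns < 0:
        raise ValueError("n_noise_columns must be >= 0")
    rng = np.random.default_rng(seed)
    names = [f"cmpd{i:03d}" for i in range(n_compounds)]
    x = rng.uniform(*x_range, size=n_compounds)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n_compounds)
    props = {"y": y}
    for j in range(n_noise_columns):
        props[f"noise{j:02d}"] = rng.normal(size=n_compounds)
    return SyntheticQSPRDataset(
        descriptors=pd.DataFrame({"x": x}, index=names),
        properties=pd.DataFrame(props, index=names),
        truth={"slope": slope, "intercept": intercept, "noise_sd": noise_sd},
        seed=seed,
    )


def generate_cluster_blobs(n_per_blob: int = 5, n_dims: int = 11,
                           separation: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """Two unit-variance Gaussian groups whose means are ``separation``
    standard deviations apart along the first axis.

    Row labels encode the true group ("A#"/"B#") for recovery checks.
    """
    if n_per_blob < 2:
        raise ValueError("need at least 2 points per blob")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per_blob, n_dims))
    b = rng.normal(size=(n_per_blob, n_dims))
    b[:, 0] += separation
    data = np.vstack([a, b])
    names = [f"A{i}" for i in range(n_per_blob)] + [f"B{i}" for i in range(n_per_blob)]
    return pd.DataFrame(data, index=names,
                        columns=[f"d{j}" for j in range(n_dims)])
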