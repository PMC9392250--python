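"""Model specification and design-matrix construction.

The repeatability animal model is  y = Xb + Za + Wpe + e : X holds the
fixed factors (reference coding, first observed level dropped) and linear
covariates, Z maps records to all pedigree animals, W maps records to the
animals that have records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree import Pedigree

__all__ = ["ModelSpec", "DesignMatrices", "build_design"]


@dataclass
class ModelSpec:
    """Trait and effect structure of the repeatability model."""

    trait: str = "y"
    factors: list[str] = field(
        default_factory=lambda: ["farm_year", "parity", "stage", "milking"]
    )
    covariates: list[str] = field(default_factory=lambda: ["thi"])


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    Za: sp.csr_matrix  # records x all pedigree animals
    Wpe: sp.csr_matrix  # records x recorded animals
    x_columns: list[str]
    animal_ids: np.ndarray  # pedigree order, columns of Za
    recorded_ids: np.ndarray  # columns of Wpe

    @property
    def n_records(self) -> int:
        return len(self.y)


def build_design(records: pd.DataFrame, spec: ModelSpec, ped: Pedigree) -> DesignMatrices:
    """Build (y, X, Z, W) from a record table against a pedigree.

    Every record's animal must exist in the pedigree; factor levels with no
    records are dropped (with a warning when the level was declared
    categorically), and X is full rank through reference coding.
    """
    for col in [spec.trait, "animal", *spec.factors, *spec.covariates]:
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    rec = records.reset_index(drop=True)
    y = rec[spec.trait].to_numpy(dtype=float)
    n = len(rec)

    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for f in spec.factors:
        cat = pd.Categorical(rec[f])
        if len(cat.categories) != len(pd.unique(cat)):
            unused = set(cat.categories) - set(pd.unique(cat.remove_unused_categories()))
            if unused:
                warnings.warn(f"factor {f}: dropping empty levels {sorted(map(str, unused))}",
                              stacklevel=2)
        cat = cat.remove_unused_categories()
        d = pd.get_dummies(cat, drop_first=True)
        cols.append(d.to_numpy(dtype=float))
        names.extend([f"{f}[{lvl}]" for lvl in d.columns])
    for c in spec.covariates:
        cols.append(rec[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    X = np.hstack(cols)

    animal_rows = ped.indices_of(rec["animal"].to_numpy())
    Za = sp.csr_matrix(
        (np.ones(n), (np.arange(n), animal_rows)), shape=(n, ped.n)
    )
    recorded_rows, w_col = np.unique(animal_rows, return_inverse=True)
    Wpe = sp.csr_matrix(
        (np.ones(n), (np.arange(n), w_col)), shape=(n, len(recorded_rows))
    )
    return DesignMatrices(
        y=y, X=X, Za=Za, Wpe=Wpe, x_columns=names,
        animal_ids=ped.ids, recorded_ids=ped.ids[recorded_rows],
    )
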