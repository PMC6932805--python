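"""Principal-component ordination of site environmental variables.

Bioclimatic and soil variables mix units (°C, mm, fractions), so the
ordination is run on the correlation structure: each variable is centred
and scaled to unit sample SD before the singular-value decomposition.
Constant variables are undefined under scaling and are dropped with a
warning; missing values are mean-imputed (count logged).  Component signs
are fixed so the largest-magnitude loading of each component is positive,
making outputs deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Ordination:
    """PCA scores, variable loadings and per-component variance proportions."""

    scores: pd.DataFrame  # rows × components
    loadings: pd.DataFrame  # variables × components
    proportion: pd.Series  # variance proportion per component (sums to 1)
    dropped: list[str]
    n_imputed: int

    def to_tsv(self, scores_path, loadings_path) -> None:
        self.scores.to_csv(scores_path, sep="\t", index_label="row")
        self.loadings.to_csv(loadings_path, sep="\t", index_label="variable")


def read_env_table(path, id_column: str | None = None) -> pd.DataFrame:
    """Read a site (or site-year) × environmental-variable CSV.

    The identifier column (first column by default) becomes the index; all
    remaining columns must be numeric environmental variables.
    """
    raw = pd.read_csv(path)
    if id_column is None:
        id_column = raw.columns[0]
    env = raw.set_index(id_column)
    env = env.apply(pd.to_numeric, errors="coerce")
    return env


def ordinate_environment(env: pd.DataFrame, n_components: int | None = None) -> Ordination:
    """Correlation-matrix PCA of an environmental table.

    Returns scores, loadings (unit-norm eigenvectors) and the proportion of
    total variance per component, ordered by decreasing variance.
    """
    if env.shape[0] < 2 or env.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 variables")
    env = env.astype(float).copy()
    n_missing = int(env.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputing %d missing environmental values", n_missing)
        env = env.fillna(env.mean())
    sd = env.std(ddof=1)
    constant = sorted(sd.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(
            f"dropping constant environmental variable(s): {constant}",
            stacklevel=2,
        )
        env = env.drop(columns=constant)
    if env.shape[1] < 1:
        raise ValueError("no non-constant variables left")
    Z = (env - env.mean()) / env.std(ddof=1)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # fix signs: largest-magnitude loading of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    proportion = var / var.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U * s)[:, :k], index=env.index, columns=comp)
    loadings = pd.DataFrame(Vt[:k].T, index=env.columns, columns=comp)
    return Ordination(
        scores=scores,
        loadings=loadings,
        proportion=pd.Series(proportion[:k], index=comp),
        dropped=constant,
        n_imputed=n_missing,
    )
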