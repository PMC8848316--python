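"""PCA species discrimination over selectable descriptor subsets.

Answers "which descriptor classes and camera views separate the species?":
z-score the selected columns, decompose by PCA, and score the separation of
species clouds with the mean silhouette coefficient on the first two
components. Components are sign-fixed (largest-magnitude loading positive)
so results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .descriptors import DESCRIPTOR_CLASSES

__all__ = ["FeatureSelection", "PCADiscrimination", "pca_discriminate"]


@dataclass(frozen=True)
class FeatureSelection:
    """Descriptor classes, camera views and day window entering the PCA."""

    classes: tuple[str, ...] = ("dimensions", "shape", "color")
    views: tuple[str, ...] = ("side", "top")
    day_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.classes) - set(DESCRIPTOR_CLASSES)
        if unknown:
            raise ValueError(f"unknown descriptor classes {sorted(unknown)}")
        if not self.classes or not self.views:
            raise ValueError("selection must include >=1 class and >=1 view")

    def columns(self) -> list[str]:
        cols = []
        for cls in self.classes:
            for c in DESCRIPTOR_CLASSES[cls]:
                if c == "Voxel":
                    # needs both views
                    if {"side", "top"} <= set(self.views):
                        cols.append(c)
                elif c.split("_", 1)[0] in self.views:
                    cols.append(c)
        return cols


@dataclass
class PCADiscrimination:
    """Scores, loadings, explained variance and the separation metric."""

    selection: FeatureSelection
    columns: list[str]
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    silhouette: float
    pairwise_silhouette: pd.DataFrame
    n_rows_dropped: int = 0


def pca_discriminate(
    table: pd.DataFrame,
    selection: FeatureSelection | None = None,
    n_components: int = 2,
    *,
    species_col: str = "species",
    day_col: str = "day",
    exclude_side_for: tuple[str, ...] = (),
) -> PCADiscrimination:
    """PCA + silhouette separation of species over a descriptor selection.

    Rows with missing values in the selected columns are dropped (logged via
    warning); constant columns are dropped. ``exclude_side_for`` blanks the
    side-view descriptors of species whose side views are uninformative
    (flat rosettes), removing those species' side contribution while keeping
    them in the analysis through top-view columns — if only side columns are
    selected those species drop out entirely.
    """
    sel = selection or FeatureSelection()
    df = table
    if sel.day_range is not None and day_col in df:
        lo, hi = sel.day_range
        df = df[(df[day_col] >= lo) & (df[day_col] <= hi)]
    cols = [c for c in sel.columns() if c in df.columns]
    missing = set(sel.columns()) - set(cols)
    if missing:
        raise ValueError(f"selected columns absent from table: {sorted(missing)}")
    if len(cols) < 2:
        raise ValueError("need >= 2 descriptor columns after selection")
    work = df[[species_col] + cols].copy()
    if exclude_side_for:
        side_cols = [c for c in cols if c.startswith("side_") or c == "Voxel"]
        work.loc[work[species_col].isin(exclude_side_for), side_cols] = np.nan
    before = len(work)
    work = work.dropna()
    dropped = before - len(work)
    if dropped:
        warnings.warn(f"{dropped} row(s) dropped for missing values",
                      stacklevel=2)
    if work[species_col].nunique() < 2:
        raise ValueError("need >= 2 species with complete rows")
    X = work[cols].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant column(s): "
            f"{[c for c, k in zip(cols, keep) if not k]}", stacklevel=2)
        cols = [c for c, k in zip(cols, keep) if k]
        X = X[:, keep]
    ncomp = min(n_components, X.shape[1])
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=ncomp, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    # sign convention: largest-|loading| positive per component
    for k in range(ncomp):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    labels = work[species_col].to_numpy()
    plane = scores[:, : min(2, ncomp)]
    sil = float(silhouette_score(plane, labels))
    species = sorted(set(labels))
    pair = pd.DataFrame(np.nan, index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            m = np.isin(labels, [a, b])
            pair.loc[a, b] = pair.loc[b, a] = float(
                silhouette_score(plane[m], labels[m]))
    score_df = pd.DataFrame(
        scores, columns=[f"PC{k + 1}" for k in range(ncomp)],
        index=work.index)
    score_df[species_col] = labels
    load_df = pd.DataFrame(
        loadings.T, index=cols,
        columns=[f"PC{k + 1}" for k in range(ncomp)])
    return PCADiscrimination(
        selection=sel, columns=cols, scores=score_df, loadings=load_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        silhouette=sil, pairwise_silhouette=pair, n_rows_dropped=dropped,
    )
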