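"""Stimulus catalogs: normative affect scores, labels, and selection.

A catalog is a :class:`pandas.DataFrame` with one row per stimulus and
columns ``stimulus_id``, ``val_mean``, ``val_sd``, ``aro_mean``, ``aro_sd``
(9-point Likert scale) plus, after :func:`binarize_labels`, the binary
columns ``val_label`` and ``aro_label`` in {+1, -1}.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATALOG_COLUMNS",
    "validate_catalog",
    "binarize_labels",
    "select_max_separation",
    "read_catalog",
    "write_catalog",
]

CATALOG_COLUMNS = ["stimulus_id", "val_mean", "val_sd", "aro_mean", "aro_sd"]
MIDPOINT = 5.0  # middle of the 9-point Likert scale


def validate_catalog(catalog: pd.DataFrame, require_labels: bool = False) -> None:
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    if catalog["stimulus_id"].duplicated().any():
        raise ValueError("stimulus ids must be unique")
    for col in ("val_mean", "aro_mean"):
        v = catalog[col].to_numpy(float)
        if len(v) and (v.min() < 1.0 or v.max() > 9.0):
            raise ValueError(f"{col} outside the 9-point Likert range [1, 9]")
    for col in ("val_sd", "aro_sd"):
        if len(catalog) and (catalog[col].to_numpy(float) <= 0).any():
            raise ValueError(f"{col} must be positive")
    if require_labels:
        for col in ("val_label", "aro_label"):
            if col not in catalog.columns:
                raise ValueError("catalog has no binary labels; "
                                 "call binarize_labels first")


def binarize_labels(catalog: pd.DataFrame) -> pd.DataFrame:
    """Derive binary affect labels from normative means.

    A stimulus is labelled +1 on a property when its normative mean
    strictly exceeds the Likert midpoint (5), else -1; a mean of exactly
    5.0 is labelled -1 by convention.
    """
    validate_catalog(catalog)
    out = catalog.copy()
    out["val_label"] = np.where(out["val_mean"].to_numpy(float) > MIDPOINT, 1, -1)
    out["aro_label"] = np.where(out["aro_mean"].to_numpy(float) > MIDPOINT, 1, -1)
    return out


def select_max_separation(catalog: pd.DataFrame, n_select: int,
                          seed_ids: Sequence = ()) -> list:
    """Greedy maximum-separation stimulus sampling in the arousal-valence plane.

    Starting from ``seed_ids`` (which count toward ``n_select``), each step
    adds the candidate whose normative (valence, arousal) mean coordinates
    have the largest summed Euclidean distance to all currently selected
    stimuli. With no seeds, the first pick is the stimulus farthest from
    the pool centroid. Ties break toward the smallest stimulus id, which
    makes the selection fully deterministic.

    Returns the selected ids in selection order.
    """
    validate_catalog(catalog)
    if n_select > len(catalog):
        raise ValueError(f"cannot select {n_select} from a pool of {len(catalog)}")
    ids = catalog["stimulus_id"].to_numpy()
    coords = catalog[["val_mean", "aro_mean"]].to_numpy(float)
    order = np.argsort(ids, kind="stable")  # id order for tie-breaking
    ids, coords = ids[order], coords[order]

    id_to_pos = {i: k for k, i in enumerate(ids)}
    selected: list[int] = []
    for sid in seed_ids:
        if sid not in id_to_pos:
            raise ValueError(f"seed id {sid!r} not in catalog")
        selected.append(id_to_pos[sid])
    if len(selected) > n_select:
        raise ValueError("more seed ids than n_select")

    available = np.ones(len(ids), bool)
    available[selected] = False
    # summed distance from each candidate to the current selection
    summed = np.zeros(len(ids))
    for pos in selected:
        summed += np.linalg.norm(coords - coords[pos], axis=1)

    while len(selected) < n_select:
        if not selected:
            centroid = coords.mean(axis=0)
            score = np.linalg.norm(coords - centroid, axis=1)
        else:
            score = summed
        score = np.where(available, score, -np.inf)
        best = int(np.argmax(score))  # argmax takes the first = smallest id
        selected.append(best)
        available[best] = False
        summed += np.linalg.norm(coords - coords[best], axis=1)

    return [ids[pos] for pos in selected]


def read_catalog(path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t")
    validate_catalog(catalog)
    return catalog


def write_catalog(catalog: pd.DataFrame, path) -> None:
    validate_catalog(catalog)
    catalog.to_csv(path, sep="\t", index=False)
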