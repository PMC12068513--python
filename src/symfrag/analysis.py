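"""Candidate post-processing: diverse selection and chemical-space maps.

``select_diverse_lowest`` reproduces the final selection step of a
generation campaign: k-means clustering (default k = 5) of candidate Morgan
fingerprints followed by picking the lowest-bandgap (highest-reward)
molecule from each cluster.  ``pca_projection`` maps candidate and
reference fingerprints into a shared 2-D principal-component basis for
plotting.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_core import canonicalize, fingerprint_array, mol_from_smiles, morgan_fingerprint

logger = logging.getLogger(__name__)

DEFAULT_SELECT_K = 5


def _fingerprint_matrix(smiles: Sequence[str]) -> np.ndarray:
    return np.array([
        fingerprint_array(morgan_fingerprint(mol_from_smiles(s)))
        for s in smiles
    ])


def select_diverse_lowest(
    candidates: Sequence[str],
    k: int = DEFAULT_SELECT_K,
    predictor=None,
    rewards: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster candidates and flag the best-scoring molecule per cluster.

    Candidates are deduplicated by canonical form; ``k`` clamps (logged) if
    fewer distinct candidates remain.  Scores come either from ``rewards``
    (parallel to ``candidates``; higher is better) or from ``predictor``
    (predicted bandgap in eV; lower is better).  Returns a table with one
    row per distinct candidate: smiles, reward, cluster, selected.
    """
    if predictor is None and rewards is None:
        raise ValueError("provide either a predictor or precomputed rewards")
    canon: dict[str, float] = {}
    for i, s in enumerate(candidates):
        c = canonicalize(s)
        if c in canon:
            continue
        if rewards is not None:
            canon[c] = float(rewards[i])
        else:
            canon[c] = -float(predictor.predict(mol_from_smiles(c)))
    smiles = sorted(canon)
    if len(smiles) < k:
        logger.info("k clamped from %d to %d distinct candidates", k, len(smiles))
        k = len(smiles)
    X = _fingerprint_matrix(smiles)
    from sklearn.cluster import KMeans

    labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
    frame = pd.DataFrame({
        "smiles": smiles,
        "reward": [canon[s] for s in smiles],
        "cluster": labels.astype(int),
    })
    frame["selected"] = False
    for cluster in range(k):
        members = frame.index[frame["cluster"] == cluster]
        best = max(members, key=lambda i: frame.loc[i, "reward"])
        frame.loc[best, "selected"] = True
    return frame


def pca_projection(
    candidates: Sequence[str],
    references: Sequence[str] = (),
) -> pd.DataFrame:
    """Deterministic 2-component PCA of Morgan fingerprints.

    Candidates and references share one fitted basis; returns a table with
    columns smiles, group ('candidate'/'reference'), pc1, pc2.
    """
    all_smiles = [canonicalize(s) for s in candidates] + \
                 [canonicalize(s) for s in references]
    groups = ["candidate"] * len(candidates) + ["reference"] * len(references)
    if len(all_smiles) < 2:
        raise ValueError("PCA needs at least 2 molecules")
    X = _fingerprint_matrix(all_smiles)
    from sklearn.decomposition import PCA

    coords = PCA(n_components=2, svd_solver="full").fit_transform(X)
    return pd.DataFrame({
        "smiles": all_smiles,
        "group": groups,
        "pc1": coords[:, 0],
        "pc2": coords[:, 1],
    })
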