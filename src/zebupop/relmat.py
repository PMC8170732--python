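"""Genomic relationship matrices, PCA and relatedness pruning.

Two GRM constructions are provided: VanRaden's method 1,

    G = Z Z' / sum_j 2 p_j (1 - p_j),   Z_ij = x_ij - 2 p_j,

and the Yang et al. (2010) estimator whose off-diagonals divide each marker
by its own 2p(1-p) and whose diagonal uses the inbreeding-corrected form

    g_ii = 1 + (1/M) sum_j (x_ij^2 - (1 + 2 p_j) x_ij + 2 p_j^2) / (2 p_j (1 - p_j)).

Matrices are always built on an explicit sample scope with frequencies from
that scope (building across deeply diverged groups skews the elements, so
taurine-only / indicine-only / study-breed scopes are kept separate).
Markers with p(1-p) < 1e-6 on the scope are excluded from both methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .genodata import (
    GenotypePanel,
    AlleleFreqTable,
    ZebuPopError,
    allele_frequencies,
)

_PQ_FLOOR = 1e-6


@dataclass
class GRMatrix:
    sample_ids: list
    matrix: np.ndarray
    method: str
    freqs: np.ndarray
    scope: str = "all"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ZebuPopError("GRM dimension does not match sample count")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ZebuPopError("GRM is not symmetric")
        self.matrix = (m + m.T) / 2.0


@dataclass
class PCAResult:
    sample_ids: list
    scores: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def impute_missing_mean(panel: GenotypePanel) -> np.ndarray:
    """Replace missing calls by the across-all-samples mean dosage per marker."""
    d = panel.dosages()
    miss = np.isnan(d)
    if miss.all(axis=0).any():
        raise ZebuPopError("marker with all calls missing cannot be mean-imputed")
    col_mean = np.nanmean(d, axis=0)
    return np.where(miss, col_mean[None, :], d)


def _usable_markers(p: np.ndarray) -> np.ndarray:
    pq = p * (1.0 - p)
    return np.flatnonzero(np.nan_to_num(pq, nan=0.0) >= _PQ_FLOOR)


def grm_vanraden(
    panel: GenotypePanel, freqs: AlleleFreqTable | None = None, scope: str = "all"
) -> GRMatrix:
    """VanRaden (2008) method-1 GRM on the panel's samples."""
    p = (freqs.freq[0] if freqs is not None else allele_frequencies(panel, "pooled").freq[0])
    keep = _usable_markers(p)
    if len(keep) == 0:
        raise ZebuPopError("all markers monomorphic on this scope")
    x = impute_missing_mean(panel)[:, keep]
    p = p[keep]
    z = x - 2.0 * p[None, :]
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    g = z @ z.T / denom
    return GRMatrix(list(panel.sample_ids), g, "vanraden", p, scope)


def grm_yang(
    panel: GenotypePanel, freqs: AlleleFreqTable | None = None, scope: str = "all"
) -> GRMatrix:
    """Yang et al. (2010) GRM: per-marker scaling, corrected diagonal."""
    p = (freqs.freq[0] if freqs is not None else allele_frequencies(panel, "pooled").freq[0])
    keep = _usable_markers(p)
    if len(keep) == 0:
        raise ZebuPopError("all markers monomorphic on this scope")
    x = impute_missing_mean(panel)[:, keep]
    p = p[keep]
    m = len(keep)
    pq2 = 2.0 * p * (1.0 - p)
    w = (x - 2.0 * p[None, :]) / np.sqrt(pq2)[None, :]
    g = w @ w.T / m
    diag = 1.0 + np.mean(
        (x * x - (1.0 + 2.0 * p[None, :]) * x + 2.0 * p[None, :] ** 2) / pq2[None, :],
        axis=1,
    )
    np.fill_diagonal(g, diag)
    return GRMatrix(list(panel.sample_ids), g, "yang", p, scope)


def pca_from_grm(grm: GRMatrix, k: int) -> PCAResult:
    """Top-k eigenpairs of the GRM; scores = eigenvector * sqrt(eigenvalue).

    Sign convention: the largest-magnitude loading of each component is made
    positive, so repeated runs produce identical score tables.
    """
    n = len(grm.sample_ids)
    if k > n:
        raise ValueError("k exceeds GRM dimension")
    if not np.isfinite(grm.matrix).all():
        raise ZebuPopError("GRM contains non-finite entries")
    evals, evecs = scipy.linalg.eigh(grm.matrix)
    order = np.argsort(evals)[::-1][:k]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(k):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = evecs * np.sqrt(np.maximum(evals, 0.0))[None, :]
    total = float(np.sum(np.maximum(np.linalg.eigvalsh(grm.matrix), 0.0)))
    pct = 100.0 * np.maximum(evals, 0.0) / total if total > 0 else np.zeros(k)
    return PCAResult(list(grm.sample_ids), scores, evals, pct)


def grm_breed_summary(grm: GRMatrix, breeds: list) -> pd.DataFrame:
    """Mean/SD of diagonal and within-breed off-diagonal elements per breed.

    Off-diagonal statistics run over unordered within-breed pairs; a breed
    with a single sample has them undefined (NaN, flagged).
    """
    if len(breeds) != len(grm.sample_ids):
        raise ZebuPopError("breed label count != GRM dimension")
    labels = np.asarray(breeds, dtype=object)
    rows = []
    for b in pd.unique(labels):
        idx = np.flatnonzero(labels == b)
        sub = grm.matrix[np.ix_(idx, idx)]
        diag = np.diag(sub)
        iu = np.triu_indices(len(idx), k=1)
        off = sub[iu]
        rows.append(
            {
                "breed": b,
                "n": len(idx),
                "mean_diag": float(diag.mean()),
                "sd_diag": float(diag.std(ddof=1)) if len(idx) > 1 else np.nan,
                "mean_offdiag": float(off.mean()) if len(off) else np.nan,
                "sd_offdiag": float(off.std(ddof=1)) if len(off) > 1 else np.nan,
                "offdiag_defined": bool(len(off)),
            }
        )
    return pd.DataFrame(rows)


def prune_related(grm: GRMatrix, threshold: float = 0.2):
    """Greedy removal of related samples until no off-diagonal exceeds ``threshold``.

    While any pair exceeds the threshold, remove the sample participating in
    the most offending pairs; ties go to the larger mean off-diagonal, then
    the larger sample index.  Returns ``(retained_ids, removed_ids)``.
    """
    n = len(grm.sample_ids)
    g = grm.matrix.copy()
    np.fill_diagonal(g, -np.inf)
    active = np.ones(n, dtype=bool)
    removed = []
    while True:
        over = (g > threshold) & active[:, None] & active[None, :]
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        cand = np.flatnonzero(counts == counts.max())
        if len(cand) > 1:
            mean_off = np.array(
                [np.mean(g[i, active & (np.arange(n) != i)]) for i in cand]
            )
            cand = cand[mean_off == mean_off.max()]
        victim = int(cand.max())
        active[victim] = False
        removed.append(grm.sample_ids[victim])
    retained = [grm.sample_ids[i] for i in np.flatnonzero(active)]
    return retained, removed


def export_grm_tsv(grm: GRMatrix, path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    df.to_csv(path, sep="\t")
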