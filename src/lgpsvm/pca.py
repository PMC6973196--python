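"""Covariance PCA with cumulative proportion-of-variance component selection.

Microarray data sit in the N >> M regime (thousands of genes, tens of
samples), so the eigendecomposition of the N x N gene covariance matrix is
computed through the thin SVD of the centered data matrix — mathematically
identical (eigenvalues are squared singular values over M-1) and tractable
for N up to ~12600.  Component count k is the smallest number of leading
components whose cumulative proportion of variance reaches the threshold
(default 95%).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PCAModel:
    """Fitted PCA: per-gene means, spectrum, and retained loadings.

    ``eigenvalues`` holds the full descending spectrum of the gene
    covariance matrix (up to rank); ``loadings`` the first ``k``
    eigenvectors as columns (N x k), sign-fixed so each column's
    largest-magnitude entry is positive.
    """

    gene_means: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    k: int
    cum_ppv: float
    ppv_threshold: float = 0.95


def fit_pca(X: np.ndarray, ppv_threshold: float = 0.95) -> PCAModel:
    """Fit PCA on a samples x genes matrix and retain components by PPV.

    Means are per gene; the covariance uses the M-1 denominator; k is the
    smallest integer whose cumulative proportion of variance is at least
    ``ppv_threshold``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x genes)")
    m, _ = X.shape
    if m < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")

    means = X.mean(axis=0)
    centered = X - means
    # thin SVD: eigenvalues of the covariance are s^2/(M-1)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (m - 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("degenerate data: total variance is zero")
    cum = np.cumsum(eigenvalues) / total
    k = int(np.searchsorted(cum, ppv_threshold - 1e-12) + 1)
    loadings = vt[:k].T.copy()
    # eigenvector sign is arbitrary; fix largest-magnitude entry positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCAModel(
        gene_means=means,
        eigenvalues=eigenvalues,
        loadings=loadings,
        k=k,
        cum_ppv=float(cum[k - 1]),
        ppv_threshold=ppv_threshold,
    )


def proportion_of_variance(eigenvalues: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Each eigenvalue's share of total variance; sums to 1.

    Small negative eigenvalues (numerical noise from a symmetric solver)
    are clipped to zero; genuinely negative input is rejected.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    scale = max(1.0, float(np.abs(ev).max(initial=0.0)))
    if np.any(ev < -tol * scale):
        raise ValueError("eigenvalues must be non-negative")
    ev = np.clip(ev, 0.0, None)
    total = ev.sum()
    if total == 0:
        raise ValueError("all-zero eigenvalues: degenerate data")
    return ev / total


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project samples onto the retained components: (X - means) @ loadings.

    Applying a model fitted on calibration data to held-out data subtracts
    the *calibration* means, keeping the held-out rows out of the fit.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.gene_means.shape[0]:
        raise ValueError(
            f"X has {X.shape[-1] if X.ndim == 2 else '?'} genes; "
            f"model expects {model.gene_means.shape[0]}"
        )
    return (X - model.gene_means) @ model.loadings


def export_loadings(model: PCAModel, path: str | Path, gene_ids=None) -> None:
    """Write the retained loadings as TSV (genes x components)."""
    cols = [f"PC{j + 1}" for j in range(model.k)]
    df = pd.DataFrame(model.loadings, columns=cols, index=gene_ids)
    df.to_csv(path, sep="\t")
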