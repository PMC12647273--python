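"""PCA over probes-as-observations, component selection and top-k ranking.

Probes are the observations and the 8 samples the variables, so each
component has one loading per sample and one score per probe — the
orientation in which a component's loading pattern across lesion conditions
can be read directly, and probes can be ranked by their score on the
lesion-discriminating axis.

Rows are already standardized per probe (mean 0, sd 1 across samples); no
further centering across probes is applied.  The decomposition is the
eigendecomposition of the sample-by-sample second-moment matrix
``Z'Z / n_probes`` (computed via SVD of Z); the contribution ratio of
component j is its eigenvalue divided by the trace.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .containers import PCAResult, SelectionResult

logger = logging.getLogger(__name__)


def run_pca(z: pd.DataFrame) -> PCAResult:
    """Decompose a standardized probe x sample matrix.

    Returns loadings (component x sample, unit-norm rows), per-probe scores
    (projections of probe rows onto the loadings) and contribution ratios
    (eigenvalue / trace).  Rank deficiency yields trailing zero ratios; an
    all-zero matrix is rejected.
    """
    X = np.asarray(z, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need >= 2 probes and >= 2 samples, got shape {X.shape}")
    if not np.any(X):
        raise ValueError("all-zero matrix has no principal components")
    n_probes, n_samples = X.shape
    # Z = U S Vt ; eigenvalues of Z'Z/n are S^2/n with eigenvectors the rows of Vt
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / n_probes
    k = min(n_probes, n_samples)
    ratios = np.zeros(n_samples)
    ratios[:k] = eigvals / eigvals.sum()
    loadings = np.zeros((n_samples, n_samples))
    loadings[:k] = vt
    if k < n_samples:
        # complete the basis so loading rows stay unit-norm
        q, _ = np.linalg.qr(np.eye(n_samples) - vt.T @ vt)
        loadings[k:] = q[:, : n_samples - k].T
    scores = X @ loadings.T
    return PCAResult(
        contribution_ratios=ratios,
        loadings=loadings,
        scores=scores,
        probe_ids=list(z.index),
        sample_ids=list(z.columns),
    )


def select_component(p: PCAResult, severity: dict[str, int] | pd.Series) -> SelectionResult:
    """Choose the lesion-discriminating component and orient it.

    The component whose loading vector has the largest absolute Spearman
    correlation with the ordinal severity covariate is selected; its sign is
    set so that low-severity (control) samples carry positive loadings, i.e.
    a positive oriented score means "high in control, low in severe lesions".
    Ties in absolute correlation go to the lowest component index.
    """
    sev = pd.Series(severity)
    missing = [s for s in p.sample_ids if s not in sev.index]
    if missing:
        raise ValueError(f"severity undefined for samples: {missing}")
    sev = sev.loc[p.sample_ids].to_numpy(dtype=float)
    if np.all(sev == sev[0]):
        raise ValueError("severity is constant across samples; no discriminating axis")
    rhos = np.zeros(p.n_components)
    for j in range(p.n_components):
        rho = spearmanr(p.loadings[j], sev).statistic
        rhos[j] = 0.0 if np.isnan(rho) else rho
    if not np.any(rhos):
        raise ValueError("no component correlates with severity")
    best = float(np.max(np.abs(rhos)))
    candidates = np.flatnonzero(np.isclose(np.abs(rhos), best))
    if len(candidates) > 1:
        logger.info("tie in |rank correlation| among components %s; lowest wins", candidates)
    comp = int(candidates[0])
    orientation = -1 if rhos[comp] > 0 else 1
    return SelectionResult(component_index=comp, orientation=orientation)


def top_k(p: PCAResult, s: SelectionResult, k: int = 100) -> SelectionResult:
    """Rank probes by oriented score descending and keep the top k.

    Ties are broken by probe id lexicographic order (logged).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(p.probe_ids):
        logger.warning("k=%d exceeds probe count %d; returning all", k, len(p.probe_ids))
        k = len(p.probe_ids)
    oriented = s.orientation * p.scores[:, s.component_index]
    ids = np.array(p.probe_ids)
    order = np.lexsort((ids, -oriented))
    ranked = oriented[order]
    if len(np.unique(ranked)) < len(ranked):
        logger.info("score ties broken by probe id lexicographic order")
    return SelectionResult(
        component_index=s.component_index,
        orientation=s.orientation,
        selected_probe_ids=list(ids[order][:k]),
        k=k,
    )


def cluster_order(
    z_subset: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Agglomerative clustering of probes and samples for heatmap display.

    Returns (probe leaf order, sample leaf order, probe linkage, sample
    linkage).  Average linkage on Euclidean distances by default.
    """
    if z_subset.shape[0] < 2:
        raise ValueError("need >= 2 probes to cluster")
    X = np.asarray(z_subset, dtype=float)
    row_link = hierarchy.linkage(pdist(X, metric=metric), method=linkage)
    row_order = [z_subset.index[i] for i in hierarchy.leaves_list(row_link)]
    if z_subset.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(X.T, metric=metric), method=linkage)
        col_order = [z_subset.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link = np.empty((0, 4))
        col_order = list(z_subset.columns)
    return row_order, col_order, row_link, col_link


def plot_heatmap(z_subset: pd.DataFrame, path: str, linkage: str = "average"):
    """Optional clustered-heatmap rendering of the selected probes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols, _, _ = cluster_order(z_subset, linkage=linkage)
    data = z_subset.loc[rows, cols]
    fig, ax = plt.subplots(figsize=(6, max(4, len(rows) * 0.06)))
    im = ax.imshow(data, aspect="auto", cmap="cividis")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-scored intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
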