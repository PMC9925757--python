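"""Feature-set assembly and sampling-adequacy diagnostics.

Each deceleration–contraction pair, together with the baseline, yields one
13-dimensional feature vector (six contraction values, six deceleration
values, baseline) plus a class label.  Three provenances are distinguished
by the set tag:

* **S1** — pipeline-estimated event points, external (e.g. clinician) labels;
* **S2** — externally marked event points and labels;
* **S3** — pipeline-estimated event points, crisp guideline-derived labels.

Adequacy of a feature table for factor/PCA analysis is assessed with the
Kaiser-Meyer-Olkin statistic (ratio of squared correlations to squared
correlations plus squared anti-image partial correlations), Bartlett's test
of sphericity, and a PCA of the correlation matrix with optional varimax
rotation of the loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import DecelContractionPair
from .io import FEATURE_COLUMNS

__all__ = [
    "LabeledFeatureVector",
    "AdequacyReport",
    "build_feature_set",
    "adequacy",
    "kmo_statistic",
    "bartlett_sphericity",
    "varimax",
]


@dataclass(frozen=True)
class LabeledFeatureVector:
    """One row of a feature set: 13 features, label and provenance tag."""

    U_st_time: float
    U_p_time: float
    U_e_time: float
    U_st_point: float
    U_p_point: float
    U_e_point: float
    D_st_time: float
    D_n_time: float
    D_e_time: float
    D_st_point: float
    D_n_point: float
    D_e_point: float
    Baseline: float
    label: str
    set_tag: str = "S1"
    source_id: str = ""

    def values(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS], dtype=float)


def build_feature_set(
    pairs: list[DecelContractionPair],
    labels: list[str],
    baseline: float,
    set_tag: str = "S1",
    source_id: str = "",
) -> list[LabeledFeatureVector]:
    """Assemble labeled feature vectors from paired events.

    Pairs lacking a contraction are rejected (logged via warnings) since six
    of the thirteen features would be missing.
    """
    if set_tag not in ("S1", "S2", "S3"):
        raise ValueError(f"unknown feature-set tag {set_tag!r}")
    if len(pairs) != len(labels):
        raise ValueError("pairs and labels must align")
    rows = []
    for i, (pair, label) in enumerate(zip(pairs, labels)):
        if pair.contraction is None:
            warnings.warn(
                f"row {i}: deceleration without a contraction dropped from {set_tag}",
                stacklevel=2,
            )
            continue
        d, c = pair.decel, pair.contraction
        vals = dict(
            U_st_time=c.U_st_time,
            U_p_time=c.U_p_time,
            U_e_time=c.U_e_time,
            U_st_point=c.U_start,
            U_p_point=c.U_peak,
            U_e_point=c.U_end,
            D_st_time=d.D_st_time,
            D_n_time=d.D_n_time,
            D_e_time=d.D_e_time,
            D_st_point=d.D_st_point,
            D_n_point=d.D_n_point,
            D_e_point=d.D_e_point,
            Baseline=baseline,
        )
        if not all(np.isfinite(v) for v in vals.values()):
            warnings.warn(f"row {i}: non-finite feature value, dropped", stacklevel=2)
            continue
        rows.append(
            LabeledFeatureVector(**vals, label=label, set_tag=set_tag, source_id=source_id)
        )
    return rows


@dataclass
class AdequacyReport:
    """KMO, Bartlett and PCA diagnostics of a feature table."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray        #: non-increasing
    loadings: pd.DataFrame         #: features × components
    singular: bool = False         #: correlation matrix was singular
    n_obs: int = 0


def _correlation_matrix(X: np.ndarray) -> np.ndarray:
    return np.corrcoef(X, rowvar=False)


def kmo_statistic(X: np.ndarray) -> tuple[float, bool]:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = Σ r²ij / (Σ r²ij + Σ q²ij) over off-diagonal pairs, where r are
    the simple correlations and q the anti-image partial correlations
    q_ij = −S_ij / √(S_ii S_jj) with S the inverse correlation matrix.
    Returns (kmo, singular_flag); a singular correlation matrix is handled
    with the pseudo-inverse.
    """
    R = _correlation_matrix(np.asarray(X, dtype=float))
    p = R.shape[0]
    singular = False
    try:
        S = np.linalg.inv(R)
        if not np.all(np.isfinite(S)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        singular = True
        S = np.linalg.pinv(R)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    Q = -S / d
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2)), singular


def bartlett_sphericity(X: np.ndarray) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    χ² = −(n − 1 − (2p + 5)/6) · ln det R with df = p(p−1)/2.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = _correlation_matrix(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        logdet = -np.inf  # singular: infinitely strong evidence of structure
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0
    return float(chi2), df, pval


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation of a loading matrix (Kaiser's iterative SVD form)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lam = L @ rot
        u, s, vt = np.linalg.svd(
            L.T @ (lam**3 - (lam * np.mean(lam**2, axis=0))), full_matrices=False
        )
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    return L @ rot


def adequacy(
    rows,
    n_components: int | None = None,
    rotate: bool = True,
    columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> AdequacyReport:
    """Compute the adequacy diagnostics of a feature table.

    ``rows`` may be LabeledFeatureVector instances, a DataFrame or a 2-D
    array.  Components default to those with eigenvalue > 1 (Kaiser rule).
    """
    if isinstance(rows, pd.DataFrame):
        X = rows.to_numpy(dtype=float)
        columns = tuple(rows.columns)
    elif isinstance(rows, np.ndarray):
        X = np.asarray(rows, dtype=float)
        columns = tuple(f"f{i}" for i in range(X.shape[1]))
    else:
        X = np.vstack([r.values() for r in rows])
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two features")
    if n <= p:
        warnings.warn(f"n = {n} ≤ p = {p}: adequacy statistics unstable", stacklevel=2)

    kmo, singular = kmo_statistic(X)
    if singular:
        warnings.warn("singular correlation matrix: KMO uses the pseudo-inverse",
                      stacklevel=2)
    chi2, df, pval = bartlett_sphericity(X)

    R = _correlation_matrix(X)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if n_components is None:
        n_components = max(1, int(np.sum(eigvals > 1.0)))
    L = eigvecs[:, :n_components] * np.sqrt(np.clip(eigvals[:n_components], 0, None))
    if rotate and n_components >= 2:
        L = varimax(L)
    loadings = pd.DataFrame(
        L, index=list(columns[:p]), columns=[f"PC{i+1}" for i in range(n_components)]
    )
    return AdequacyReport(
        kmo=kmo,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        eigenvalues=eigvals,
        loadings=loadings,
        singular=singular,
        n_obs=n,
    )
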