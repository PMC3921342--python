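"""Exploratory factor analysis pipeline.

Variable screening on pairwise correlation, suitability diagnostics
(Bartlett sphericity, KMO/MSA from the anti-image correlations),
principal-axis factoring by iterated communalities, and direct-oblimin
rotation (gradient-projection algorithm, Kaiser row normalization
optional).  Reports pattern/structure matrices, factor correlations,
communalities and scree eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EFAResult:
    correlation_matrix: np.ndarray
    bartlett: tuple[float, int, float]
    kmo_overall: float
    msa_per_variable: np.ndarray
    eigenvalues: np.ndarray
    n_factors: int
    communalities: np.ndarray
    pattern: np.ndarray
    structure: np.ndarray
    phi: np.ndarray
    converged: bool
    n_iterations: int
    variable_names: list[str] = field(default_factory=list)
    low_communality: list[str] = field(default_factory=list)

    def masked_pattern(self, threshold: float = 0.30) -> pd.DataFrame:
        """Pattern matrix with |loading| < threshold blanked for reporting."""
        df = pd.DataFrame(
            self.pattern,
            index=self.variable_names or range(self.pattern.shape[0]),
            columns=[f"F{j + 1}" for j in range(self.pattern.shape[1])],
        )
        return df.where(df.abs() >= threshold)


def screen_variables(
    table: pd.DataFrame,
    max_abs_corr: float = 0.90,
    drop_list: Sequence[str] = (),
    outcome: Optional[np.ndarray] = None,
    log: Optional[list] = None,
) -> pd.DataFrame:
    """Drop explicitly listed and highly collinear variables.

    Pairs with |r| > ``max_abs_corr`` are resolved one at a time (most
    correlated pair first): the member kept is the one more correlated
    (in absolute value) with ``outcome`` when given, else the
    alphabetically first.  Every removal is appended to ``log`` with its
    reason.
    """
    if not 0 < max_abs_corr <= 1:
        raise ValueError("max_abs_corr must lie in (0, 1]")
    log = log if log is not None else []
    cols = [c for c in table.columns if c != "area_id"]
    keep = [c for c in cols if c not in set(drop_list)]
    for c in cols:
        if c in set(drop_list):
            log.append((c, "explicit drop_list"))
    while True:
        if len(keep) < 2:
            break
        r = table[keep].corr().to_numpy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.abs(r).argmax(), r.shape)
        if abs(r[i, j]) <= max_abs_corr:
            break
        a, b = keep[i], keep[j]
        if outcome is not None:
            ra = abs(np.corrcoef(table[a], outcome)[0, 1])
            rb = abs(np.corrcoef(table[b], outcome)[0, 1])
            drop = b if ra >= rb else a
        else:
            drop = max(a, b)
        keep.remove(drop)
        log.append((drop, f"|r|={abs(r[i, j]):.3f} with {a if drop == b else b}"))
    if not keep:
        raise ValueError("screening removed every variable")
    out_cols = (["area_id"] if "area_id" in table.columns else []) + keep
    return table[out_cols].copy()


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity against an identity correlation matrix.

    ``chi2 = -((n - 1) - (2p + 5)/6) ln det R`` on ``p(p-1)/2`` degrees
    of freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("sample size must exceed the number of variables")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is singular; screen variables further")
    chi2 = -((n - 1) - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy (overall and per-variable MSA).

    Anti-image (negative partial) correlations come from the scaled
    inverse of R; KMO is the ratio of summed squared correlations to
    summed squared correlations plus summed squared partials.
    """
    R = np.asarray(R, dtype=float)
    try:
        rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular") from exc
    d = np.sqrt(np.diag(rinv))
    q = -rinv / np.outer(d, d)
    np.fill_diagonal(q, 0.0)
    r2 = R**2
    np.fill_diagonal(r2, 0.0)
    q2 = q**2
    overall = r2.sum() / (r2.sum() + q2.sum())
    msa = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), msa


def principal_axis_factoring(
    R: np.ndarray,
    n_factors: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Iterated-communalities principal-axis extraction.

    Starts from squared multiple correlations, eigendecomposes the
    reduced correlation matrix, rebuilds loadings from the top-k
    components (negative eigenvalues truncated at zero), and repeats
    until communalities stabilise.  Heywood communalities are clipped to
    just below 1 with a warning.  Returns (loadings, communalities,
    eigenvalues-of-final-reduced-matrix, converged).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("need 1 <= n_factors < number of variables")
    rinv = np.linalg.inv(R)
    h2 = 1.0 - 1.0 / np.diag(rinv)  # squared multiple correlations
    converged = False
    evals = np.zeros(p)
    loadings = np.zeros((p, n_factors))
    for _ in range(max_iter):
        rr = R.copy()
        np.fill_diagonal(rr, h2)
        evals, evecs = np.linalg.eigh(rr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        lam = evecs[:, :n_factors] * np.sqrt(np.clip(evals[:n_factors], 0.0, None))
        new_h2 = (lam**2).sum(axis=1)
        if (new_h2 > 1.0).any():
            warnings.warn("Heywood case: communality > 1 clipped", stacklevel=2)
            new_h2 = np.minimum(new_h2, 1.0 - 1e-6)
        delta = np.abs(new_h2 - h2).max()
        h2, loadings = new_h2, lam
        if delta < tol:
            converged = True
            break
    # canonical sign: largest-magnitude element of each column positive
    for j in range(n_factors):
        k = np.abs(loadings[:, j]).argmax()
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
    return loadings, h2, evals, converged


def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Direct-oblimin criterion value and gradient wrt the loadings."""
    p, k = L.shape
    L2 = L**2
    N = np.ones((k, k)) - np.eye(k)
    C = np.ones((p, p)) / p
    M = (np.eye(p) - gamma * C) @ L2 @ N
    f = float((L2 * M).sum()) / 4.0
    G = L * M
    return f, G


def oblimin_rotate(
    loadings: np.ndarray,
    gamma: float = 0.0,
    kaiser: bool = True,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct-oblimin rotation by oblique gradient projection.

    ``gamma = 0`` is direct quartimin (the SPSS default delta).  With
    ``kaiser`` the rows are normalized to unit length before rotation
    and denormalized afterwards.  Returns (pattern, structure, phi) with
    ``structure = pattern @ phi``.

    Raises RuntimeError (carrying the last criterion value) if the
    projection iteration fails to converge.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k < 2:
        raise ValueError("need at least 2 factors to rotate")
    if kaiser:
        norms = np.sqrt((A**2).sum(axis=1))
        norms = np.where(norms > 0, norms, 1.0)
        A = A / norms[:, None]

    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T @ np.diag((T * G).sum(axis=0))
        s = np.sqrt((Gp**2).sum())
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            Tt = X / np.sqrt((X**2).sum(axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    if not converged:
        raise RuntimeError(f"oblimin rotation did not converge (criterion={f:.6g})")
    phi = T.T @ T
    pattern = L
    if kaiser:
        pattern = pattern * norms[:, None]
    # canonical orientation: dominant loading of each factor positive
    for j in range(k):
        m = np.abs(pattern[:, j]).argmax()
        if pattern[m, j] < 0:
            pattern[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1
    structure = pattern @ phi
    return pattern, structure, phi


def run_efa(
    table: pd.DataFrame,
    n_factors_range: Sequence[int] = (5, 6, 7, 8),
    gamma: float = 0.0,
    kaiser: bool = True,
    mask_threshold: float = 0.30,
    low_communality: float = 0.50,
) -> tuple[dict[int, EFAResult], int]:
    """Fit PAF + oblimin for each k in range; suggest k by Kaiser criterion.

    Diagnostics (Bartlett, KMO, per-variable MSA) are computed once on
    the input correlation matrix and attached to every result.  Pattern
    loadings below ``mask_threshold`` are masked only in reports (via
    :meth:`EFAResult.masked_pattern`); variables whose communality falls
    below ``low_communality`` are flagged.  Returns (results-by-k,
    suggested k); the final choice of k belongs to the analyst.
    """
    cols = [c for c in table.columns if c != "area_id"]
    if len(cols) < 2:
        raise ValueError("need at least 2 covariate columns")
    X = table[cols].to_numpy(dtype=float)
    n = X.shape[0]
    R = np.corrcoef(X, rowvar=False)
    bart = bartlett_sphericity(R, n)
    overall, msa = kmo(R)
    scree = np.sort(np.linalg.eigvalsh(R))[::-1]
    suggested = int((scree > 1.0).sum())
    results: dict[int, EFAResult] = {}
    for k in n_factors_range:
        load, h2, evals, conv = principal_axis_factoring(R, k)
        if k >= 2:
            pattern, structure, phi = oblimin_rotate(load, gamma=gamma, kaiser=kaiser)
        else:
            pattern, structure, phi = load, load, np.eye(1)
        results[k] = EFAResult(
            correlation_matrix=R,
            bartlett=bart,
            kmo_overall=overall,
            msa_per_variable=msa,
            eigenvalues=scree,
            n_factors=k,
            communalities=h2,
            pattern=pattern,
            structure=structure,
            phi=phi,
            converged=conv,
            n_iterations=0,
            variable_names=cols,
            low_communality=[c for c, h in zip(cols, h2) if h < low_communality],
        )
    if suggested not in results and results:
        suggested = min(results, key=lambda k: abs(k - suggested))
    return results, suggested
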