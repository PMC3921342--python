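"""Multiplicative decomposition of posterior relative risk.

For each kept draw the relative risk of an area factors exactly as
``exp(beta0) * prod_k exp(x_ik beta_k) * exp(u_i) * exp(v_i)``; each
factor is summarized per area so the covariate, spatially structured and
unstructured contributions can be mapped separately.  Total-RR summaries
are computed on the per-draw products, never on products of summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bymspat.bym_mcmc import PosteriorDraws
from bymspat.geo_adjacency import AreaMap, write_geojson_areas


@dataclass
class ComponentSurfaces:
    """Per-area posterior summaries of every multiplicative RR component.

    ``components`` maps component name ('intercept', each covariate,
    'spatial', 'unstructured', 'total_rr') to a DataFrame with columns
    mean/median/q2.5/q97.5, one row per area (in draw order).
    """

    area_index: list[int]
    components: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.components)

    def to_frame(self, area_id: list[str] | None = None) -> pd.DataFrame:
        n = len(self.area_index)
        out = pd.DataFrame({"area_id": area_id if area_id is not None else self.area_index})
        if len(out) != n:
            raise ValueError("area_id length mismatch")
        for name, df in self.components.items():
            for col in df.columns:
                out[f"{name}.{col}"] = df[col].to_numpy()
        return out


def _summary(draws_mat: np.ndarray) -> pd.DataFrame:
    """Summaries over axis 0 (draws) for each area."""
    q = np.quantile(draws_mat, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": draws_mat.mean(axis=0),
            "median": q[1],
            "q2.5": q[0],
            "q97.5": q[2],
        }
    )


def decompose_rr(draws: PosteriorDraws, X: np.ndarray | None = None) -> ComponentSurfaces:
    """Split posterior RR into multiplicative component surfaces.

    ``X`` must carry one column per sampled coefficient (omit or pass an
    empty array for covariate-free models).
    """
    if X is None:
        X = np.zeros((0, draws.beta.shape[2]))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = draws.beta.shape[2]
    if X.shape[1] != p:
        raise ValueError(
            f"covariate matrix has {X.shape[1]} columns but draws carry {p} coefficients"
        )
    if draws.u is not None:
        n = draws.u.shape[2]
    elif draws.v is not None:
        n = draws.v.shape[2]
    elif X.shape[0]:
        n = X.shape[0]
    else:
        raise ValueError("cannot infer number of areas")
    if p and X.shape[0] != n:
        raise ValueError("covariate rows != number of areas in draws")

    S = draws.n_chains * draws.n_kept
    b0 = draws.beta0.reshape(S)
    beta = draws.beta.reshape(S, p)
    u = draws.u.reshape(S, n) if draws.u is not None else np.zeros((S, n))
    v = draws.v.reshape(S, n) if draws.v is not None else np.zeros((S, n))

    eta = b0[:, None] + (beta @ X.T if p else 0.0) + u + v
    surfaces = ComponentSurfaces(area_index=list(range(n)))
    surfaces.components["total_rr"] = _summary(np.exp(eta))
    surfaces.components["intercept"] = _summary(
        np.exp(np.repeat(b0[:, None], n, axis=1))
    )
    names = draws.covariate_names or [f"beta[{j}]" for j in range(p)]
    for j, name in enumerate(names):
        surfaces.components[name] = _summary(np.exp(np.outer(beta[:, j], X[:, j])))
    surfaces.components["spatial"] = _summary(np.exp(u))
    surfaces.components["unstructured"] = _summary(np.exp(v))
    return surfaces


def component_draw_product(
    draws: PosteriorDraws, X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (product of components, exp(linear predictor)) matrices.

    Exposed for the identity check that the decomposition is exact draw
    by draw.
    """
    if X is None:
        X = np.zeros((0, draws.beta.shape[2]))
    X = np.asarray(X, dtype=float)
    p = draws.beta.shape[2]
    n = draws.u.shape[2] if draws.u is not None else (
        draws.v.shape[2] if draws.v is not None else X.shape[0]
    )
    S = draws.n_chains * draws.n_kept
    b0 = draws.beta0.reshape(S)
    beta = draws.beta.reshape(S, p)
    u = draws.u.reshape(S, n) if draws.u is not None else np.zeros((S, n))
    v = draws.v.reshape(S, n) if draws.v is not None else np.zeros((S, n))
    prod = np.exp(b0)[:, None] * np.exp(u) * np.exp(v)
    for j in range(p):
        prod = prod * np.exp(np.outer(beta[:, j], X[:, j]))
    eta = b0[:, None] + (beta @ X.T if p else 0.0) + u + v
    return prod, np.exp(eta)


def export_surfaces(
    surfaces: ComponentSurfaces,
    area_map: AreaMap,
    csv_path,
    geojson_path=None,
) -> pd.DataFrame:
    """Write per-area component summaries as CSV (and optionally GeoJSON).

    Area ids are taken from ``area_map``; a count mismatch between the
    surfaces and the map is an error naming the offending side.
    """
    if len(surfaces.area_index) != area_map.n:
        raise ValueError(
            f"surfaces cover {len(surfaces.area_index)} areas but the map has "
            f"{area_map.n}: ids {area_map.area_id[:5]}..."
        )
    table = surfaces.to_frame(area_id=area_map.area_id)
    table.to_csv(csv_path, index=False)
    if geojson_path is not None:
        props = {c: table[c].to_numpy() for c in table.columns if c != "area_id"}
        write_geojson_areas(area_map, geojson_path, properties=props)
    return table
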