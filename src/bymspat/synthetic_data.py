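"""Synthetic areal datasets with known ground truth.

Generates (1) connected planar lattices (grid or clipped Voronoi),
(2) covariate tables with a prescribed common-factor structure, and
(3) outcome counts from a BYM generative model (intercept + covariate
effects + intrinsic-CAR structured effect + iid unstructured effect),
packaging the generating parameters so downstream estimation stages can
be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram

from bymspat.ecological_indices import OutcomeTable
from bymspat.geo_adjacency import AdjacencyMatrix, AreaMap, build_adjacency


@dataclass
class SimulationSpec:
    """Parameters of one synthetic-dataset draw.

    ``loading_matrix`` is the variables x factors pattern; covariates are
    generated as ``X = F @ loading_matrix.T + E`` with factor scores F
    drawn with covariance ``factor_correlations`` and unique noise scaled
    to unit total variance per variable.  Outcomes follow a log-linear
    relative-risk model with structured (ICAR, scale ``sigma_u``) and
    unstructured (normal, scale ``sigma_v``) random effects.
    """

    n_areas: int = 101
    lattice_kind: str = "grid"
    n_factors: int = 6
    loading_matrix: Optional[np.ndarray] = None
    factor_correlations: Optional[np.ndarray] = None
    noise_sd: float = 1.0
    beta0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_u: float = 0.3
    sigma_v: float = 0.1
    survey_size_range: tuple[int, int] = (50, 250)
    baseline_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        if self.lattice_kind not in ("grid", "voronoi"):
            raise ValueError("lattice_kind must be 'grid' or 'voronoi'")
        if self.loading_matrix is not None:
            self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.factor_correlations is None and self.loading_matrix is not None:
            self.factor_correlations = np.eye(self.loading_matrix.shape[1])
        if self.factor_correlations is not None:
            phi = np.asarray(self.factor_correlations, dtype=float)
            if not np.allclose(phi, phi.T, atol=1e-10):
                raise ValueError("factor_correlations must be symmetric")
            if not np.allclose(np.diag(phi), 1.0, atol=1e-10):
                raise ValueError("factor_correlations must have unit diagonal")
            if np.linalg.eigvalsh(phi).min() <= 0:
                raise ValueError("factor_correlations must be positive definite")
            self.factor_correlations = phi
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        lo, hi = self.survey_size_range
        if lo < 1 or hi < lo:
            raise ValueError("survey_size_range must satisfy 1 <= min <= max")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must lie in (0, 1)")
        for name in ("sigma_u", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated dataset plus the parameters that produced it."""

    area_map: AreaMap
    adjacency: AdjacencyMatrix
    covariates: "object"  # pandas DataFrame with area_id + covariate columns
    outcomes: OutcomeTable
    truth: dict


def default_loading_pattern() -> tuple[np.ndarray, np.ndarray, list[str]]:
    """A 26-variable, 6-factor pattern with realistic magnitudes.

    Mostly simple structure (one dominant loading per variable in the
    0.3-0.9 range, signs mixed) with a handful of mild cross-loadings,
    plus modestly correlated factors.  Returns (loadings, phi, names).
    """
    names = [f"var{i + 1:02d}" for i in range(26)]
    lam = np.zeros((26, 6))
    primary = [
        (0, 0, 0.91), (1, 0, 0.82), (2, 0, 0.78), (3, 0, 0.71), (4, 0, 0.58),
        (5, 0, 0.57), (6, 0, 0.55),
        (7, 1, 0.93), (8, 1, -0.78), (9, 1, -0.65), (10, 1, -0.57), (11, 1, -0.47),
        (12, 2, 0.91), (13, 2, 0.90), (14, 2, 0.80),
        (15, 3, -0.83), (16, 3, 0.73), (17, 3, -0.64),
        (18, 4, 0.77), (19, 4, 0.54), (20, 4, 0.45),
        (21, 5, -0.68), (22, 5, -0.59), (23, 5, -0.49), (24, 5, 0.40),
        (25, 5, 0.31),
    ]
    for i, j, v in primary:
        lam[i, j] = v
    phi = np.eye(6)
    phi[1, 5] = phi[5, 1] = 0.26
    phi[0, 2] = phi[2, 0] = 0.30
    phi[0, 5] = phi[5, 0] = 0.15
    return lam, phi, names


def make_lattice(spec: SimulationSpec) -> AreaMap:
    """Build a connected planar map of ``n_areas`` polygons.

    ``grid`` tiles unit squares row-major over a near-square grid,
    trimming trailing cells of the last row (connectivity preserved).
    ``voronoi`` tessellates seeded random points in the unit square,
    retrying (bounded) if the rook-contiguity graph comes out
    disconnected.
    """
    n = spec.n_areas
    if spec.lattice_kind == "grid":
        ncols = int(np.ceil(np.sqrt(n)))
        ids, geoms = [], []
        for k in range(n):
            r, c = divmod(k, ncols)
            geoms.append(box(c, -r - 1, c + 1, -r))
            ids.append(f"A{k + 1:03d}")
        return AreaMap(area_id=ids, geometry=geoms)

    rng = np.random.default_rng(spec.seed)
    envelope = box(0.0, 0.0, 1.0, 1.0)
    last_err: Exception | None = None
    for _ in range(10):
        pts = rng.uniform(0.05, 0.95, size=(n, 2))
        cells = voronoi_diagram(MultiPoint([tuple(p) for p in pts]), envelope=envelope)
        polys: list[Polygon | None] = [None] * n
        for cell in cells.geoms:
            clipped = cell.intersection(envelope)
            for i, p in enumerate(pts):
                if polys[i] is None and clipped.contains(MultiPoint([tuple(p)]).geoms[0]):
                    polys[i] = clipped
                    break
        if any(p is None or p.is_empty for p in polys):
            last_err = ValueError("voronoi cell assignment failed")
            continue
        amap = AreaMap(
            area_id=[f"A{k + 1:03d}" for k in range(n)],
            geometry=polys,  # type: ignore[arg-type]
        )
        try:
            build_adjacency(amap, rule="rook", snap_grid=1e-9)
        except Exception as exc:  # disconnected or degenerate tessellation
            last_err = exc
            continue
        return amap
    raise RuntimeError(f"could not generate a connected voronoi lattice: {last_err}")


def simulate_covariates(spec: SimulationSpec, n_areas: Optional[int] = None):
    """Draw a factor-structured covariate table.

    ``X = F @ loadings.T + E``; unique error variances are set so every
    variable has unit total variance, then columns are standardized to
    sample mean 0 / sd 1.  Raises if any implied unique variance is
    non-positive (communality >= 1).
    """
    import pandas as pd

    if spec.loading_matrix is None:
        raise ValueError("SimulationSpec.loading_matrix is required")
    n = spec.n_areas if n_areas is None else int(n_areas)
    lam = spec.loading_matrix
    phi = spec.factor_correlations
    if phi is None:
        phi = np.eye(lam.shape[1])
    communality = np.einsum("ij,jk,ik->i", lam, phi, lam)
    unique_var = 1.0 - communality
    if (unique_var <= 0).any():
        bad = np.flatnonzero(unique_var <= 0).tolist()
        raise ValueError(f"communality >= 1 for variables {bad}")
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(phi)
    scores = rng.standard_normal((n, lam.shape[1])) @ chol.T
    noise = rng.standard_normal((n, lam.shape[0])) * np.sqrt(unique_var)
    x = scores @ lam.T + noise
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    cols = [f"var{i + 1:02d}" for i in range(lam.shape[0])]
    df = pd.DataFrame(x, columns=cols)
    df.insert(0, "area_id", [f"A{k + 1:03d}" for k in range(n)])
    return df


def icar_covariance(adjacency: AdjacencyMatrix, sigma_u: float) -> np.ndarray:
    """Moore-Penrose pseudo-inverse covariance of the sum-zero ICAR."""
    w = adjacency.dense()
    q = (np.diag(w.sum(axis=1)) - w) / sigma_u**2
    return np.linalg.pinv(q)


def sample_icar(
    adjacency: AdjacencyMatrix,
    sigma_u: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One draw from the intrinsic CAR distribution, constrained to sum to 0.

    The ICAR precision ``Q = sigma_u^-2 (D - W)`` is singular with null
    space span{1}; the draw lives in the orthogonal (sum-zero) subspace,
    generated along the non-null eigenvectors with variances ``1/lambda``.
    """
    if sigma_u <= 0:
        raise ValueError("sigma_u must be > 0")
    adjacency.require_connected()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = adjacency.dense()
    lap = np.diag(w.sum(axis=1)) - w
    evals, evecs = np.linalg.eigh(lap)
    # exactly one zero eigenvalue on a connected graph
    keep = evals > 1e-10 * evals.max()
    z = rng.standard_normal(keep.sum()) * sigma_u / np.sqrt(evals[keep])
    u = evecs[:, keep] @ z
    return u - u.mean()


def simulate_outcomes(
    spec: SimulationSpec,
    covariates=None,
    adjacency: Optional[AdjacencyMatrix] = None,
    area_map: Optional[AreaMap] = None,
    likelihood: str = "poisson",
) -> SyntheticDataset:
    """Generate outcome counts from the BYM model and package the truth.

    Survey sizes are uniform over ``survey_size_range``; relative risk is
    ``theta_i = exp(beta0 + x_i.beta + u_i + v_i)`` and counts are
    Poisson with mean ``baseline_rate * n_i * theta_i`` truncated at
    ``n_i`` (or Binomial(n_i, p) with ``likelihood='binomial'``).
    """
    if area_map is None:
        area_map = make_lattice(spec)
    if adjacency is None:
        adjacency = build_adjacency(area_map, rule="queen")
    if covariates is None:
        if spec.loading_matrix is not None:
            covariates = simulate_covariates(spec)
        else:
            import pandas as pd

            covariates = pd.DataFrame({"area_id": area_map.area_id})
    n = spec.n_areas
    xcols = [c for c in covariates.columns if c != "area_id"]
    p = len(spec.beta)
    if p > len(xcols):
        raise ValueError(f"beta has {p} entries but only {len(xcols)} covariates exist")
    if len(covariates) != n:
        raise ValueError("covariate row count != n_areas")
    x = covariates[xcols[:p]].to_numpy() if p else np.zeros((n, 0))

    rng = np.random.default_rng(spec.seed + 1)
    sizes = rng.integers(spec.survey_size_range[0], spec.survey_size_range[1] + 1, size=n)
    u = (
        sample_icar(adjacency, spec.sigma_u, seed=rng)
        if spec.sigma_u > 0
        else np.zeros(n)
    )
    v = rng.normal(0.0, spec.sigma_v, size=n) if spec.sigma_v > 0 else np.zeros(n)
    eta = spec.beta0 + (x @ spec.beta if p else 0.0) + u + v
    theta = np.exp(eta)
    if not np.isfinite(theta).all():
        raise FloatingPointError("relative risk overflow; check spec scales")
    rate = spec.baseline_rate * theta
    if (rate > 1).mean() > 0.05:
        raise ValueError(
            "baseline_rate * theta exceeds 1 in more than 5% of areas; "
            "implausible simulation spec"
        )
    if likelihood == "binomial":
        obs = rng.binomial(sizes, np.clip(rate, 0, 1))
    elif likelihood == "poisson":
        obs = np.minimum(rng.poisson(spec.baseline_rate * sizes * theta), sizes)
    else:
        raise ValueError("likelihood must be 'poisson' or 'binomial'")
    outcomes = OutcomeTable.from_counts(area_map.area_id, obs, sizes)
    truth = {
        "beta0": spec.beta0,
        "beta": spec.beta.copy(),
        "u": u,
        "v": v,
        "sigma_u": spec.sigma_u,
        "sigma_v": spec.sigma_v,
        "theta": theta,
        "covariate_names": xcols[:p],
    }
    return SyntheticDataset(
        area_map=area_map,
        adjacency=adjacency,
        covariates=covariates,
        outcomes=outcomes,
        truth=truth,
    )
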