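import numpy as np
import pytest
from shapely.geometry import box

from bymspat.bym_mcmc import BYMConfig, fit_bym
from bymspat.geo_adjacency import AdjacencyMatrix, AreaMap, build_adjacency
from bymspat.synthetic_data import SimulationSpec, default_loading_pattern, simulate_outcomes


def grid_area_map(nrows: int, ncols: int) -> AreaMap:
    ids, geoms = [], []
    for r in range(nrows):
        for c in range(ncols):
            ids.append(f"r{r}c{c}")
            geoms.append(box(c, -r - 1, c + 1, -r))
    return AreaMap(area_id=ids, geometry=geoms)


@pytest.fixture(scope="session")
def grid2x2():
    return grid_area_map(2, 2)


@pytest.fixture(scope="session")
def grid3x3():
    return grid_area_map(3, 3)


@pytest.fixture(scope="session")
def adj2x2_rook(grid2x2):
    return build_adjacency(grid2x2, rule="rook")


@pytest.fixture(scope="session")
def adj4_path():
    # simple path 0-1-2-3
    return AdjacencyMatrix(n=4, neighbours=[[1], [0, 2], [1, 3], [2]])


@pytest.fixture(scope="session")
def synthetic_small():
    """101-area dataset with two true covariate effects (0.5, -0.3)."""
    lam, phi, _ = default_loading_pattern()
    spec = SimulationSpec(
        n_areas=101,
        loading_matrix=lam,
        factor_correlations=phi,
        beta=np.array([0.5, -0.3]),
        sigma_u=0.3,
        sigma_v=0.1,
        seed=42,
    )
    return simulate_outcomes(spec)


@pytest.fixture(scope="session")
def short_fit(synthetic_small):
    """A quick 2-chain fit reused by summary/DIC/decomposition tests."""
    ds = synthetic_small
    X = ds.covariates[["var01", "var02"]].to_numpy()
    cfg = BYMConfig(burn_in=400, samples=400, seed=7)
    draws = fit_bym(ds.outcomes, X, ds.adjacency, cfg, covariate_names=["var01", "var02"])
    return ds, X, draws
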