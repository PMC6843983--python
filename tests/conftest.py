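import numpy as np
import pytest

from ecolattice import simulate
from ecolattice.spde import MaternSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lattice():
    """10x10 lattice of covariate cells, fixed seed."""
    cfg = simulate.GeneratorConfig(lattice_nx=10, lattice_ny=10, seed=2024)
    return simulate.generate_lattice(cfg)


@pytest.fixture(scope="session")
def glm_limit_fit():
    """No-random-effects dataset and its Poisson-GLM-limit fit (session-cached)."""
    import statsmodels.api as sm

    from ecolattice import model

    cfg = simulate.GeneratorConfig(
        lattice_nx=20,
        lattice_ny=20,
        beta={"intercept": float(np.log(150.0)), "landuse8[dense_forest]": float(np.log(1.384))},
        matern_count=MaternSpec(range_m=30_000.0, sd=0.0),
        iid_sd=0.0,
        seed=99,
    )
    lat = simulate.generate_lattice(cfg)
    counts, truth = simulate.generate_species_counts(lat, cfg)
    lat["species_count"] = counts.to_numpy()
    data, _ = model.model_data_from_cells(lat)
    spec = model.ModelSpec(
        field=MaternSpec(range_m=30_000.0, sd=1e-6),
        iid_sd=1e-6,
        optimize_hyper=False,
        n_draws=400,
        seed=5,
    )
    fitted = model.fit(data, spec)
    glm = sm.GLM(data.counts, data.X, family=sm.families.Poisson()).fit()
    return data, truth, fitted, glm
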