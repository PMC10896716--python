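import numpy as np
import pytest
from hypothesis import settings

from easidemand import model, prep, synth

settings.register_profile("ci", max_examples=50, deadline=None,
                          derandomize=True)
settings.load_profile("ci")


class ObsData:
    """Minimal observation container for parameter-level elasticity tests."""

    def __init__(self, lnp, lnx, z=None, cmeans=None, quartile=None,
                 group_names=()):
        self.lnp = np.atleast_2d(lnp)
        self.lnx = np.atleast_1d(lnx)
        self.z = z
        self.cmeans = cmeans
        self.quartile = quartile
        self.group_names = list(group_names)


def random_admissible(seed, n_groups=4, degree=2):
    """Admissible EASI parameters drawn through the DGP's rejection sampler."""
    cfg = synth.SynthConfig(n_groups=n_groups, poly_degree_true=degree,
                            seed=seed)
    prefs = synth.generate_preferences(cfg)
    params = model.EASIParameters(
        b=prefs.b, A=prefs.A, D=prefs.D, G=prefs.G,
        M=np.zeros((n_groups, 0)), theta=np.zeros(n_groups))
    return prefs, params


def random_obs(prefs, seed, n=12):
    rng = np.random.default_rng(seed)
    J = prefs.n_groups
    lnp = rng.normal(0.0, 0.2, (n, J))
    lnx = rng.normal(prefs.y_ref, 0.5, n)
    z = np.column_stack([np.log(rng.integers(1, 9, n)),
                         rng.integers(0, 2, n).astype(float),
                         rng.uniform(0.2, 0.8, n)])
    return ObsData(lnp, lnx, z=z, group_names=prefs.group_names)


def truth_parameters(prefs, data):
    """TruePreferences as EASIParameters padded to the prepared z width."""
    J = prefs.n_groups
    pad = data.z.shape[1] - prefs.G.shape[1]
    return model.EASIParameters(
        b=prefs.b, A=prefs.A, D=prefs.D,
        G=np.column_stack([prefs.G, np.zeros((J, pad))]),
        M=np.zeros((J, 0)), theta=np.zeros(J))


@pytest.fixture(scope="session")
def small_bundle():
    """J=4 panel, 300 households x 2 waves, full noise; quick fits."""
    cfg = synth.SynthConfig(n_households=300, n_waves=2, n_clusters=20,
                            n_groups=4, seed=11)
    prefs = synth.generate_preferences(cfg)
    panel = synth.generate_panel(cfg, prefs)
    data = prep.prepare(panel)
    return cfg, prefs, panel, data


@pytest.fixture(scope="session")
def small_fit(small_bundle):
    cfg, prefs, panel, data = small_bundle
    res = model.EASIDemandModel(data, degree=cfg.poly_degree_true).fit()
    return cfg, prefs, panel, data, res


@pytest.fixture(scope="session")
def default_fit():
    """The default study conditions: J=6, 2,000 households x 3 waves,
    censoring and quality/search confounding on (seed 1)."""
    cfg = synth.SynthConfig(seed=1)
    prefs = synth.generate_preferences(cfg)
    panel = synth.generate_panel(cfg, prefs)
    data = prep.prepare(panel)
    res = model.EASIDemandModel(data, degree=2).fit(compute_cov=False)
    return cfg, prefs, panel, data, res


@pytest.fixture(scope="session")
def clean_fit():
    """Policy-simulation conditions: default size, cleanly measured prices
    (no quality/search/item noise) so the two accounting bases coincide;
    censoring and cluster taste stay on."""
    cfg = synth.SynthConfig(seed=5, quality_loading=0.0, search_loading=0.0,
                            item_price_noise=0.0)
    prefs = synth.generate_preferences(cfg)
    panel = synth.generate_panel(cfg, prefs)
    data = prep.prepare(panel)
    dataT = synth.prepared_from_truth(panel)
    res = model.EASIDemandModel(data, degree=2).fit(compute_cov=False)
    return cfg, prefs, panel, data, dataT, res
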