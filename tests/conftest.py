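import numpy as np
import pytest

from recredit import ProjectSimConfig, build_assessment_map, synthetic


@pytest.fixture(scope="session")
def demo_landscape():
    return synthetic.demo_landscape(seed=11, n_conditions_per_supersection=500)


@pytest.fixture(scope="session")
def demo_inventory(demo_landscape):
    return synthetic.generate_inventory(demo_landscape)


@pytest.fixture(scope="session")
def demo_ground_truth(demo_landscape):
    return synthetic.landscape_ground_truth(demo_landscape)


@pytest.fixture(scope="session")
def demo_assessment_map(demo_landscape):
    return build_assessment_map(demo_landscape)


@pytest.fixture(scope="session")
def demo_portfolio(demo_landscape, demo_inventory):
    projects, gt = synthetic.generate_projects(
        ProjectSimConfig(n_projects=40, adverse_selection_strength=2.0, seed=11),
        demo_landscape,
        demo_inventory,
    )
    return projects, gt


@pytest.fixture(scope="session")
def stratified_landscape():
    return synthetic.density_stratified_landscape(seed=5, n_conditions_per_supersection=600)


@pytest.fixture(scope="session")
def stratified_inventory(stratified_landscape):
    return synthetic.generate_inventory(stratified_landscape)


@pytest.fixture(scope="session")
def homogeneous_landscape():
    return synthetic.density_homogeneous_landscape(seed=5, n_conditions_per_supersection=600)


@pytest.fixture(scope="session")
def homogeneous_inventory(homogeneous_landscape):
    return synthetic.generate_inventory(homogeneous_landscape)


@pytest.fixture(scope="session")
def demo_results(demo_landscape, demo_inventory, demo_portfolio):
    from recredit import CreditingAnalysis

    projects, _ = demo_portfolio
    analysis = CreditingAnalysis.from_landscape(demo_landscape, demo_inventory, projects)
    return analysis.fit(n_draws=1000, seed=11)


def weighted_mean(densities, acres):
    """Brute-force ratio-of-sums oracle used across inventory tests."""
    num = 0.0
    den = 0.0
    for d, a in zip(densities, acres, strict=True):
        num += d * a
        den += a
    return num / den


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
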