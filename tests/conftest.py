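import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sporekit import drive_model as dm

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def single_killer_config(kappa: float, pi: float,
                         killer_id: str = "k") -> dm.CrossConfig:
    """Heterozygous single-killer cross at one locus."""
    return dm.CrossConfig(
        loci=[dm.Locus("L", "chr3", 3_000_000)],
        parent1={"L": "ref"},
        parent2={"L": killer_id},
        killers=[dm.KillerAllele(killer_id, "L", kappa, pi)])


def random_supported_newick(n_leaves: int, rng: np.random.Generator,
                            support_range=(50, 100)) -> str:
    """Random binary tree by sequential joining, with branch lengths and
    integer support labels on internal nodes."""
    nodes = [f"L{i}:{rng.uniform(0.1, 2.0):.4f}" for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        sup = int(rng.integers(support_range[0], support_range[1] + 1))
        nodes.append(f"({a},{b}){sup}:{rng.uniform(0.1, 2.0):.4f}")
    return f"({nodes[0]},{nodes[1]});"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
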