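import numpy as np
import pytest

from vinecover import CriterionSpec, make_decision_matrix
from vinecover.topsis import BENEFIT, COST


@pytest.fixture
def toy_3x2():
    """3 alternatives x 2 criteria (benefit, cost), weights (0.6, 0.4)."""
    return make_decision_matrix(
        [[7, 2], [8, 3], [9, 1]],
        ["a", "b", "c"],
        [CriterionSpec("quality", BENEFIT, 0.6), CriterionSpec("price", COST, 0.4)],
    )


def random_decision_matrix(rng, n=None, m=None):
    """Random positive-valued matrix with random directions and weights."""
    n = n or rng.integers(2, 8)
    m = m or rng.integers(1, 6)
    x = rng.uniform(0.1, 10.0, size=(n, m))
    w = rng.dirichlet(np.ones(m))
    dirs = rng.choice([BENEFIT, COST], size=m)
    crits = [CriterionSpec(f"c{j}", dirs[j], float(w[j])) for j in range(m)]
    return make_decision_matrix(x, [f"a{i}" for i in range(n)], crits)
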