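import numpy as np
import pytest

from cogsoc import MMSBMParams, RatingsTable, synthetic
from cogsoc._rng import rng_for
from cogsoc.sociogram import Classroom
from cogsoc.synthetic import SociogramSpec, _planted_classroom_profiles


def random_params(U, T, K, L, rng):
    """A valid random parameter set (not via the package's initializer)."""
    theta = rng.dirichlet(np.ones(K), size=U)
    eta = rng.dirichlet(np.ones(L), size=T)
    p = rng.dirichlet(np.ones(5), size=(K, L))
    return MMSBMParams(theta, eta, p)


def random_links(U, T, rng, n=None):
    """Random duplicate-free links covering every user and task."""
    pairs = [(u, t) for u in range(U) for t in range(T)]
    if n is not None:
        keep = rng.choice(len(pairs), size=n, replace=False)
        pairs = [pairs[i] for i in sorted(keep)]
    return [(u, t, int(rng.integers(1, 6))) for u, t in pairs]


def table_from_links(links, U, T):
    return RatingsTable.from_links(
        [(f"u{u}", f"t{t}", s) for u, t, s in links],
        users=[f"u{u}" for u in range(U)],
        tasks=[f"t{t}" for t in range(T)],
    )


def make_test_classroom(n=25, seed=0, cid="c0", age=10, balanced_gender=True):
    """A classroom with planted-pattern profiles; returns (classroom, profiles)."""
    rng = rng_for(seed, "testclass", cid)
    ids = tuple(f"{cid}s{i:02d}" for i in range(n))
    if balanced_gender:
        genders = {s: ("boy" if i % 2 == 0 else "girl") for i, s in enumerate(ids)}
    else:
        genders = {
            s: rng.choice(list(synthetic.GENDER_PROBS),
                          p=list(synthetic.GENDER_PROBS.values()))
            for s in ids
        }
    classroom = Classroom(classroom_id=cid, age=age, students=ids, gender=genders)
    theta = _planted_classroom_profiles(n, rng)
    return classroom, {s: theta[i] for i, s in enumerate(ids)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_population():
    return synthetic.make_planted_params(300, 10, seed=42)


@pytest.fixture(scope="session")
def planted_ratings(planted_population):
    return synthetic.sample_ratings(planted_population, coverage=1.0, seed=42)


@pytest.fixture
def uniform_spec():
    return SociogramSpec(0.0, 0.0, 0.0)
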