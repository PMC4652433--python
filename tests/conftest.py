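import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from famrisk.pedigree import (
    CancerHistory,
    Pedigree,
    Relative,
    RelativeRole,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


GROUP_ROLE_LIST = [
    RelativeRole.MATERNAL_AUNT_UNCLE,
    RelativeRole.MATERNAL_AUNT_UNCLE_CHILD,
    RelativeRole.PATERNAL_AUNT_UNCLE,
    RelativeRole.PATERNAL_AUNT_UNCLE_CHILD,
    RelativeRole.SIBLING,
    RelativeRole.CHILD,
]


def random_pedigree(rng: np.random.Generator, max_relatives: int = 5) -> Pedigree:
    """Light random pedigree builder used by the oracle and property suites.

    Samples relative slots without replacement, draws ages from
    {unknown} ∪ [40, 80] and history flags independently.  Intentionally
    distinct from famrisk.simulate.gen_pedigree.
    """
    slots = [(role, 0) for role in RelativeRole] + [
        (role, idx) for role in GROUP_ROLE_LIST for idx in (1, 2)
    ]
    n = int(rng.integers(0, max_relatives + 1))
    chosen = rng.choice(len(slots), size=min(n, len(slots)), replace=False)
    counters: dict = {}
    relatives = []
    for i in chosen:
        role, _ = slots[int(i)]
        idx = counters.get(role, 0)  # contiguous member indices per role
        counters[role] = idx + 1
        age = None if rng.random() < 0.2 else int(rng.integers(40, 81))
        relatives.append(
            Relative(
                role,
                idx,
                CancerHistory(
                    affected=True,
                    age_at_diagnosis=age,
                    multiple_polyps=bool(rng.random() < 0.08),
                    other_related_cancers=bool(rng.random() < 0.12),
                    multiple_primary_crc=bool(rng.random() < 0.06),
                ),
            )
        )
    return Pedigree(tuple(sorted(relatives, key=Relative.sort_key)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def mother_at_60():
    return Pedigree.of(Relative(RelativeRole.MOTHER, 0, CancerHistory(True, 60)))


@pytest.fixture
def two_sided_pedigree():
    return Pedigree.of(
        Relative(RelativeRole.MOTHER, 0, CancerHistory(True, 60)),
        Relative(RelativeRole.MATERNAL_GRANDFATHER, 0, CancerHistory(True, 70)),
    )
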