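import random

import numpy as np
import pytest

from faakit.profiling import CANONICAL, MultipleAlignment

AA = CANONICAL


def make_alignment(rows, subtype="other", ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return MultipleAlignment(ids=ids, rows=list(rows), subtype=subtype)


def random_alignment(rng: random.Random, max_rows=12, max_cols=30, gap_prob=0.15):
    n = rng.randint(2, max_rows)
    m = rng.randint(1, max_cols)
    rows = [
        "".join(
            "-" if rng.random() < gap_prob else rng.choice(AA) for _ in range(m)
        )
        for _ in range(n)
    ]
    return make_alignment(rows)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def nprng():
    return np.random.default_rng(20240917)
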