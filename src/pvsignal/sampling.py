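"""Seeded simple random sampling of non-cases at a fixed ratio per case.

The generator is pinned to numpy's PCG64 via ``numpy.random.default_rng``
so that a published (seed, input order) pair replays exactly.  Sampling is
unstratified: the design states no matching variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SamplingPlan", "PoolTooSmallError", "sample_noncases"]


class PoolTooSmallError(ValueError):
    """The non-case pool cannot supply ratio x n_cases distinct reports."""


@dataclass(frozen=True)
class SamplingPlan:
    ratio: int
    seed: int
    pool_size: int
    n_cases: int

    @property
    def sample_size(self) -> int:
        return self.ratio * self.n_cases

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be a positive integer")
        if self.sample_size > self.pool_size:
            raise PoolTooSmallError(
                f"need {self.sample_size} non-cases "
                f"({self.ratio} x {self.n_cases}) but pool has {self.pool_size}"
            )


def sample_noncases(noncases: Sequence, n_cases: int, ratio: int, seed: int) -> list:
    """Draw ratio x n_cases non-cases uniformly without replacement.

    Deterministic for identical (input order, seed); the sample is returned
    sorted by ``report_id`` so downstream artifacts are stable.
    """
    plan = SamplingPlan(ratio=ratio, seed=seed, pool_size=len(noncases), n_cases=n_cases)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(noncases), size=plan.sample_size, replace=False)
    return sorted((noncases[i] for i in idx), key=lambda r: r.report_id)
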