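"""Case-control sample construction.

Cases for one phenotype definition are paired 1-to-1 with healthy controls
(subjects carrying no case flag under any definition), matched exactly on
sex and greedily on the smallest combined age/ICV difference, without
replacement. Comorbid subjects are excluded from both sides first, and an
optional CTQ threshold is applied to the cases before matching so the final
sample is always balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord

__all__ = [
    "MatchedPair",
    "MatchedSample",
    "MatchingError",
    "exclude_comorbid",
    "apply_ctq_threshold",
    "eligible_controls",
    "match_one_to_one",
]


class MatchingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MatchedPair:
    case_id: str
    control_id: str
    age_diff: float   # years, case minus control
    icv_diff: float   # mm^3, case minus control


@dataclass
class MatchedSample:
    """Ordered 1-to-1 case-control pairs for one phenotype definition."""

    phenotype: str
    ctq_threshold: float | None
    pairs: list[MatchedPair] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def case_ids(self) -> list[str]:
        return [p.case_id for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p.control_id for p in self.pairs]

    @property
    def subject_ids(self) -> list[str]:
        """Cases then controls, pair order preserved."""
        return self.case_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_ids,
                "control_id": self.control_ids,
                "age_diff": [p.age_diff for p in self.pairs],
                "icv_diff": [p.icv_diff for p in self.pairs],
            }
        )


def exclude_comorbid(subjects: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Drop subjects with a comorbid-disorder exclusion flag."""
    return [s for s in subjects if not s.excluded]


def apply_ctq_threshold(
    cases: Iterable[SubjectRecord], tau: float | None
) -> list[SubjectRecord]:
    """Keep cases with CTQ score >= tau (inclusive); ``tau=None`` is identity."""
    cases = list(cases)
    if tau is None:
        return cases
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"CTQ threshold must lie in [0, 1], got {tau}")
    return [c for c in cases if c.ctq >= tau]


def eligible_controls(subjects: Iterable[SubjectRecord]) -> list[SubjectRecord]:
    """Healthy-control pool: no case flag under any definition, not excluded."""
    return [s for s in subjects if not s.excluded and not s.any_flag()]


def match_one_to_one(
    cases: Sequence[SubjectRecord],
    control_pool: Sequence[SubjectRecord],
    phenotype: str = "",
    ctq_threshold: float | None = None,
    rng: np.random.Generator | None = None,  # unused; the procedure is deterministic
) -> MatchedSample:
    """Greedy sex-exact nearest-neighbour matching without replacement.

    Cases are processed in ascending id order. For each case, among the
    unused same-sex controls, the minimiser of

        d = |age_case - age_control| / sigma_age + |icv_case - icv_control| / sigma_icv

    is chosen, where the scales are standard deviations over the full control
    pool; ties break toward the smallest control id. The result does not
    depend on the input order of the pool.
    """
    if len(cases) == 0:
        raise MatchingError("no cases to match")
    if len(control_pool) == 0:
        raise MatchingError("empty control pool")
    case_ids = {c.id for c in cases}
    for s in control_pool:
        if s.id in case_ids:
            raise MatchingError(f"control pool contains case {s.id}")
        if s.any_flag():
            raise MatchingError(f"control {s.id} carries a phenotype flag")

    pool = sorted(control_pool, key=lambda s: s.id)
    pool_age = np.array([s.age for s in pool])
    pool_icv = np.array([s.icv for s in pool])
    pool_female = np.array([s.sex == "female" for s in pool])
    sigma_age = pool_age.std() or 1.0
    sigma_icv = pool_icv.std() or 1.0
    used = np.zeros(len(pool), dtype=bool)

    pairs = []
    for case in sorted(cases, key=lambda s: s.id):
        candidates = np.flatnonzero(~used & (pool_female == (case.sex == "female")))
        if len(candidates) == 0:
            raise MatchingError(
                f"no unused {case.sex} control remains for case {case.id}"
            )
        d = (
            np.abs(case.age - pool_age[candidates]) / sigma_age
            + np.abs(case.icv - pool_icv[candidates]) / sigma_icv
        )
        pick = candidates[int(np.argmin(d))]  # pool sorted by id => ties -> smallest id
        used[pick] = True
        ctrl = pool[pick]
        pairs.append(
            MatchedPair(
                case_id=case.id,
                control_id=ctrl.id,
                age_diff=case.age - ctrl.age,
                icv_diff=case.icv - ctrl.icv,
            )
        )
    return MatchedSample(phenotype=phenotype, ctq_threshold=ctq_threshold, pairs=pairs)
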