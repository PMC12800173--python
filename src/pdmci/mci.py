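"""Clinical diagnostic reference test: comprehensive-assessment PD-MCI
classification and cognitive domain profiling.

The comprehensive (two-tests-per-domain) operationalisation used here flags
a test as impaired when its covariate-adjusted z-score is 1.5 SD or more
below the normative mean (z <= -1.5, boundary inclusive), and classifies a
person with PD as PD-MCI when at least two of the ten battery tests are
impaired, regardless of whether they probe the same domain or different
domains.

Domain-level impairment for profiling — not part of the MCI rule itself —
is defined as at least one of the domain's two tests impaired; profiles are
then none / single-domain / multi-domain, with an amnestic flag when the
memory domain is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .schema import DOMAINS, TESTS, z_col

DEFAULT_THRESHOLD = -1.5
MIN_IMPAIRED_TESTS = 2


@dataclass
class CognitiveStatus:
    participant_id: object
    impaired_tests: frozenset
    untested: frozenset
    status: str  # "NC" | "MCI"
    domain_impaired: dict = field(default_factory=dict)
    profile: str = "none"  # none | single_domain | multi_domain
    amnestic: bool = False

    @property
    def n_impaired(self) -> int:
        return len(self.impaired_tests)

    @property
    def complete(self) -> bool:
        return not self.untested


def impairment_flags(
    z_row: pd.Series, threshold: float = DEFAULT_THRESHOLD
) -> tuple[frozenset, frozenset]:
    """Impaired and untested test sets for one z-score profile.

    ``z_row`` holds ``z_<test>`` entries oriented lower = worse. A test is
    impaired iff z <= threshold (inclusive); a missing z marks the test as
    untested, never as impaired.
    """
    if threshold >= 0:
        warnings.warn(
            f"impairment threshold {threshold} is non-negative; "
            "z-scores are oriented lower = worse",
            stacklevel=2,
        )
    impaired, untested = set(), set()
    for test in TESTS:
        z = z_row.get(z_col(test))
        if z is None or z != z:
            untested.add(test)
        elif z <= threshold:
            impaired.add(test)
    return frozenset(impaired), frozenset(untested)


def classify_level2(
    impaired: frozenset, untested: frozenset = frozenset(), participant_id=None
) -> CognitiveStatus:
    """Apply the two-test rule and derive the domain profile."""
    status = "MCI" if len(impaired) >= MIN_IMPAIRED_TESTS else "NC"
    domain_impaired = {
        d: any(t in impaired for t in pair) for d, pair in DOMAINS.items()
    }
    n_domains = sum(domain_impaired.values())
    profile = "none" if n_domains == 0 else ("single_domain" if n_domains == 1 else "multi_domain")
    return CognitiveStatus(
        participant_id=participant_id,
        impaired_tests=impaired,
        untested=untested,
        status=status,
        domain_impaired=domain_impaired,
        profile=profile,
        amnestic=domain_impaired["memory"],
    )


def classify_cohort(
    zscores: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Classify every row of a z-score table.

    Returns one row per input row: status, n_impaired, impaired_tests
    (comma-joined), profile, amnestic, per-domain impairment flags, and a
    completeness flag (participants with untested items remain classifiable
    but carry the caveat).
    """
    records = []
    for idx, row in zscores.iterrows():
        impaired, untested = impairment_flags(row, threshold)
        st = classify_level2(impaired, untested, row.get("participant_id", idx))
        rec = {
            "participant_id": st.participant_id,
            "status": st.status,
            "n_impaired": st.n_impaired,
            "impaired_tests": ",".join(sorted(st.impaired_tests)),
            "profile": st.profile,
            "amnestic": st.amnestic,
            "complete": st.complete,
        }
        for d in DOMAINS:
            rec[f"domain_{d}"] = st.domain_impaired[d]
        records.append(rec)
    return pd.DataFrame(records, index=zscores.index)


def profile_summary(classified: pd.DataFrame) -> dict:
    """Per-domain impairment proportions and the none/single/multi breakdown."""
    n = len(classified)
    if n == 0:
        return {"n": 0, "domains": {}, "profiles": {}}
    return {
        "n": n,
        "domains": {
            d: float(classified[f"domain_{d}"].mean()) for d in DOMAINS
        },
        "profiles": {
            p: float((classified["profile"] == p).mean())
            for p in ("none", "single_domain", "multi_domain")
        },
    }
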