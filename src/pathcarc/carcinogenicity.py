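"""Poly-3 survival-adjusted carcinogenicity statistic and binary tumor calls.

The two-year rodent bioassay target is a pooled two-proportion z statistic
on survival-adjusted tumor incidence.  Animals dying tumor-free before
terminal sacrifice contribute fractional weight (death-time fraction cubed)
to the effective group size; tumor-bearing animals and terminal survivors
contribute 1.  Upper outliers are capped at the standard-normal critical
value for 2e-5 significance; binary calls use a one-sided p <= 0.01 rule,
so equivocal bioassay outcomes (one-sided p around 0.075-0.084) fall on
the negative side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "BioassayRecord",
    "CarcinogenicityTarget",
    "Z_CAP",
    "CALL_P_THRESHOLD",
    "poly3_z",
    "cap_z",
    "binary_call",
    "poly3_adjusted_counts",
    "read_bioassay_tsv",
    "write_bioassay_tsv",
]

#: upper cap on the poly-3 z: standard-normal critical value at 2e-5 significance
Z_CAP = float(stats.norm.isf(2e-5))

#: one-sided significance threshold for a positive carcinogenicity call
CALL_P_THRESHOLD = 0.01


@dataclass(frozen=True)
class BioassayRecord:
    """Survival-adjusted counts and tumor proportions for one chemical.

    Adjusted animal counts are real-valued (poly-3 weights are fractional).
    """

    chemical_id: str
    n_treat: float
    p_treat: float
    n_cont: float
    p_cont: float

    def __post_init__(self):
        problems = []
        if not self.n_treat > 0:
            problems.append(f"n_treat={self.n_treat} must be > 0")
        if not self.n_cont > 0:
            problems.append(f"n_cont={self.n_cont} must be > 0")
        if not 0.0 <= self.p_treat <= 1.0:
            problems.append(f"p_treat={self.p_treat} must be in [0, 1]")
        if not 0.0 <= self.p_cont <= 1.0:
            problems.append(f"p_cont={self.p_cont} must be in [0, 1]")
        if problems:
            raise ValueError(
                f"invalid bioassay record {self.chemical_id!r}: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class CarcinogenicityTarget:
    chemical_id: str
    z_raw: float
    z_capped: float
    call: str  # 'positive' | 'negative'
    p_one_sided: float


def poly3_z(rec: BioassayRecord) -> float:
    """Pooled two-proportion z on survival-adjusted incidence.

    z = (p_t - p_c) / sqrt(phat (1 - phat) (1/n_t + 1/n_c)) with
    phat the adjusted-count-weighted pooled proportion; z = 0 when the
    pooled proportion is degenerate (0 or 1).
    """
    phat = (rec.n_treat * rec.p_treat + rec.n_cont * rec.p_cont) / (
        rec.n_treat + rec.n_cont
    )
    if phat <= 0.0 or phat >= 1.0:
        return 0.0
    se = math.sqrt(phat * (1.0 - phat) * (1.0 / rec.n_treat + 1.0 / rec.n_cont))
    return (rec.p_treat - rec.p_cont) / se


def cap_z(z: float) -> float:
    """Cap upper outliers at the 2e-5 critical value; the lower tail is untouched."""
    return min(z, Z_CAP)


def binary_call(rec: BioassayRecord) -> CarcinogenicityTarget:
    """Positive iff the one-sided upper-tail p of the raw z is <= 0.01."""
    z = poly3_z(rec)
    p = float(stats.norm.sf(z))
    call = "positive" if p <= CALL_P_THRESHOLD else "negative"
    return CarcinogenicityTarget(rec.chemical_id, z, cap_z(z), call, p)


def poly3_adjusted_counts(animals: Sequence[tuple]) -> tuple:
    """Survival-adjusted (n, tumor proportion) from per-animal outcomes.

    ``animals`` holds (death_time, tumor) pairs with death_time the fraction
    of the study length in (0, 1].  A tumor-free animal dying at time t
    weighs t**3; tumor-bearing animals and terminal survivors weigh 1.
    """
    if not animals:
        raise ValueError("at least one animal is required")
    n_adj = 0.0
    tumors = 0
    for death_time, tumor in animals:
        if not 0.0 < death_time <= 1.0:
            raise ValueError(f"death_time {death_time} outside (0, 1]")
        if tumor:
            tumors += 1
            n_adj += 1.0
        else:
            n_adj += 1.0 if death_time >= 1.0 else death_time**3
    return n_adj, tumors / n_adj


def read_bioassay_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = ["chemical_id", "n_treat", "p_treat", "n_cont", "p_cont"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"bioassay file {path} missing columns: {missing}")
    return [
        BioassayRecord(
            str(r.chemical_id),
            float(r.n_treat),
            float(r.p_treat),
            float(r.n_cont),
            float(r.p_cont),
        )
        for r in df.itertuples(index=False)
    ]


def write_bioassay_tsv(records: Sequence[BioassayRecord], path, with_calls: bool = False) -> None:
    rows = []
    for rec in records:
        row = {
            "chemical_id": rec.chemical_id,
            "n_treat": rec.n_treat,
            "p_treat": rec.p_treat,
            "n_cont": rec.n_cont,
            "p_cont": rec.p_cont,
        }
        if with_calls:
            tgt = binary_call(rec)
            row.update(
                z_raw=tgt.z_raw,
                z_capped=tgt.z_capped,
                p_one_sided=tgt.p_one_sided,
                call=tgt.call,
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
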