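"""Comparative relative expression from qPCR Ct values.

Each measurement is a threshold cycle (Ct) for a target transcript and
for a single-copy reference gene (ACTIN) in the same sample.  The
normalized difference between a test and a reference sample gives
ddCt, and the relative quantity is

    RQ = (2 x primer efficiency) ** (-ddCt)

with efficiency expressed as a fraction in (0, 1] (efficiency 1 recovers
the familiar 2^-ddCt).  A convention flag switches to the
(1 + efficiency) base some instruments report; it is off by default.
Technical replicates are averaged to one Ct before ddCt; biological
replicates propagate to the replicate SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sinescan")

CT_COLUMNS = ["sample", "transcript", "bio_rep", "tech_rep",
              "target_ct", "reference_ct", "efficiency"]


@dataclass
class QpcrMeasurement:
    """One (sample, transcript) measurement: target and reference Ct."""

    sample_id: str
    transcript: str  # e.g. "regular" | "element_containing"
    target_ct: float
    reference_ct: float
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name, ct in (("target_ct", self.target_ct),
                         ("reference_ct", self.reference_ct)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not (0 < self.efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


@dataclass
class RelativeExpression:
    mean_rq: float
    sd: float | None  # None (flagged) with < 2 replicates
    n: int


def delta_delta_ct(test: QpcrMeasurement, reference: QpcrMeasurement) -> float:
    """(Ct_target - Ct_actin)_test - (Ct_target - Ct_actin)_reference."""
    if test.transcript != reference.transcript:
        raise ValueError("ddCt requires the same target in both samples")
    return test.delta_ct - reference.delta_ct


def relative_quantity(ddct: float, efficiency: float = 1.0,
                      convention: str = "doubling") -> float:
    """RQ = base ** (-ddCt); base = 2*efficiency ("doubling", default)
    or 1+efficiency ("one_plus")."""
    if convention == "doubling":
        base = 2.0 * efficiency
    elif convention == "one_plus":
        base = 1.0 + efficiency
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if base <= 0:
        raise ValueError("non-positive base")
    return base ** (-ddct)


def summarize_replicates(rqs: Sequence[float]) -> RelativeExpression:
    """Mean RQ and sample SD over biological replicates (SD flagged None
    with fewer than 2)."""
    arr = np.asarray(list(rqs), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicates")
    if arr.size < 2:
        logger.warning("single replicate: SD undefined")
        return RelativeExpression(float(arr.mean()), None, 1)
    return RelativeExpression(float(arr.mean()), float(arr.std(ddof=1)),
                              int(arr.size))


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def analyze_ct_table(df: pd.DataFrame, reference_sample: str,
                     convention: str = "doubling") -> pd.DataFrame:
    """Full ddCt workflow over a tidy Ct table.

    Technical replicates are averaged per (sample, transcript, bio_rep);
    each biological replicate's ddCt is taken against the matching
    biological replicate of ``reference_sample``; RQs are then summarized
    per (sample, transcript).
    """
    tech = (df.groupby(["sample", "transcript", "bio_rep"], as_index=False)
              .agg(target_ct=("target_ct", "mean"),
                   reference_ct=("reference_ct", "mean"),
                   efficiency=("efficiency", "mean")))
    ref = tech[tech["sample"] == reference_sample].set_index(
        ["transcript", "bio_rep"])
    if ref.empty:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    rows = []
    for (sample, transcript), grp in tech.groupby(["sample", "transcript"]):
        rqs = []
        for _, r in grp.iterrows():
            try:
                rrow = ref.loc[(transcript, r["bio_rep"])]
            except KeyError:
                logger.warning("no reference bio_rep %s for %s/%s",
                               r["bio_rep"], sample, transcript)
                continue
            test = QpcrMeasurement(sample, transcript, r["target_ct"],
                                   r["reference_ct"], r["efficiency"])
            refm = QpcrMeasurement(reference_sample, transcript,
                                   rrow["target_ct"], rrow["reference_ct"],
                                   rrow["efficiency"])
            rqs.append(relative_quantity(delta_delta_ct(test, refm),
                                         r["efficiency"], convention))
        if not rqs:
            continue
        summ = summarize_replicates(rqs)
        rows.append({"sample": sample, "transcript": transcript,
                     "mean_rq": summ.mean_rq, "sd": summ.sd, "n": summ.n})
    return pd.DataFrame(rows, columns=["sample", "transcript", "mean_rq",
                                       "sd", "n"])
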