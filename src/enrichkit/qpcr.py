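"""Comparative-CT (delta-delta-CT) relative quantification for qRT-PCR.

Per sample: dCT = CT_target - CT_reference (reference gene from the same
well/sample, e.g. 18S rRNA).  ddCT = dCT - calibrator dCT; relative
quantity RQ = efficiency**(-ddCT) with the classic efficiency of 2.
Group comparison is a two-tailed two-sample t-test on per-replicate RQs
(pooled variance by default), significance at 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CtMeasurement",
    "RelativeQuantity",
    "GroupComparison",
    "ddct_rq",
    "compare_groups",
]


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    group: str
    gene: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not 0.0 < ct < 45.0:
                raise ValueError(
                    f"sample {self.sample_id!r} gene {self.gene!r}: {name}={ct} "
                    "outside (0, 45) cycles"
                )
        if self.replicate < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate must be >= 1, got {self.replicate}"
            )


@dataclass(frozen=True)
class RelativeQuantity:
    sample_id: str
    group: str
    gene: str
    replicate: int
    delta_ct: float
    delta_delta_ct: float
    rq: float


@dataclass(frozen=True)
class GroupComparison:
    gene: str
    group_a: str
    group_b: str
    mean_rq_a: float
    mean_rq_b: float
    t_statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False  # zero within-group variance fallback used


def ddct_rq(
    measurements: Sequence[CtMeasurement],
    calibrator: str,
    efficiency: float = 2.0,
) -> list[RelativeQuantity]:
    """Relative quantities per sample, calibrated on a group mean or sample.

    ``calibrator`` names either a group (then per gene the calibrator dCT
    is that group's mean dCT, so the calibrator group's geometric-mean RQ
    is 1) or a single sample_id.  Duplicate (sample_id, gene) rows raise.
    """
    if efficiency <= 1.0:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    if not measurements:
        return []

    seen: set[tuple[str, str]] = set()
    for m in measurements:
        key = (m.sample_id, m.gene)
        if key in seen:
            raise ValueError(
                f"duplicate measurement for sample {m.sample_id!r} gene {m.gene!r}"
            )
        seen.add(key)

    groups = {m.group for m in measurements}
    sample_ids = {m.sample_id for m in measurements}
    if calibrator not in groups and calibrator not in sample_ids:
        raise ValueError(
            f"calibrator {calibrator!r} matches neither a group nor a sample"
        )

    genes = {m.gene for m in measurements}
    cal_dct: dict[str, float] = {}
    for gene in genes:
        if calibrator in groups:
            vals = [
                m.ct_target - m.ct_reference
                for m in measurements
                if m.gene == gene and m.group == calibrator
            ]
        else:
            vals = [
                m.ct_target - m.ct_reference
                for m in measurements
                if m.gene == gene and m.sample_id == calibrator
            ]
        if not vals:
            raise ValueError(
                f"gene {gene!r}: no calibrator measurements ({calibrator!r})"
            )
        cal_dct[gene] = float(np.mean(vals))

    out = []
    for m in measurements:
        dct = m.ct_target - m.ct_reference
        ddct = dct - cal_dct[m.gene]
        out.append(
            RelativeQuantity(
                sample_id=m.sample_id,
                group=m.group,
                gene=m.gene,
                replicate=m.replicate,
                delta_ct=dct,
                delta_delta_ct=ddct,
                rq=float(efficiency ** (-ddct)),
            )
        )
    return out


def compare_groups(
    rqs: Iterable[RelativeQuantity],
    alpha: float = 0.05,
    equal_var: bool = True,
    log2_scale: bool = False,
) -> list[GroupComparison]:
    """Two-tailed two-sample t-test per gene between the two groups.

    Defaults to the pooled-variance Student test on RQ values;
    ``equal_var=False`` switches to Welch and ``log2_scale`` tests
    log2(RQ) instead (variance stabilisation).  Groups with zero variance
    get an exact-separation fallback (p = 0 if the means differ, 1 if not)
    flagged as degenerate.
    """
    rqs = list(rqs)
    genes = sorted({r.gene for r in rqs})
    comparisons = []
    for gene in genes:
        sub = [r for r in rqs if r.gene == gene]
        groups = sorted({r.group for r in sub})
        if len(groups) != 2:
            raise ValueError(
                f"gene {gene!r}: expected exactly 2 groups, got {groups}"
            )
        ga, gb = groups
        a = np.array([r.rq for r in sub if r.group == ga], dtype=float)
        b = np.array([r.rq for r in sub if r.group == gb], dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"gene {gene!r}: each group needs >= 2 replicates "
                f"(got {len(a)} vs {len(b)})"
            )
        va = np.log2(a) if log2_scale else a
        vb = np.log2(b) if log2_scale else b
        degenerate = va.var(ddof=1) == 0.0 and vb.var(ddof=1) == 0.0
        if degenerate:
            separated = va.mean() != vb.mean()
            t_stat = math.inf if separated else 0.0
            p = 0.0 if separated else 1.0
        else:
            t_stat, p = stats.ttest_ind(va, vb, equal_var=equal_var)
            t_stat, p = float(t_stat), float(p)
        comparisons.append(
            GroupComparison(
                gene=gene,
                group_a=ga,
                group_b=gb,
                mean_rq_a=float(a.mean()),
                mean_rq_b=float(b.mean()),
                t_statistic=t_stat,
                p_value=p,
                significant=bool(p < alpha),
                degenerate=degenerate,
            )
        )
    return comparisons
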