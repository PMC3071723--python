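"""Exact two-library enrichment testing on per-contig read counts.

The statistic is the classic two-library digital-expression test: under the
null hypothesis that a contig is sampled at the same per-read rate in both
libraries, the count ``y`` in library B conditional on the combined count
``t = x + y`` is Binomial(t, q) with ``q = N_B / (N_A + N_B)``.  The
conditional point mass can be written

    p(y | x) = (N_B/N_A)^y * (x+y)! / (x! * y! * (1 + N_B/N_A)^(x+y))

which is algebraically identical to the binomial mass at ``y``.  Everything
is evaluated in log space (``gammaln`` for the factorials, regularised
incomplete beta for the tails) so that counts up to 10^6 neither overflow
nor lose the tiny tail probabilities this analysis lives on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import betainc, gammaln

__all__ = [
    "Partition",
    "Direction",
    "Basis",
    "ContigCountRecord",
    "LibrarySizes",
    "EnrichmentConfig",
    "EnrichmentCall",
    "PartitionSummary",
    "ac_point_probability",
    "ac_pvalue",
    "fold_enrichment",
    "classify_partition",
    "call_enrichment",
    "robust_candidates",
]


class Partition(str, enum.Enum):
    MIXED = "mixed"
    A_ONLY = "a_only"
    B_ONLY = "b_only"


class Direction(str, enum.Enum):
    A = "A"
    B = "B"
    NONE = "none"


class Basis(str, enum.Enum):
    ALL_READS = "all_reads"
    READS_IN_CONTIGS = "reads_in_contigs"


@dataclass(frozen=True)
class ContigCountRecord:
    """Read counts for one contig in library A and library B."""

    contig_id: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(
                f"contig {self.contig_id!r}: counts must be non-negative "
                f"(got x={self.x}, y={self.y})"
            )


@dataclass(frozen=True)
class LibrarySizes:
    """Total read counts of the two libraries.

    ``basis`` records whether the totals are raw library yields or only the
    reads that ended up inside contigs; the test itself only uses the ratio.
    """

    n_a: int
    n_b: int
    basis: Basis = Basis.READS_IN_CONTIGS

    def __post_init__(self) -> None:
        if self.n_a <= 0 or self.n_b <= 0:
            raise ValueError(
                f"library sizes must be positive (got n_a={self.n_a}, n_b={self.n_b})"
            )

    @property
    def q_b(self) -> float:
        """Null success probability for the count in library B."""
        return self.n_b / (self.n_a + self.n_b)


class Sidedness(str, enum.Enum):
    ONE_SIDED = "one_sided"
    TWO_SIDED = "two_sided"


class RobustRule(str, enum.Enum):
    FOLD = "fold"
    READS = "reads"
    EITHER = "either"


@dataclass(frozen=True)
class EnrichmentConfig:
    """Thresholds and switches for enrichment calling.

    Defaults follow the study design: raw p-value cutoff 0.001, two-sided
    min-tail-doubled p-values, robust candidates selected by >=100-fold
    enrichment or >100 reads in one library (``either``), exclusive contigs
    excluded from testing, no multiple-testing correction.
    """

    alpha: float = 0.001
    sidedness: Sidedness = Sidedness.TWO_SIDED
    robust_min_fold: float = 100.0
    robust_min_reads: int = 100
    robust_rule: RobustRule = RobustRule.EITHER
    include_exclusive: bool = False
    fdr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.robust_min_fold < 1.0:
            raise ValueError(
                f"robust_min_fold must be >= 1, got {self.robust_min_fold}"
            )
        if self.robust_min_reads < 0:
            raise ValueError(
                f"robust_min_reads must be >= 0, got {self.robust_min_reads}"
            )


@dataclass
class EnrichmentCall:
    """Per-contig result of the enrichment test."""

    contig_id: str
    partition: Partition
    x: int
    y: int
    rate_a: float
    rate_b: float
    fold: float
    p_value: float | None
    direction: Direction
    enriched: bool
    robust: bool = False
    robust_by: tuple[str, ...] = ()
    q_value: float | None = None


@dataclass
class PartitionSummary:
    """Table-1 style accounting of a two-library count table."""

    n_mixed: int
    n_a_only: int
    n_b_only: int
    reads_a: int
    reads_b: int

    @property
    def n_contigs(self) -> int:
        return self.n_mixed + self.n_a_only + self.n_b_only

    @property
    def total_reads(self) -> int:
        return self.reads_a + self.reads_b


def _validate_counts(x: int, y: int, sizes: LibrarySizes) -> None:
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative (got x={x}, y={y})")
    # LibrarySizes validates positivity on construction; re-check for raw tuples.
    if sizes.n_a <= 0 or sizes.n_b <= 0:
        raise ValueError("library sizes must be positive")


def ac_point_probability(x: int, y: int, sizes: LibrarySizes) -> float:
    """Conditional probability of count ``y`` in B given ``x`` in A.

    Under the shared-rate null this equals the Binomial(x + y, q_b) mass at
    ``y``.  Evaluated through the log-space form
    ``y*log(N_B/N_A) + lgamma(x+y+1) - lgamma(x+1) - lgamma(y+1)
    - (x+y)*log(1 + N_B/N_A)``.
    """
    _validate_counts(x, y, sizes)
    if x == 0 and y == 0:
        return 1.0
    log_ratio = math.log(sizes.n_b) - math.log(sizes.n_a)
    log_p = (
        y * log_ratio
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y) * math.log1p(math.exp(log_ratio))
    )
    return float(math.exp(log_p))


def _binom_cdf(y: np.ndarray, t: np.ndarray, q: float) -> np.ndarray:
    """P(Y <= y) for Y ~ Binomial(t, q), via the regularised incomplete beta."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.ones(np.broadcast(y, t).shape)
    lower = y < t
    # I_{1-q}(t - y, y + 1) == sum_{k<=y} C(t,k) q^k (1-q)^(t-k)
    out[lower] = betainc(
        np.broadcast_to(t, out.shape)[lower] - np.broadcast_to(y, out.shape)[lower],
        np.broadcast_to(y, out.shape)[lower] + 1.0,
        1.0 - q,
    )
    return out


def _binom_sf_inclusive(y: np.ndarray, t: np.ndarray, q: float) -> np.ndarray:
    """P(Y >= y) for Y ~ Binomial(t, q)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.ones(np.broadcast(y, t).shape)
    upper = y > 0
    out[upper] = betainc(
        np.broadcast_to(y, out.shape)[upper],
        np.broadcast_to(t, out.shape)[upper]
        - np.broadcast_to(y, out.shape)[upper]
        + 1.0,
        q,
    )
    return out


def pvalues_vectorized(
    x: np.ndarray,
    y: np.ndarray,
    sizes: LibrarySizes,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> np.ndarray:
    """Vectorised exact p-values for arrays of count pairs.

    Same contract as :func:`ac_pvalue`; (x, y) = (0, 0) rows get p = 1.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    t = x + y
    q = sizes.q_b
    lower = _binom_cdf(y, t, q)
    upper = _binom_sf_inclusive(y, t, q)
    smaller = np.minimum(lower, upper)
    if sidedness is Sidedness.ONE_SIDED:
        p = smaller
    else:
        p = np.minimum(1.0, 2.0 * smaller)
    return np.where(t == 0, 1.0, p)


def ac_pvalue(
    x: int,
    y: int,
    sizes: LibrarySizes,
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> float:
    """Exact two-library enrichment p-value for one contig.

    One-sided: the smaller of the two binomial tails P(Y <= y) and
    P(Y >= y), i.e. the tail toward the observed deviation.  Two-sided
    (default): twice the smaller tail, capped at 1.  The doubled min-tail
    p-value is super-uniform under the null, hence valid if conservative.
    """
    _validate_counts(x, y, sizes)
    if isinstance(sidedness, str):
        sidedness = Sidedness(sidedness)
    return float(
        pvalues_vectorized(
            np.array([x]), np.array([y]), sizes, sidedness=sidedness
        )[0]
    )


def fold_enrichment(x: int, y: int, sizes: LibrarySizes) -> float:
    """Normalised fold enrichment max(r_a/r_b, r_b/r_a) with r = count/size.

    Returns ``math.inf`` when exactly one count is zero; raises if both are.
    """
    _validate_counts(x, y, sizes)
    if x == 0 and y == 0:
        raise ValueError("fold enrichment undefined for x = y = 0")
    if x == 0 or y == 0:
        return math.inf
    r_a = x / sizes.n_a
    r_b = y / sizes.n_b
    return max(r_a / r_b, r_b / r_a)


def _partition_of(x: int, y: int) -> Partition:
    if x > 0 and y == 0:
        return Partition.A_ONLY
    if y > 0 and x == 0:
        return Partition.B_ONLY
    return Partition.MIXED


def classify_partition(
    table: Sequence[ContigCountRecord],
) -> tuple[list[Partition], PartitionSummary]:
    """Label every contig mixed / a_only / b_only and summarise the table."""
    if not table:
        raise ValueError("count table is empty")
    seen: set[str] = set()
    labels: list[Partition] = []
    n_mixed = n_a = n_b = 0
    reads_a = reads_b = 0
    for rec in table:
        if rec.contig_id in seen:
            raise ValueError(f"duplicate contig_id {rec.contig_id!r}")
        seen.add(rec.contig_id)
        if rec.x == 0 and rec.y == 0:
            raise ValueError(
                f"contig {rec.contig_id!r} has zero reads in both libraries"
            )
        part = _partition_of(rec.x, rec.y)
        labels.append(part)
        if part is Partition.MIXED:
            n_mixed += 1
        elif part is Partition.A_ONLY:
            n_a += 1
        else:
            n_b += 1
        reads_a += rec.x
        reads_b += rec.y
    return labels, PartitionSummary(
        n_mixed=n_mixed,
        n_a_only=n_a,
        n_b_only=n_b,
        reads_a=reads_a,
        reads_b=reads_b,
    )


def summary_from_class_counts(
    n_mixed: int,
    n_a_only: int,
    n_b_only: int,
    reads_a: int = 0,
    reads_b: int = 0,
) -> PartitionSummary:
    """Build a partition summary directly from per-class counts.

    Used for accounting checks against an externally reported breakdown
    rather than a full count table.
    """
    for name, v in (
        ("n_mixed", n_mixed),
        ("n_a_only", n_a_only),
        ("n_b_only", n_b_only),
        ("reads_a", reads_a),
        ("reads_b", reads_b),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return PartitionSummary(n_mixed, n_a_only, n_b_only, reads_a, reads_b)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_enrichment(
    table: Sequence[ContigCountRecord],
    sizes: LibrarySizes,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentCall]:
    """Run the exact test over a count table and call enrichment.

    Mixed contigs are always tested.  Exclusive contigs (one zero count)
    are labelled but only tested when ``config.include_exclusive`` is set;
    otherwise their p_value is None and they are never called enriched.
    Output order matches input order.
    """
    config = config or EnrichmentConfig()
    if not table:
        return []
    labels, _ = classify_partition(table)

    x = np.array([r.x for r in table], dtype=np.int64)
    y = np.array([r.y for r in table], dtype=np.int64)
    tested = np.array(
        [
            lab is Partition.MIXED or config.include_exclusive
            for lab in labels
        ]
    )
    p = np.full(len(table), np.nan)
    p[tested] = pvalues_vectorized(
        x[tested], y[tested], sizes, sidedness=config.sidedness
    )
    q = np.full(len(table), np.nan)
    if config.fdr and tested.any():
        q[tested] = _bh_adjust(p[tested])
    crit = q if config.fdr else p

    calls: list[EnrichmentCall] = []
    for i, rec in enumerate(table):
        rate_a = rec.x / sizes.n_a
        rate_b = rec.y / sizes.n_b
        if rate_a > rate_b:
            direction = Direction.A
        elif rate_b > rate_a:
            direction = Direction.B
        else:
            direction = Direction.NONE
        fold = fold_enrichment(rec.x, rec.y, sizes)
        p_i = float(p[i]) if tested[i] else None
        enriched = (
            tested[i]
            and direction is not Direction.NONE
            and crit[i] < config.alpha
        )
        calls.append(
            EnrichmentCall(
                contig_id=rec.contig_id,
                partition=labels[i],
                x=rec.x,
                y=rec.y,
                rate_a=rate_a,
                rate_b=rate_b,
                fold=fold,
                p_value=p_i,
                direction=direction,
                enriched=bool(enriched),
                q_value=float(q[i]) if config.fdr and tested[i] else None,
            )
        )
    return calls


def robust_candidates(
    calls: Iterable[EnrichmentCall],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentCall]:
    """Select enriched calls passing the magnitude filter.

    rule=fold keeps fold >= robust_min_fold; rule=reads keeps
    max(x, y) > robust_min_reads; rule=either keeps the union.  Each kept
    call has ``robust_by`` set to the criteria that fired.
    """
    config = config or EnrichmentConfig()
    if not isinstance(config.robust_rule, RobustRule):
        raise ValueError(f"unknown robust rule {config.robust_rule!r}")
    kept: list[EnrichmentCall] = []
    for call in calls:
        if not call.enriched or call.p_value is None:
            continue
        if not config.fdr and call.p_value >= config.alpha:
            continue
        fired: list[str] = []
        if call.fold >= config.robust_min_fold:
            fired.append("fold")
        if max(call.x, call.y) > config.robust_min_reads:
            fired.append("reads")
        rule = config.robust_rule
        ok = (
            ("fold" in fired)
            if rule is RobustRule.FOLD
            else ("reads" in fired)
            if rule is RobustRule.READS
            else bool(fired)
        )
        if ok:
            call.robust = True
            call.robust_by = tuple(fired)
            kept.append(call)
    return kept
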