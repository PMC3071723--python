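"""Synthetic two-library count tables with known ground truth.

Emulates the study design at configurable scale: two libraries of fixed
total read yield distributed over tens of thousands of contigs, an
abundance distribution flattened by normalization, optional
library-exclusive contigs, and a configurable fraction of truly enriched
contigs with known fold effects.  Counts are allocated multinomially per
library so column sums match the configured yields exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .enrichment import (
    Basis,
    ContigCountRecord,
    EnrichmentConfig,
    LibrarySizes,
    Sidedness,
    pvalues_vectorized,
)

__all__ = [
    "AbundanceModel",
    "TrueClass",
    "SimulationConfig",
    "SimulationResult",
    "simulate_study",
    "power_curve",
]


class AbundanceModel(str, enum.Enum):
    FLAT = "flat"
    LOGNORMAL = "lognormal"


class TrueClass(str, enum.Enum):
    NULL = "null"
    ENRICHED_A = "enriched_A"
    ENRICHED_B = "enriched_B"
    EXCLUSIVE_A = "exclusive_A"
    EXCLUSIVE_B = "exclusive_B"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the source study's scale: 45,538 contigs, library
    yields 742,771 (A, female) and 721,543 (B, male).  ``abundance_model``
    "flat" gives equal expected rates (the idealised fully normalized
    library); "lognormal" draws per-contig base rates as 10**(sigma * Z)
    with ``lognormal_sigma`` on the log10 scale (default 0.5, a mildly
    flattened profile).
    """

    n_contigs: int = 45_538
    n_reads_a: int = 742_771
    n_reads_b: int = 721_543
    abundance_model: AbundanceModel = AbundanceModel.FLAT
    lognormal_sigma: float = 0.5
    frac_enriched: float = 0.0
    fold_grid: tuple[float, ...] = (100.0,)
    frac_exclusive: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs <= 0 or self.n_reads_a <= 0 or self.n_reads_b <= 0:
            raise ValueError("n_contigs and library sizes must be positive")
        if not 0.0 <= self.frac_enriched < 1.0:
            raise ValueError("frac_enriched must be in [0, 1)")
        if not 0.0 <= self.frac_exclusive < 1.0:
            raise ValueError("frac_exclusive must be in [0, 1)")
        if self.frac_enriched + self.frac_exclusive >= 1.0:
            raise ValueError("frac_enriched + frac_exclusive must be < 1")
        if self.frac_enriched > 0 and not self.fold_grid:
            raise ValueError("fold_grid must be non-empty when frac_enriched > 0")
        if any(f <= 0 for f in self.fold_grid):
            raise ValueError("true folds must be positive")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass
class SimulationResult:
    table: list[ContigCountRecord]
    sizes: LibrarySizes
    truth: pd.DataFrame  # columns: contig_id, true_class, true_fold
    n_dropped: int  # contigs that received zero reads in both libraries


def _base_rates(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.abundance_model is AbundanceModel.FLAT:
        return np.ones(config.n_contigs)
    z = rng.standard_normal(config.n_contigs)
    return 10.0 ** (config.lognormal_sigma * z)


def simulate_study(config: SimulationConfig) -> SimulationResult:
    """Generate a two-library count table with per-contig ground truth.

    Truly enriched contigs get a rate ratio of ``true_fold`` between the
    libraries (split symmetrically, sqrt(fold) up in one library and down
    in the other, so the average abundance is preserved).  Exclusive
    contigs have one library's rate forced to zero.  Counts are drawn
    multinomially per library; contigs with zero reads in both libraries
    are dropped (they would not appear in an assembly-derived table) and
    counted in ``n_dropped``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_contigs

    n_enriched = int(round(config.frac_enriched * n))
    n_exclusive = int(round(config.frac_exclusive * n))

    classes = np.full(n, TrueClass.NULL.value, dtype=object)
    folds = np.ones(n)

    # deterministic layout: enriched first, then exclusive, alternating sides
    idx = 0
    for k in range(n_enriched):
        classes[idx] = (
            TrueClass.ENRICHED_A.value if k % 2 == 0 else TrueClass.ENRICHED_B.value
        )
        folds[idx] = config.fold_grid[k % len(config.fold_grid)]
        idx += 1
    for k in range(n_exclusive):
        classes[idx] = (
            TrueClass.EXCLUSIVE_A.value if k % 2 == 0 else TrueClass.EXCLUSIVE_B.value
        )
        folds[idx] = np.inf
        idx += 1

    base = _base_rates(config, rng)
    rate_a = base.copy()
    rate_b = base.copy()
    enr_a = classes == TrueClass.ENRICHED_A.value
    enr_b = classes == TrueClass.ENRICHED_B.value
    rate_a[enr_a] *= np.sqrt(folds[enr_a])
    rate_b[enr_a] /= np.sqrt(folds[enr_a])
    rate_b[enr_b] *= np.sqrt(folds[enr_b])
    rate_a[enr_b] /= np.sqrt(folds[enr_b])
    rate_b[classes == TrueClass.EXCLUSIVE_A.value] = 0.0
    rate_a[classes == TrueClass.EXCLUSIVE_B.value] = 0.0

    counts_a = rng.multinomial(config.n_reads_a, rate_a / rate_a.sum())
    counts_b = rng.multinomial(config.n_reads_b, rate_b / rate_b.sum())

    width = len(str(n))
    ids = np.array([f"sim{format(i, f'0{width}d')}" for i in range(n)])
    nonzero = (counts_a + counts_b) > 0

    table = [
        ContigCountRecord(cid, int(a), int(b))
        for cid, a, b in zip(ids[nonzero], counts_a[nonzero], counts_b[nonzero])
    ]
    truth = pd.DataFrame(
        {
            "contig_id": ids[nonzero],
            "true_class": classes[nonzero],
            "true_fold": folds[nonzero],
        }
    )
    sizes = LibrarySizes(
        n_a=int(counts_a[nonzero].sum()),
        n_b=int(counts_b[nonzero].sum()),
        basis=Basis.READS_IN_CONTIGS,
    )
    return SimulationResult(
        table=table,
        sizes=sizes,
        truth=truth,
        n_dropped=int((~nonzero).sum()),
    )


def power_curve(
    config: SimulationConfig,
    alpha_grid: Sequence[float],
    fold_grid: Sequence[float],
    depth_grid: Sequence[float] = (5.0, 20.0),
    frac_enriched: float = 0.02,
) -> pd.DataFrame:
    """Empirical power and false-positive rate over a (fold, depth) grid.

    ``depth_grid`` entries are expected reads per contig per library; each
    cell runs one simulation with ``frac_enriched`` truly enriched contigs
    at a single fold, applies the exact test, and tabulates the fraction of
    truly enriched contigs called (power) and of truly null contigs called
    (FPR), with Wilson 95% intervals.  Output has one row per
    (alpha, fold, depth) combination.
    """
    if not len(alpha_grid) or not len(fold_grid) or not len(depth_grid):
        raise ValueError("alpha_grid, fold_grid and depth_grid must be non-empty")

    rows = []
    for fold in fold_grid:
        for depth in depth_grid:
            n_reads = max(1, int(round(depth * config.n_contigs)))
            cell_cfg = SimulationConfig(
                n_contigs=config.n_contigs,
                n_reads_a=n_reads,
                n_reads_b=n_reads,
                abundance_model=config.abundance_model,
                lognormal_sigma=config.lognormal_sigma,
                frac_enriched=0.0 if fold == 1.0 else frac_enriched,
                fold_grid=(fold,) if fold != 1.0 else (1.0,),
                frac_exclusive=0.0,
                seed=config.seed + hash((round(fold, 6), round(depth, 6))) % 10_000,
            )
            sim = simulate_study(cell_cfg)
            x = np.array([r.x for r in sim.table])
            y = np.array([r.y for r in sim.table])
            # test every emitted contig (exclusive ones included): a truly
            # enriched contig sampled to zero on the depleted side must still
            # count as callable, or power would dip at extreme folds
            p = pvalues_vectorized(x, y, sim.sizes, sidedness=Sidedness.TWO_SIDED)
            is_null = sim.truth["true_class"].to_numpy() == TrueClass.NULL.value
            is_enr = np.isin(
                sim.truth["true_class"].to_numpy(),
                [TrueClass.ENRICHED_A.value, TrueClass.ENRICHED_B.value],
            )
            for alpha in alpha_grid:
                called = p < alpha
                n_null = int(is_null.sum())
                k_null = int((called & is_null).sum())
                n_enr = int(is_enr.sum())
                k_enr = int((called & is_enr).sum())
                fpr = k_null / n_null if n_null else np.nan
                power = k_enr / n_enr if n_enr else fpr
                fpr_lo, fpr_hi = proportion_confint(k_null, n_null, method="wilson")
                if n_enr:
                    pw_lo, pw_hi = proportion_confint(k_enr, n_enr, method="wilson")
                else:
                    pw_lo, pw_hi = fpr_lo, fpr_hi
                rows.append(
                    {
                        "alpha": alpha,
                        "fold": fold,
                        "depth": depth,
                        "n_null": n_null,
                        "n_enriched": n_enr,
                        "power": power,
                        "power_lo": pw_lo,
                        "power_hi": pw_hi,
                        "fpr": fpr,
                        "fpr_lo": fpr_lo,
                        "fpr_hi": fpr_hi,
                    }
                )
    return pd.DataFrame(rows)
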