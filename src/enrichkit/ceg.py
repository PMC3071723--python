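"""Transcriptome-coverage estimation against a core-eukaryotic-gene set.

A reference of highly conserved genes, grouped into conservation
categories, is used as a yardstick: the fraction of reference genes with
at least one homology hit estimates the fraction of the transcriptome
captured by the assembly.  The extrapolation from core-gene coverage to
transcriptome-wide coverage assumes proportional sampling and is labelled
as such in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = ["CegReference", "CoverageReport", "coverage_from_hits", "default_reference"]


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CegReference:
    """Ordered (category name, gene count) pairs plus per-gene membership.

    ``gene_category`` maps gene id -> category name.  When a reference is
    built from category sizes alone, placeholder ids
    ``<category>_g<k>`` are generated so hit tables keyed by placeholder
    ids round-trip.
    """

    categories: tuple[tuple[str, int], ...]
    gene_category: Mapping[str, str]

    def __post_init__(self) -> None:
        sizes = dict(self.categories)
        per_cat: dict[str, int] = {name: 0 for name in sizes}
        for gene, cat in self.gene_category.items():
            if cat not in sizes:
                raise ValueError(f"gene {gene!r} assigned to unknown category {cat!r}")
            per_cat[cat] += 1
        for name, n in sizes.items():
            if per_cat[name] != n:
                raise ValueError(
                    f"category {name!r} declares {n} genes but "
                    f"{per_cat[name]} are mapped"
                )

    @property
    def total_genes(self) -> int:
        return sum(n for _, n in self.categories)

    @classmethod
    def from_category_sizes(cls, sizes: Sequence[tuple[str, int]]) -> "CegReference":
        mapping: dict[str, str] = {}
        for name, n in sizes:
            if n <= 0:
                raise ValueError(f"category {name!r} must have a positive gene count")
            for k in range(1, n + 1):
                mapping[f"{name}_g{k:03d}"] = name
        return cls(categories=tuple(sizes), gene_category=mapping)


def default_reference() -> CegReference:
    """The packaged 248-gene, four-category reference."""
    text = resources.files("enrichkit.data").joinpath("ceg248.yaml").read_text()
    spec = yaml.safe_load(text)
    sizes = [(c["name"], int(c["n_genes"])) for c in spec["categories"]]
    return CegReference.from_category_sizes(sizes)


@dataclass(frozen=True)
class CoverageReport:
    category_sizes: tuple[tuple[str, int], ...]
    category_hits: tuple[tuple[str, int], ...]
    total_hits: int
    total_genes: int
    single_hit_genes: int

    @property
    def coverage_fraction(self) -> float:
        return self.total_hits / self.total_genes

    @property
    def coverage_percent(self) -> float:
        """Full-precision percentage; use :attr:`coverage_percent_display`
        for the nearest-integer rendering."""
        return 100.0 * self.coverage_fraction

    @property
    def coverage_percent_display(self) -> int:
        return _round_half_up(self.coverage_percent)

    @classmethod
    def from_category_hits(
        cls,
        hits: Sequence[int],
        reference: CegReference,
        single_hit_genes: int = 0,
    ) -> "CoverageReport":
        """Build a report from per-category covered-gene counts."""
        if len(hits) != len(reference.categories):
            raise ValueError(
                f"{len(hits)} hit counts for {len(reference.categories)} categories"
            )
        for h, (name, n) in zip(hits, reference.categories):
            if not 0 <= h <= n:
                raise ValueError(
                    f"category {name!r}: hits {h} outside [0, {n}]"
                )
        return cls(
            category_sizes=reference.categories,
            category_hits=tuple(
                (name, int(h)) for (name, _), h in zip(reference.categories, hits)
            ),
            total_hits=int(sum(hits)),
            total_genes=reference.total_genes,
            single_hit_genes=single_hit_genes,
        )


def coverage_from_hits(
    hit_table: Mapping[str, int],
    reference: CegReference | None = None,
) -> CoverageReport:
    """Coverage report from a gene -> hit-count table.

    A gene is covered iff it has >= 1 hit; multiplicity beyond presence
    does not change coverage.  Genes absent from the reference raise.
    """
    reference = reference or default_reference()
    hits_per_cat = {name: 0 for name, _ in reference.categories}
    single = 0
    for gene, n_hits in hit_table.items():
        if gene not in reference.gene_category:
            raise ValueError(f"gene {gene!r} not in the reference")
        if n_hits < 1:
            raise ValueError(f"gene {gene!r}: hit count must be >= 1, got {n_hits}")
        hits_per_cat[reference.gene_category[gene]] += 1
        if n_hits == 1:
            single += 1
    return CoverageReport.from_category_hits(
        [hits_per_cat[name] for name, _ in reference.categories],
        reference,
        single_hit_genes=single,
    )
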