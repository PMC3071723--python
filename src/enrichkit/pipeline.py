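"""End-to-end pipeline: counting summary -> enrichment -> keyword filter
-> optional CEG and qPCR reports, with a JSON provenance record."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import KeywordSet, MatchMode, keyword_select
from .ceg import coverage_from_hits, default_reference
from .enrichment import (
    Basis,
    EnrichmentConfig,
    LibrarySizes,
    RobustRule,
    Sidedness,
    call_enrichment,
    classify_partition,
    robust_candidates,
)
from .io import (
    read_annotation_table,
    read_ceg_hits,
    read_count_table,
    read_ct_table,
    write_calls,
    write_qpcr_report,
    write_summary,
)
from .qpcr import compare_groups, ddct_rq

logger = logging.getLogger("enrichkit")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    counts_path: str
    out_dir: str
    annotations_path: str | None = None
    ceg_hits_path: str | None = None
    ct_path: str | None = None
    ct_calibrator: str | None = None
    n_a: int | None = None  # override library sizes (basis all_reads)
    n_b: int | None = None
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    keywords: KeywordSet = field(default_factory=KeywordSet)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        enr = raw.pop("enrichment", {})
        kw = raw.pop("keywords", {})
        config = cls(
            **raw,
            enrichment=EnrichmentConfig(
                alpha=enr.get("alpha", 0.001),
                sidedness=Sidedness(enr.get("sidedness", "two_sided")),
                robust_min_fold=enr.get("robust_min_fold", 100.0),
                robust_min_reads=enr.get("robust_min_reads", 100),
                robust_rule=RobustRule(enr.get("robust_rule", "either")),
                include_exclusive=enr.get("include_exclusive", False),
                fdr=enr.get("fdr", False),
            ),
            keywords=KeywordSet(
                keywords=tuple(kw.get("keywords", KeywordSet().keywords)),
                match_mode=MatchMode(kw.get("match_mode", "word")),
            ),
        )
        return config

    def to_dict(self) -> dict:
        return {
            "counts_path": self.counts_path,
            "out_dir": self.out_dir,
            "annotations_path": self.annotations_path,
            "ceg_hits_path": self.ceg_hits_path,
            "ct_path": self.ct_path,
            "ct_calibrator": self.ct_calibrator,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "enrichment": {
                "alpha": self.enrichment.alpha,
                "sidedness": self.enrichment.sidedness.value,
                "robust_min_fold": self.enrichment.robust_min_fold,
                "robust_min_reads": self.enrichment.robust_min_reads,
                "robust_rule": self.enrichment.robust_rule.value,
                "include_exclusive": self.enrichment.include_exclusive,
                "fdr": self.enrichment.fdr,
            },
            "keywords": {
                "keywords": list(self.keywords.keywords),
                "match_mode": self.keywords.match_mode.value,
            },
            "seed": self.seed,
            "log_level": self.log_level,
        }


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; returns {artifact name: path}.

    On any stage failure, files written so far are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, str] = {}

    def _emit(name: str, filename: str):
        p = out_dir / filename
        written.append(p)
        outputs[name] = str(p)
        return p

    try:
        # --- counting / partition summary -------------------------------
        try:
            table, sizes_in_contigs = read_count_table(config.counts_path)
            if not table:
                raise ValueError("count table is empty")
        except Exception as exc:
            raise PipelineError("counts", str(exc)) from exc
        if config.n_a is not None and config.n_b is not None:
            sizes = LibrarySizes(config.n_a, config.n_b, basis=Basis.ALL_READS)
        else:
            sizes = sizes_in_contigs
        logger.info(
            "enrichment settings: alpha=%s sidedness=%s basis=%s robust_rule=%s "
            "min_fold=%s min_reads=%s",
            config.enrichment.alpha,
            config.enrichment.sidedness.value,
            sizes.basis.value,
            config.enrichment.robust_rule.value,
            config.enrichment.robust_min_fold,
            config.enrichment.robust_min_reads,
        )

        try:
            _, summary = classify_partition(table)
            calls = call_enrichment(table, sizes, config.enrichment)
            robust = robust_candidates(calls, config.enrichment)
        except Exception as exc:
            raise PipelineError("enrichment", str(exc)) from exc

        from .enrichment import Direction

        n_enr_a = sum(1 for c in calls if c.enriched and c.direction is Direction.A)
        n_enr_b = sum(1 for c in calls if c.enriched and c.direction is Direction.B)
        write_summary(
            summary,
            _emit("summary", "partition_summary.tsv"),
            n_enriched_a=n_enr_a,
            n_enriched_b=n_enr_b,
        )
        write_calls(calls, _emit("calls", "enrichment_calls.tsv"))
        write_calls(robust, _emit("robust", "robust_candidates.tsv"))

        # --- keyword mining ---------------------------------------------
        if config.annotations_path:
            try:
                ann = read_annotation_table(config.annotations_path)
                selected = keyword_select(ann, config.keywords)
            except Exception as exc:
                raise PipelineError("annotation", str(exc)) from exc
            enriched_ids = {c.contig_id for c in calls if c.enriched}
            robust_ids = {c.contig_id for c in robust}
            p = _emit("keyword_candidates", "keyword_candidates.tsv")
            with p.open("w", encoding="utf-8") as fh:
                fh.write(
                    "contig_id\tdescription\tmatched_keywords\tenriched\trobust\n"
                )
                for rec, hits in selected:
                    fh.write(
                        f"{rec.contig_id}\t{rec.description}\t{';'.join(hits)}\t"
                        f"{str(rec.contig_id in enriched_ids).lower()}\t"
                        f"{str(rec.contig_id in robust_ids).lower()}\n"
                    )

        # --- CEG coverage -----------------------------------------------
        if config.ceg_hits_path:
            try:
                hits = read_ceg_hits(config.ceg_hits_path)
                report = coverage_from_hits(hits, default_reference())
            except Exception as exc:
                raise PipelineError("ceg", str(exc)) from exc
            p = _emit("ceg", "ceg_coverage.tsv")
            with p.open("w", encoding="utf-8") as fh:
                fh.write("category\tn_genes\tn_hit\n")
                for (name, n), (_, h) in zip(
                    report.category_sizes, report.category_hits
                ):
                    fh.write(f"{name}\t{n}\t{h}\n")
                fh.write(f"total\t{report.total_genes}\t{report.total_hits}\n")
                fh.write(
                    f"# coverage_percent (core-gene fraction; transcriptome-wide "
                    f"value is an extrapolation): {report.coverage_percent_display}\n"
                )
                fh.write(f"# single_hit_genes: {report.single_hit_genes}\n")

        # --- qPCR -------------------------------------------------------
        if config.ct_path:
            try:
                if not config.ct_calibrator:
                    raise ValueError("ct_calibrator required with ct_path")
                cts = read_ct_table(config.ct_path)
                rqs = ddct_rq(cts, calibrator=config.ct_calibrator)
                comparisons = compare_groups(rqs)
            except Exception as exc:
                raise PipelineError("qpcr", str(exc)) from exc
            write_qpcr_report(
                rqs,
                comparisons,
                _emit("qpcr_rq", "qpcr_relative_quantities.tsv"),
                _emit("qpcr_comparisons", "qpcr_group_comparisons.tsv"),
            )

        # --- provenance -------------------------------------------------
        prov = {
            "package": "enrichkit",
            "version": __version__,
            "config": config.to_dict(),
            "library_sizes": {
                "n_a": sizes.n_a,
                "n_b": sizes.n_b,
                "basis": sizes.basis.value,
            },
            "outputs": {k: str(Path(v).name) for k, v in outputs.items()},
        }
        p = _emit("provenance", "provenance.json")
        p.write_text(json.dumps(prov, indent=2) + "\n", encoding="utf-8")
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return outputs
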