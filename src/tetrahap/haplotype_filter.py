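"""Microhaplotype-, sample- and locus-level retention rules.

The filter pipeline mirrors the order in which DArTag microhaplotype data
are cleaned before dosage calling:

1. microhaplotype retention — RefMatch/AltMatch haplotypes are kept only
   if (a) at least ``min_samples_hap`` samples show at least
   ``min_reads_hap`` reads for them and (b) they align to their locus's
   reference microhaplotype with identity and coverage strictly above
   ``min_identity``/``min_coverage``;
2. sample exclusion — samples missing (zero reads) at >=
   ``max_sample_missing`` of loci are dropped;
3. locus retention — a locus is kept iff >= ``min_samples_locus`` samples
   carry >= ``min_reads_locus`` total reads for it;
4. paralog collapse — retained loci that still carry >=
   ``max_haps_per_locus`` microhaplotypes are reduced to their Ref and
   Alt records (excess off-target haplotypes at one amplicon usually mean
   paralogous amplification).

Strictness follows the rules as printed: identity/coverage thresholds are
strict (``>``), the sample/read/missing thresholds are inclusive (``>=``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from tetrahap.madc_io import HaplotypeRecord, MADCTable


@dataclass
class FilterConfig:
    min_samples_hap: int = 10
    min_reads_hap: int = 2
    min_identity: float = 0.90
    min_coverage: float = 0.90
    max_sample_missing: float = 0.95
    min_samples_locus: int = 10
    min_reads_locus: int = 10
    max_haps_per_locus: int = 10

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "max_sample_missing"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "min_samples_hap",
            "min_reads_hap",
            "min_samples_locus",
            "min_reads_locus",
            "max_haps_per_locus",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FilterReport:
    """Per-rule removal counters; reconciles exactly with table sizes."""

    haps_in: int = 0
    haps_removed_support: int = 0
    haps_removed_alignment: int = 0
    haps_removed_collapse: int = 0
    haps_removed_locus_drop: int = 0
    samples_in: int = 0
    samples_removed_missing: int = 0
    loci_in: int = 0
    loci_removed_depth: int = 0
    loci_collapsed: int = 0

    @property
    def haps_retained(self) -> int:
        return (
            self.haps_in
            - self.haps_removed_support
            - self.haps_removed_alignment
            - self.haps_removed_collapse
            - self.haps_removed_locus_drop
        )

    @property
    def loci_retained(self) -> int:
        return self.loci_in - self.loci_removed_depth

    @property
    def samples_retained(self) -> int:
        return self.samples_in - self.samples_removed_missing

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport()
        for f in out.__dataclass_fields__:
            setattr(out, f, getattr(self, f) + getattr(other, f))
        return out

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [(k, getattr(self, k)) for k in self.__dataclass_fields__]
        rows += [
            ("haps_retained", self.haps_retained),
            ("samples_retained", self.samples_retained),
            ("loci_retained", self.loci_retained),
        ]
        pd.DataFrame(rows, columns=["counter", "value"]).to_csv(
            path, sep="\t", index=False
        )


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
# mild linear gap penalty: gaps only open when they buy matches
_aligner.open_gap_score = -0.5
_aligner.extend_gap_score = -0.5


def alignment_identity(query: str, reference: str) -> tuple[float, float]:
    """Global-alignment identity and coverage of ``query`` against
    ``reference``.

    identity = matches / columns where both sequences contribute a base;
    coverage = reference positions aligned to query bases / len(reference).
    """
    if not query or not reference:
        raise ValueError("empty sequence")
    aln = _aligner.align(query, reference)[0]
    matches = 0
    aligned_cols = 0
    covered_ref = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        span = qe - qs
        aligned_cols += span
        covered_ref += re_ - rs
        matches += sum(
            1 for a, b in zip(query[qs:qe], reference[rs:re_]) if a == b
        )
    if aligned_cols == 0:
        return 0.0, 0.0
    return matches / aligned_cols, covered_ref / len(reference)


def filter_haplotypes(
    table: MADCTable, cfg: FilterConfig | None = None
) -> tuple[MADCTable, FilterReport]:
    """Apply the RefMatch/AltMatch retention rules; Ref and Alt records
    are always kept."""
    cfg = cfg or FilterConfig()
    report = FilterReport(haps_in=len(table.records))
    by_locus = table.locus_index()
    ref_seq: dict[str, str] = {}
    for locus, recs in by_locus.items():
        refs = [r for r in recs if r.hap_class == "Ref"]
        if not refs:
            raise ValueError(f"locus {locus} has no Ref record")
        ref_seq[locus] = refs[0].sequence

    kept: list[HaplotypeRecord] = []
    for rec in table.records:
        if rec.hap_class in ("Ref", "Alt"):
            kept.append(rec)
            continue
        support = int(np.sum(rec.counts >= cfg.min_reads_hap))
        if support < cfg.min_samples_hap:
            report.haps_removed_support += 1
            continue
        ident, cov = alignment_identity(rec.sequence, ref_seq[rec.locus_id])
        if not (ident > cfg.min_identity and cov > cfg.min_coverage):
            report.haps_removed_alignment += 1
            continue
        kept.append(rec)
    return MADCTable(table.sample_ids, kept, table.n_missing_cells), report


def filter_samples(
    table: MADCTable, cfg: FilterConfig | None = None
) -> tuple[MADCTable, FilterReport]:
    """Drop samples with >= ``max_sample_missing`` fraction of loci at
    zero total read depth."""
    cfg = cfg or FilterConfig()
    report = FilterReport(samples_in=len(table.sample_ids))
    depth = table.locus_depth()
    missing_frac = (depth.to_numpy() == 0).mean(axis=0)
    keep = [
        s
        for s, frac in zip(table.sample_ids, missing_frac)
        if frac < cfg.max_sample_missing
    ]
    report.samples_removed_missing = len(table.sample_ids) - len(keep)
    if not keep:
        raise ValueError("all samples excluded by the missing-data rule")
    return table.subset_samples(keep), report


def filter_loci(
    table: MADCTable, cfg: FilterConfig | None = None
) -> tuple[MADCTable, FilterReport]:
    """Apply the locus depth rule, then collapse >= ``max_haps_per_locus``
    loci to Ref and Alt."""
    cfg = cfg or FilterConfig()
    report = FilterReport(loci_in=len(table.locus_ids))
    depth = table.locus_depth()
    covered = (depth.to_numpy() >= cfg.min_reads_locus).sum(axis=1)
    keep_locus = {
        locus
        for locus, n in zip(depth.index, covered)
        if n >= cfg.min_samples_locus
    }
    report.loci_removed_depth = len(depth.index) - len(keep_locus)

    kept: list[HaplotypeRecord] = []
    by_locus = table.locus_index()
    for locus, recs in by_locus.items():
        if locus not in keep_locus:
            report.haps_removed_locus_drop += len(recs)
            continue
        if len(recs) >= cfg.max_haps_per_locus:
            core = [r for r in recs if r.hap_class in ("Ref", "Alt")]
            report.haps_removed_collapse += len(recs) - len(core)
            report.loci_collapsed += 1
            kept.extend(core)
        else:
            kept.extend(recs)
    return MADCTable(table.sample_ids, kept, table.n_missing_cells), report


def apply_filters(
    table: MADCTable, cfg: FilterConfig | None = None
) -> tuple[MADCTable, FilterReport]:
    """Full pipeline: haplotype rules -> sample exclusion -> locus rules."""
    cfg = cfg or FilterConfig()
    t1, r1 = filter_haplotypes(table, cfg)
    t2, r2 = filter_samples(t1, cfg)
    t3, r3 = filter_loci(t2, cfg)
    return t3, r1.merge(r2).merge(r3)
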