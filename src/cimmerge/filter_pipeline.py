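"""Replicate merging, threshold filtering, ranking and pooling of peptide IDs.

This is the heart of the workflow.  For each trendline's folder of replicate
peptide-ID lists the stages run in a fixed order:

1. merge replicates on the identity key (protein, sequence, modification),
   computing a replicate count and the retention-time relative standard
   deviation (RT-RSD) across replicates;
2. filter on replicate count and RT-RSD;
3. average the remaining metrics across replicates and filter on them
   (products per amino acid, intensity, length window, matched products,
   consecutive products, summed product intensity, search-engine score,
   absolute ppm mass error — all comparisons inclusive);
4. rank by search-engine (PLGS) score and keep the top-scoring record per
   identity key.

On top of the per-trendline pipeline sit three pooling modes: best-trendline
selection (report unique counts per trendline, keep the winner), multi-sequence
merging (pool single-pass and best-multipass lists), and multi-trendline
merging (pool every trendline's filtered list).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as _dc_fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .peptide_io import PeptideID

__all__ = [
    "FilterThresholds",
    "MergedPeptide",
    "TrendlineReport",
    "rt_rsd",
    "merge_replicates",
    "apply_replicate_and_rsd_filters",
    "apply_metric_filters",
    "failed_rules",
    "rank_and_dedup",
    "run_tag_pipeline",
    "identify_best_trendline",
    "merge_multisequence",
    "merge_multitrendline",
]

log = logging.getLogger(__name__)

Key = tuple[str, str, str]


@dataclass(frozen=True)
class FilterThresholds:
    """Threshold set applied to merged peptide records.

    All comparisons downstream are inclusive; the ppm mass error is
    compared on its absolute value.  The shipped defaults are editable
    working values typical of HDX peptide-map curation practice — tune them
    per instrument and target via a YAML profile (:meth:`from_file`).
    """

    min_replicates: int = 2
    max_rt_rsd: float = 5.0          # percent
    min_products_per_aa: float = 0.2
    min_intensity: float = 5000.0
    min_length: int = 5
    max_length: int = 40
    min_matched_products: int = 3
    min_consecutive_products: int = 2
    min_sum_product_intensity: float = 1000.0
    min_plgs_score: float = 6.5
    max_abs_ppm_error: float = 10.0

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError(
                f"min_length {self.min_length} > max_length {self.max_length}"
            )
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")

    @classmethod
    def no_op(cls) -> "FilterThresholds":
        """Thresholds that pass everything (useful to isolate one rule)."""
        return cls(
            min_replicates=1,
            max_rt_rsd=math.inf,
            min_products_per_aa=0.0,
            min_intensity=0.0,
            min_length=1,
            max_length=10**9,
            min_matched_products=0,
            min_consecutive_products=0,
            min_sum_product_intensity=0.0,
            min_plgs_score=0.0,
            max_abs_ppm_error=math.inf,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "FilterThresholds":
        """Load thresholds from a flat key/value YAML profile.

        Keys mirror the field names; missing keys keep their defaults and
        unknown keys raise.
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown threshold key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {f.name: getattr(self, f.name) for f in _dc_fields(self)}
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


@dataclass(frozen=True)
class MergedPeptide:
    """A per-identity-key record after replicate merging and averaging.

    Numeric metrics are arithmetic means over the representing instances
    (one per replicate — the highest-scoring instance when a replicate
    holds the key more than once).  ``mh_ppm_error`` is the mean of the
    absolute ppm errors.  ``source_tags`` records which trendline folders
    contributed; pooling unions it.
    """

    protein_id: str
    sequence: str
    modification: str
    start: int
    end: int
    replicate_count: int
    rt_mean: float
    rt_rsd: float  # percent
    plgs_score: float
    intensity: float
    products_per_aa: float
    matched_products: float
    consecutive_products: float
    sum_product_intensity: float
    mh_ppm_error: float  # mean absolute error
    source_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.rt_rsd < 0:
            raise ValueError("rt_rsd must be >= 0")
        if not self.source_tags:
            raise ValueError("source_tags must be non-empty")

    @property
    def key(self) -> Key:
        return (self.protein_id, self.sequence, self.modification)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrendlineReport:
    """Unique-peptide counts per trendline tag and the selected best tag."""

    counts: dict[str, int]
    best_tag: str
    best_list: tuple[MergedPeptide, ...]

    def __post_init__(self) -> None:
        if self.counts and self.counts[self.best_tag] != max(self.counts.values()):
            raise ValueError("best_tag must have the maximal count")


def rt_rsd(rts: Sequence[float]) -> float:
    """Retention-time relative standard deviation, in percent.

    Sample (n-1) standard deviation over mean x 100.  A single value gives
    0 by convention — the replicate-count threshold, not RT-RSD, governs
    singletons.  Non-positive RTs are rejected.
    """
    if not rts:
        raise ValueError("rt_rsd needs at least one value")
    if any(r <= 0 or not math.isfinite(r) for r in rts):
        raise ValueError(f"retention times must be finite and > 0: {list(rts)!r}")
    if len(rts) == 1:
        return 0.0
    mean = sum(rts) / len(rts)
    var = sum((r - mean) ** 2 for r in rts) / (len(rts) - 1)
    return 100.0 * math.sqrt(var) / mean


def merge_replicates(tables: Sequence[Sequence[PeptideID]]) -> list[MergedPeptide]:
    """Merge replicate peptide-ID lists from one trendline folder.

    Records are grouped on the identity key.  Within a replicate the
    highest-scoring instance represents the key; the replicate count is the
    number of distinct replicates holding the key, and RT-RSD is computed
    over one retention time per replicate.  All numeric metrics are
    arithmetic means over the representing instances; coordinates come from
    the top-scoring representative.

    All input records must share one trendline tag (they come from one
    folder); mixed tags raise ``ValueError``.  Empty input yields an empty
    list.  Output order follows first appearance of each key.
    """
    records = [r for table in tables for r in table]
    if not records:
        return []
    tags = {r.trendline_tag for r in records}
    if len(tags) > 1:
        raise ValueError(
            f"merge_replicates expects a single trendline tag, got {sorted(tags)}"
        )
    tag = tags.pop()

    # key -> replicate_id -> best instance within that replicate
    groups: dict[Key, dict[str, PeptideID]] = {}
    order: list[Key] = []
    for rec in records:
        reps = groups.get(rec.key)
        if reps is None:
            groups[rec.key] = reps = {}
            order.append(rec.key)
        best = reps.get(rec.replicate_id)
        if best is None or rec.plgs_score > best.plgs_score:
            reps[rec.replicate_id] = rec

    merged: list[MergedPeptide] = []
    for key in order:
        reps = groups[key]
        instances = list(reps.values())
        top = max(instances, key=lambda r: r.plgs_score)
        n = len(instances)
        rts = [r.rt for r in instances]
        merged.append(
            MergedPeptide(
                protein_id=top.protein_id,
                sequence=top.sequence,
                modification=top.modification,
                start=top.start,
                end=top.end,
                replicate_count=n,
                rt_mean=sum(rts) / n,
                rt_rsd=rt_rsd(rts),
                plgs_score=sum(r.plgs_score for r in instances) / n,
                intensity=sum(r.intensity for r in instances) / n,
                products_per_aa=sum(r.products_per_aa for r in instances) / n,
                matched_products=sum(r.matched_products for r in instances) / n,
                consecutive_products=sum(r.consecutive_products for r in instances) / n,
                sum_product_intensity=sum(r.sum_product_intensity for r in instances) / n,
                mh_ppm_error=sum(abs(r.mh_ppm_error) for r in instances) / n,
                source_tags=frozenset({tag}),
            )
        )
    return merged


def apply_replicate_and_rsd_filters(
    merged: Sequence[MergedPeptide], th: FilterThresholds
) -> list[MergedPeptide]:
    """Keep records seen in enough replicates with stable retention times."""
    out = [
        m
        for m in merged
        if m.replicate_count >= th.min_replicates and m.rt_rsd <= th.max_rt_rsd
    ]
    log.info(
        "replicate/RT-RSD filter: %d in, %d removed, %d out",
        len(merged), len(merged) - len(out), len(out),
    )
    return out


# rule name -> predicate(record, thresholds) -> passes?
_METRIC_RULES = {
    "min_products_per_aa": lambda m, t: m.products_per_aa >= t.min_products_per_aa,
    "min_intensity": lambda m, t: m.intensity >= t.min_intensity,
    "min_length": lambda m, t: m.length >= t.min_length,
    "max_length": lambda m, t: m.length <= t.max_length,
    "min_matched_products": lambda m, t: m.matched_products >= t.min_matched_products,
    "min_consecutive_products": lambda m, t: m.consecutive_products
    >= t.min_consecutive_products,
    "min_sum_product_intensity": lambda m, t: m.sum_product_intensity
    >= t.min_sum_product_intensity,
    "min_plgs_score": lambda m, t: m.plgs_score >= t.min_plgs_score,
    "max_abs_ppm_error": lambda m, t: abs(m.mh_ppm_error) <= t.max_abs_ppm_error,
}


def failed_rules(m: MergedPeptide, th: FilterThresholds) -> list[str]:
    """Names of the metric rules a record fails (empty list = passes all)."""
    return [name for name, rule in _METRIC_RULES.items() if not rule(m, th)]


def apply_metric_filters(
    merged: Sequence[MergedPeptide], th: FilterThresholds
) -> list[MergedPeptide]:
    """Apply the averaged-metric thresholds; order preserved.

    Removal reasons per record are logged at DEBUG level.
    """
    out: list[MergedPeptide] = []
    removed = 0
    for m in merged:
        bad = failed_rules(m, th)
        if bad:
            removed += 1
            log.debug(
                "removed %s/%s [%d-%d]: failed %s",
                m.protein_id, m.sequence, m.start, m.end, ", ".join(bad),
            )
        else:
            out.append(m)
    log.info(
        "metric filter: %d in, %d removed, %d out", len(merged), removed, len(out)
    )
    return out


def _rank_key(m: MergedPeptide):
    # descending score, then descending summed product intensity, then
    # ascending |ppm error|, then lexicographic identity key
    return (-m.plgs_score, -m.sum_product_intensity, abs(m.mh_ppm_error), m.key)


def rank_and_dedup(merged: Sequence[MergedPeptide]) -> list[MergedPeptide]:
    """Rank by PLGS score (descending) and keep one record per identity key.

    Ties break on higher summed product intensity, then smaller absolute
    ppm error, then the lexicographic identity key, so the result is
    deterministic and independent of input order.  The surviving record's
    ``source_tags`` is the union over all duplicates of the key.
    """
    tag_union: dict[Key, frozenset[str]] = {}
    for m in merged:
        tag_union[m.key] = tag_union.get(m.key, frozenset()) | m.source_tags
    seen: set[Key] = set()
    out: list[MergedPeptide] = []
    for m in sorted(merged, key=_rank_key):
        if m.key in seen:
            continue
        seen.add(m.key)
        out.append(replace(m, source_tags=tag_union[m.key]))
    return out


def run_tag_pipeline(
    tables: Sequence[Sequence[PeptideID]], th: FilterThresholds
) -> list[MergedPeptide]:
    """Full per-trendline pipeline: merge -> replicate/RSD -> metrics -> dedup."""
    merged = merge_replicates(tables)
    merged = apply_replicate_and_rsd_filters(merged, th)
    merged = apply_metric_filters(merged, th)
    return rank_and_dedup(merged)


def _tag_sort_key(tag: str):
    # smaller fwhm_start wins ties (least smoothing); fall back to the string
    head = tag.split("_", 1)[0]
    try:
        return (float(head), tag)
    except ValueError:
        return (math.inf, tag)


def identify_best_trendline(
    per_tag_tables: Mapping[str, Sequence[Sequence[PeptideID]]],
    th: FilterThresholds,
) -> TrendlineReport:
    """Run the pipeline per trendline and pick the best-performing one.

    The best tag is the one with the most unique peptides after filtering;
    ties go to the smaller ``fwhm_start`` (the least-smoothing trendline).
    The winner's final list rides along in the report.
    """
    if not per_tag_tables:
        raise ValueError("identify_best_trendline needs at least one tag")
    finals = {
        tag: run_tag_pipeline(tables, th)
        for tag, tables in per_tag_tables.items()
    }
    counts = {tag: len(final) for tag, final in finals.items()}
    # deterministic selection: max count, ties to smallest fwhm_start
    top = max(counts.values())
    candidates = sorted(
        (t for t, c in counts.items() if c == top), key=_tag_sort_key
    )
    best = candidates[0]
    log.info("per-trendline unique counts: %s; best: %s", counts, best)
    return TrendlineReport(counts=counts, best_tag=best, best_list=tuple(finals[best]))


def merge_multisequence(
    single_pass_final: Sequence[MergedPeptide],
    multipass_final: Sequence[MergedPeptide],
    th: FilterThresholds,
) -> list[MergedPeptide]:
    """Pool single-pass and multipass lists into one final peptide list.

    Both inputs must already be replicate-merged and replicate/RSD-filtered;
    the pooled list passes through the metric filters and score-ranked
    deduplication.  The unique-key set of the result equals the union of
    the two inputs' metric-filtered unique-key sets.
    """
    pooled = list(single_pass_final) + list(multipass_final)
    return rank_and_dedup(apply_metric_filters(pooled, th))


def merge_multitrendline(
    all_tag_tables: Mapping[str, Sequence[Sequence[PeptideID]]],
    th: FilterThresholds,
) -> list[MergedPeptide]:
    """Pool every trendline's replicate-merged, filtered list and dedup.

    ``all_tag_tables`` should be the full processing output: the
    single-pass folder (``"1_1"``) plus every multipass trendline folder.
    Each tag is replicate-merged and replicate/RSD-filtered separately,
    then everything is pooled, metric-filtered and deduplicated.  The
    resulting unique-key set is exactly the union over tags of each tag's
    filtered unique-key set.
    """
    if not all_tag_tables:
        raise ValueError("merge_multitrendline needs at least one tag")
    pooled: list[MergedPeptide] = []
    for tag in sorted(all_tag_tables, key=_tag_sort_key):
        merged = merge_replicates(all_tag_tables[tag])
        pooled.extend(apply_replicate_and_rsd_filters(merged, th))
    return rank_and_dedup(apply_metric_filters(pooled, th))
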