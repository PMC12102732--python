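"""Synthetic peptide-mapping data with trendline-dependent detection.

This module stands in for the vendor peak-detection/search engine.  It
generates ground-truth peptides from a protein sequence by pseudo-protease
digestion, then emits per-trendline, per-replicate peptide-ID tables in the
exact folder layout the pipeline consumes.

The physics being emulated: in a multipass cyclic ion-mobility separation,
ions lap the cyclic cell and their arrival times wrap around the fixed
200-bin acquisition window, destroying the linear relationship between
drift time (DT) and ion-mobility peak width (FWHM).  Peak detection smooths
each DT bin with a width given by a linear DT-vs-FWHM trendline, so any one
trendline matches only part of the wrapped width distribution.  We model
this with a mixture of FWHM populations (wrapped and unwrapped components)
and a Gaussian detection kernel: a peptide is detected under a trendline
with probability

    p = p_max * exp(-(fwhm_trendline(dt) - fwhm_true)^2 / (2 sigma^2))

so detection decays as the trendline's smoothing width misses the peptide's
true peak width.  Single-pass data keeps the linear DT-FWHM relationship
(no wrap-around) and is processed with an auto-fitted trendline, but at a
lower detection ceiling, emulating the co-elution losses that motivate
multipass separation in the first place.

Planted false positives ("decoys") each violate exactly one filter rule by
a wide deterministic margin, so filter efficacy can be audited per rule,
and pipeline output can be scored for precision/recall against the ground
truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peptide_io import PeptideID, ProteinRecord, write_peptide_table
from .filter_pipeline import FilterThresholds, MergedPeptide
from .trendline import (
    SINGLE_PASS_TAG,
    ProcessingPlan,
    Trendline,
    build_processing_plan,
    fit_auto_trendline,
    fwhm_at,
)

__all__ = [
    "TruePeptide",
    "Decoy",
    "SimulationGroundTruth",
    "DetectionModel",
    "random_protein",
    "digest_in_silico",
    "wrap_dt",
    "make_decoys",
    "build_ground_truth",
    "simulate_tables",
    "write_simulation",
    "score_against_truth",
    "detected_true_keys",
    "default_simulation",
    "trendline_response",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(length: int, seed: int, protein_id: str = "SIMPROT") -> ProteinRecord:
    """A random target protein sequence over the 20 standard residues."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
    return ProteinRecord(protein_id, seq)


@dataclass(frozen=True)
class TruePeptide:
    """One planted true peptide with its ion-mobility ground truth.

    ``dt_bin``/``true_fwhm`` describe the wrapped multipass observation;
    ``sp_dt_bin``/``sp_fwhm`` the unwrapped single-pass one.  ``component``
    indexes the FWHM mixture component the peptide belongs to.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    base_rt: float
    dt_bin: float
    true_fwhm: float
    sp_dt_bin: float
    sp_fwhm: float
    base_plgs_score: float
    base_intensity: float
    products_per_aa: float
    matched_products: int
    consecutive_products: int
    base_sum_product_intensity: float
    component: int

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protein_id, self.sequence, "")


@dataclass(frozen=True)
class Decoy:
    """A planted false positive engineered to fail one named filter rule.

    All other attributes sit comfortably inside the thresholds, so the
    decoy survives iff its designated rule is disabled.  The replicate-count
    decoy appears in the first replicate only; the RT-RSD decoy carries
    deterministic per-replicate retention-time offsets.
    """

    rule: str
    protein_id: str
    sequence: str
    start: int
    end: int
    base_rt: float
    dt_bin: float
    plgs_score: float
    intensity: float
    products_per_aa: float
    matched_products: int
    consecutive_products: int
    sum_product_intensity: float
    mh_ppm_error: float
    rt_offsets: tuple[float, ...] = (0.0,)
    first_replicate_only: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.protein_id, self.sequence, "")


@dataclass(frozen=True)
class SimulationGroundTruth:
    """Planted truth for one simulated mapping experiment."""

    protein: ProteinRecord
    true_peptides: tuple[TruePeptide, ...]
    false_positives: tuple[Decoy, ...]
    rng_seed: int

    def true_keys(self) -> set[tuple[str, str, str]]:
        return {p.key for p in self.true_peptides}

    def decoy_keys(self) -> set[tuple[str, str, str]]:
        return {d.key for d in self.false_positives}


@dataclass(frozen=True)
class DetectionModel:
    """Parameters of the trendline-dependent detection process.

    The FWHM mixture (``mixture_means``/``sds``/``weights``) emulates
    wrapped vs unwrapped ion populations in multipass data; ``width_sigma``
    is the tolerance of the Gaussian detection kernel (DT bins).  The
    single-pass population follows the linear law
    ``fwhm = sp_intercept + sp_slope * dt`` with ``sp_fwhm_sd`` scatter and
    detection ceiling ``sp_p_max``.
    """

    p_max: float = 0.95
    width_sigma: float = 3.0
    mixture_means: tuple[float, ...] = (8.0, 20.0)
    mixture_sds: tuple[float, ...] = (1.0, 1.0)
    mixture_weights: tuple[float, ...] = (0.5, 0.5)
    rt_jitter_sd: float = 0.02     # minutes
    score_jitter_sd: float = 0.3
    ppm_sd: float = 2.0
    intensity_jitter: float = 0.1  # lognormal sigma
    sp_p_max: float = 0.7
    sp_intercept: float = 4.0
    sp_slope: float = 0.01
    sp_fwhm_sd: float = 0.3
    n_passes: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_max <= 1.0 and 0.0 <= self.sp_p_max <= 1.0):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be > 0")
        if not (
            len(self.mixture_means)
            == len(self.mixture_sds)
            == len(self.mixture_weights)
            >= 1
        ):
            raise ValueError("mixture component lists must have equal length >= 1")
        if any(s <= 0 for s in self.mixture_sds):
            raise ValueError("mixture SDs must be > 0")


def wrap_dt(periodic_dt: float, n_passes: int, window: float = 200.0) -> float:
    """Observed drift-time bin after multipass wrap-around.

    An ion with per-pass drift time ``periodic_dt`` arriving after
    ``n_passes`` traversals is recorded at ``(periodic_dt * n_passes) mod
    window`` — faster ions lap slower ones inside the fixed window.
    """
    if periodic_dt <= 0:
        raise ValueError("periodic_dt must be > 0")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    return (periodic_dt * n_passes) % window


def digest_in_silico(
    protein: ProteinRecord,
    length_range: tuple[int, int] = (5, 25),
    density: float = 1.0,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Pseudo-protease digestion: random overlapping fragments.

    Nonspecific acid proteases (pepsin-like) cut promiscuously, so the
    peptide population is modeled as ``round(density * protein_length)``
    fragments with uniform random start positions and lengths drawn
    uniformly from ``length_range``, deduplicated on coordinates.  Returns
    ``(sequence, start, end)`` triples, reproducible for a seed.
    """
    lo, hi = length_range
    if not (4 <= lo <= hi <= 60):
        raise ValueError(f"length_range must satisfy 4 <= lo <= hi <= 60, got {length_range}")
    if protein.length < lo:
        raise ValueError(
            f"protein {protein.protein_id!r} (length {protein.length}) is "
            f"shorter than the minimum peptide length {lo}"
        )
    rng = np.random.default_rng(seed)
    n_target = max(1, round(density * protein.length))
    seen: set[tuple[int, int]] = set()
    out: list[tuple[str, int, int]] = []
    # oversample to compensate for coordinate collisions
    for _ in range(4 * n_target):
        if len(out) >= n_target:
            break
        length = int(rng.integers(lo, min(hi, protein.length) + 1))
        start = int(rng.integers(1, protein.length - length + 2))
        end = start + length - 1
        if (start, end) in seen:
            continue
        seen.add((start, end))
        out.append((protein.sequence[start - 1 : end], start, end))
    return out


def _decoy_sequence(rng: np.random.Generator, protein: ProteinRecord, length: int) -> str:
    """A random sequence of the given length absent from the protein."""
    for _ in range(1000):
        seq = "".join(rng.choice(list(_AMINO_ACIDS), size=length))
        if seq not in protein.sequence:
            return seq
    raise RuntimeError("could not draw a decoy sequence absent from the protein")


def make_decoys(
    protein: ProteinRecord, th: FilterThresholds, seed: int
) -> list[Decoy]:
    """One decoy per filter rule, each violating its rule by a wide margin.

    Rules whose threshold sits at a no-op extreme (so no violating value
    exists) are skipped.
    """
    rng = np.random.default_rng(seed)
    good_len = max(th.min_length, min(10, th.max_length))

    def base(rule: str, length: int, **overrides) -> Decoy:
        seq = _decoy_sequence(rng, protein, length)
        start = int(rng.integers(1, max(2, protein.length - length + 1)))
        fields = dict(
            rule=rule,
            protein_id=protein.protein_id,
            sequence=seq,
            start=start,
            end=start + length - 1,
            base_rt=10.0,
            dt_bin=float(rng.uniform(10, 190)),
            plgs_score=max(th.min_plgs_score, 7.0) + 1.0,
            intensity=max(th.min_intensity, 5000.0) * 4,
            products_per_aa=max(th.min_products_per_aa, 0.2) * 4,
            matched_products=max(th.min_matched_products, 3) + 5,
            consecutive_products=max(th.min_consecutive_products, 2) + 3,
            sum_product_intensity=max(th.min_sum_product_intensity, 1000.0) * 4,
            mh_ppm_error=1.0,
        )
        fields.update(overrides)
        return Decoy(**fields)

    decoys: list[Decoy] = []
    if th.min_replicates > 1:
        decoys.append(base("min_replicates", good_len, first_replicate_only=True))
    if math.isfinite(th.max_rt_rsd):
        # offsets give an RT-RSD of ~15% around a 10-minute base, far above
        # any practical threshold
        decoys.append(
            base("max_rt_rsd", good_len, rt_offsets=(-1.5, 1.5, 0.0))
        )
    if th.min_products_per_aa > 0:
        decoys.append(
            base("min_products_per_aa", good_len,
                 products_per_aa=th.min_products_per_aa * 0.05)
        )
    if th.min_intensity > 0:
        decoys.append(base("min_intensity", good_len, intensity=th.min_intensity * 0.1))
    if th.min_length > 4:
        decoys.append(base("min_length", th.min_length - 1))
    if th.max_length < 60:
        decoys.append(base("max_length", th.max_length + 1))
    if th.min_matched_products > 0:
        decoys.append(base("min_matched_products", good_len, matched_products=0))
    if th.min_consecutive_products > 0:
        decoys.append(base("min_consecutive_products", good_len, consecutive_products=0))
    if th.min_sum_product_intensity > 0:
        decoys.append(
            base("min_sum_product_intensity", good_len,
                 sum_product_intensity=th.min_sum_product_intensity * 0.1)
        )
    if th.min_plgs_score > 0:
        decoys.append(base("min_plgs_score", good_len, plgs_score=th.min_plgs_score * 0.3))
    if math.isfinite(th.max_abs_ppm_error):
        decoys.append(
            base("max_abs_ppm_error", good_len, mh_ppm_error=th.max_abs_ppm_error * 2.5)
        )
    return decoys


def build_ground_truth(
    protein: ProteinRecord,
    model: DetectionModel,
    seed: int,
    length_range: tuple[int, int] = (5, 25),
    density: float = 0.5,
    thresholds: FilterThresholds | None = None,
) -> SimulationGroundTruth:
    """Plant true peptides (with ion-mobility attributes) and decoys.

    True peptides carry base metrics that pass the default thresholds in
    expectation; their multipass FWHM is drawn from the model's mixture
    (independently of drift time — the wrap-around signature) while the
    single-pass FWHM follows the model's linear law.
    """
    th = thresholds or FilterThresholds()
    rng = np.random.default_rng(seed)
    fragments = digest_in_silico(protein, length_range, density, seed=int(rng.integers(2**31)))
    k = len(model.mixture_means)
    weights = np.asarray(model.mixture_weights, dtype=float)
    weights = weights / weights.sum()

    peptides: list[TruePeptide] = []
    for seq, start, end in fragments:
        comp = int(rng.choice(k, p=weights))
        true_fwhm = float(
            rng.normal(model.mixture_means[comp], model.mixture_sds[comp])
        )
        true_fwhm = max(true_fwhm, 1.0)
        periodic = float(rng.uniform(20, 195))
        sp_fwhm = max(
            model.sp_intercept + model.sp_slope * periodic
            + float(rng.normal(0, model.sp_fwhm_sd)),
            1.0,
        )
        length = end - start + 1
        ppa = float(rng.uniform(0.5, 2.0))
        matched = max(3, round(ppa * length))
        intensity = float(10 ** rng.uniform(4.0, 5.5))
        peptides.append(
            TruePeptide(
                protein_id=protein.protein_id,
                sequence=seq,
                start=start,
                end=end,
                base_rt=float(rng.uniform(2.0, 28.0)),
                dt_bin=wrap_dt(periodic, model.n_passes),
                true_fwhm=true_fwhm,
                sp_dt_bin=periodic,
                sp_fwhm=sp_fwhm,
                base_plgs_score=float(rng.uniform(7.0, 9.5)),
                base_intensity=intensity,
                products_per_aa=ppa,
                matched_products=matched,
                consecutive_products=int(rng.integers(2, matched + 1)),
                base_sum_product_intensity=intensity * float(rng.uniform(0.5, 2.0)),
                component=comp,
            )
        )
    decoys = make_decoys(protein, th, seed=int(rng.integers(2**31)))
    return SimulationGroundTruth(
        protein=protein,
        true_peptides=tuple(peptides),
        false_positives=tuple(decoys),
        rng_seed=seed,
    )


def _detection_prob(trend: Trendline, dt: float, true_fwhm: float,
                    p_max: float, sigma: float) -> float:
    mismatch = fwhm_at(trend, dt) - true_fwhm
    return p_max * math.exp(-(mismatch**2) / (2.0 * sigma**2))


def _emit(
    rng: np.random.Generator,
    p: TruePeptide,
    model: DetectionModel,
    dt: float,
    replicate_id: str,
    tag: str,
) -> PeptideID:
    return PeptideID(
        protein_id=p.protein_id,
        sequence=p.sequence,
        start=p.start,
        end=p.end,
        modification="",
        plgs_score=max(0.0, p.base_plgs_score + float(rng.normal(0, model.score_jitter_sd))),
        rt=max(0.1, p.base_rt + float(rng.normal(0, model.rt_jitter_sd))),
        dt_bin=float(np.clip(dt + rng.normal(0, 0.5), 0.0, 200.0)),
        intensity=p.base_intensity * float(rng.lognormal(0, model.intensity_jitter)),
        products_per_aa=p.products_per_aa,
        matched_products=p.matched_products,
        consecutive_products=p.consecutive_products,
        sum_product_intensity=p.base_sum_product_intensity
        * float(rng.lognormal(0, model.intensity_jitter)),
        mh_ppm_error=float(rng.normal(0, model.ppm_sd)),
        replicate_id=replicate_id,
        trendline_tag=tag,
    )


def _emit_decoy(d: Decoy, rep_index: int, replicate_id: str, tag: str) -> PeptideID:
    rt = d.base_rt + d.rt_offsets[rep_index % len(d.rt_offsets)]
    return PeptideID(
        protein_id=d.protein_id,
        sequence=d.sequence,
        start=d.start,
        end=d.end,
        modification="",
        plgs_score=d.plgs_score,
        rt=rt,
        dt_bin=d.dt_bin,
        intensity=d.intensity,
        products_per_aa=d.products_per_aa,
        matched_products=d.matched_products,
        consecutive_products=d.consecutive_products,
        sum_product_intensity=d.sum_product_intensity,
        mh_ppm_error=d.mh_ppm_error,
        replicate_id=replicate_id,
        trendline_tag=tag,
    )


def simulate_tables(
    gt: SimulationGroundTruth,
    model: DetectionModel,
    plan: ProcessingPlan,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, list[list[PeptideID]]]:
    """Emit per-trendline, per-replicate peptide-ID tables.

    For every multipass trendline in the plan, each true peptide is
    detected with the Gaussian-kernel probability against its wrapped
    multipass FWHM; the single-pass tag uses the unwrapped population and
    the plan's auto-calculated trendline at the single-pass ceiling.
    Decoys are appended according to their behavior flags.  One random
    substream per (tag, replicate) makes output fully reproducible and
    independent of tag iteration order.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tag_to_trend = {tag: t for t, tag in plan.output_layout.items()}
    tables: dict[str, list[list[PeptideID]]] = {}
    for tag in sorted(tag_to_trend):
        trend = tag_to_trend[tag]
        single = tag == SINGLE_PASS_TAG
        reps: list[list[PeptideID]] = []
        for r in range(n_replicates):
            # deterministic substream per (tag, replicate)
            ss = np.random.SeedSequence(
                entropy=gt.rng_seed + seed,
                spawn_key=(zlib.crc32(tag.encode()), r),
            )
            rng = np.random.default_rng(ss)
            replicate_id = f"rep{r + 1}"
            rows: list[PeptideID] = []
            for p in gt.true_peptides:
                if single:
                    prob = _detection_prob(
                        trend, p.sp_dt_bin, p.sp_fwhm, model.sp_p_max, model.width_sigma
                    )
                    dt = p.sp_dt_bin
                else:
                    prob = _detection_prob(
                        trend, p.dt_bin, p.true_fwhm, model.p_max, model.width_sigma
                    )
                    dt = p.dt_bin
                if rng.random() < prob:
                    rows.append(_emit(rng, p, model, dt, replicate_id, tag))
            for d in gt.false_positives:
                if d.first_replicate_only and r != 0:
                    continue
                rows.append(_emit_decoy(d, r, replicate_id, tag))
            reps.append(rows)
        tables[tag] = reps
    return tables


def write_simulation(
    tables: Mapping[str, Sequence[Sequence[PeptideID]]],
    gt: SimulationGroundTruth,
    root: str | Path,
) -> Path:
    """Write the folder layout the pipeline consumes, plus a truth sidecar.

    Layout: ``root/<tag>/rep<i>.csv`` for every tag and replicate, and
    ``root/ground_truth.csv`` listing true peptides and decoys (column
    ``kind`` is ``true`` or the violated rule name).
    """
    root = Path(root)
    for tag, reps in tables.items():
        for i, table in enumerate(reps):
            write_peptide_table(table, root / tag / f"rep{i + 1}.csv")
    rows = [
        {"protein_id": p.protein_id, "sequence": p.sequence,
         "start": p.start, "end": p.end, "kind": "true"}
        for p in gt.true_peptides
    ] + [
        {"protein_id": d.protein_id, "sequence": d.sequence,
         "start": d.start, "end": d.end, "kind": d.rule}
        for d in gt.false_positives
    ]
    sidecar = root / "ground_truth.csv"
    pd.DataFrame(rows, columns=["protein_id", "sequence", "start", "end", "kind"]).to_csv(
        sidecar, index=False
    )
    return root


def detected_true_keys(
    tables: Mapping[str, Sequence[Sequence[PeptideID]]],
    gt: SimulationGroundTruth,
) -> set[tuple[str, str, str]]:
    """True keys that appear at least once anywhere in the emitted tables."""
    truth = gt.true_keys()
    seen = {
        rec.key
        for reps in tables.values()
        for table in reps
        for rec in table
    }
    return seen & truth


def score_against_truth(
    final_list: Sequence[MergedPeptide],
    gt: SimulationGroundTruth,
    detectable: set[tuple[str, str, str]] | None = None,
) -> tuple[float, float]:
    """Precision and recall of a final peptide list against planted truth.

    Precision = true keys in the final list / final-list size; recall =
    true keys in the final list / number of detectable true keys
    (``detectable`` defaults to every planted true key; pass
    :func:`detected_true_keys` output to score against what the simulated
    detection actually offered).  Both are 0 for empty denominators.
    """
    truth = gt.true_keys()
    final_keys = {m.key for m in final_list}
    hits = final_keys & truth
    denom = truth if detectable is None else detectable
    precision = len(hits) / len(final_keys) if final_keys else 0.0
    recall = len(final_keys & denom) / len(denom) if denom else 0.0
    return precision, recall


def default_simulation(
    seed: int,
    protein_length: int = 300,
    n_replicates: int = 3,
    trendline_texts: str = "7-9,19-21",
    density: float = 0.5,
    model: DetectionModel | None = None,
    thresholds: FilterThresholds | None = None,
):
    """The default simulation profile: one protein, bimodal FWHM mixture,
    two matched multipass trendlines plus the auto-calculated single pass.

    Returns ``(gt, model, plan, tables)``.
    """
    model = model or DetectionModel()
    protein = random_protein(protein_length, seed=seed)
    gt = build_ground_truth(
        protein, model, seed=seed, density=density, thresholds=thresholds
    )
    sp_points = [(p.sp_dt_bin, p.sp_fwhm) for p in gt.true_peptides]
    plan = build_processing_plan(trendline_texts, single_pass_points=sp_points)
    tables = simulate_tables(gt, model, plan, n_replicates=n_replicates, seed=0)
    return gt, model, plan, tables


def trendline_response(
    gt: SimulationGroundTruth,
    model: DetectionModel,
    trendlines: Sequence[Trendline],
    th: FilterThresholds,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[int]:
    """Unique filtered peptide count per candidate trendline.

    Sweeping trendlines from far below to far above the true FWHM
    population traces the characteristic response: counts collapse at the
    extremes (excessive under-/over-smoothing) and peak where the
    trendline matches the population.
    """
    from .filter_pipeline import run_tag_pipeline
    from .trendline import folder_tag

    counts: list[int] = []
    for t in trendlines:
        plan = build_processing_plan(t.render())
        tables = simulate_tables(gt, model, plan, n_replicates=n_replicates, seed=seed)
        counts.append(len(run_tag_pipeline(tables[folder_tag(t)], th)))
    return counts
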