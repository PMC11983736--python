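"""Synthetic data with planted cis-regulatory structure.

Four generators emulate the inputs of a smoke-exposure lncRNA/mRNA study:

* :func:`generate_annotation` — a transcript annotation with a known number
  of divergent lncRNA/coding-gene pairs planted within a distance threshold,
  surrounded by decoy transcripts guaranteed to be farther away.
* :func:`generate_array_experiment` — a duplicate two-condition probe-level
  intensity matrix in which the planted lncRNAs are upregulated and their
  partner mRNAs repressed by known linear fold changes.
* :func:`generate_paired_cohort` — a paired tumor/normal two-gene cohort
  with planted fold differences and a planted negative cross-gene Pearson
  correlation between the two genes' tumor values.
* :func:`generate_single_cell` — a multi-(cell type x exposure) population
  of two-gene expression values whose per-stratum correlation is driven to
  a target by an expression-exclusivity mixture.

Every generator derives an independent pseudo-random stream from
``(seed, call-name)``, so adding or reordering calls never perturbs another
generator's output, and each attaches a ``truth`` record describing what
was planted.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AnnotationSet, ExpressionMatrix, TranscriptAnnotation

__all__ = [
    "GeneratorConfig",
    "StratumSpec",
    "generate_annotation",
    "generate_array_experiment",
    "generate_paired_cohort",
    "generate_single_cell",
]

logger = logging.getLogger(__name__)

# Gene-extent bounds used when laying out loci (bp).
_CODING_LEN = (5_000, 50_000)
_LNC_LEN = (500, 20_000)
_MAX_LEN = 50_000
_PLANTED_TSS_GAP = (1_000, 200_000)  # planted divergent TSS distances drawn here
_LOCUS_MARGIN = 10_000


class GeneratorError(ValueError):
    """Raised for invalid generator configuration or infeasible layouts."""


@dataclass(frozen=True)
class StratumSpec:
    """One (cell type, exposure) stratum of the single-cell generator."""

    cell_type: str
    exposure: str
    n_cells: int
    target_r: float


def _default_strata() -> list[StratumSpec]:
    # Weak negative coefficients, slightly stronger in smokers, mirroring
    # field-effect expectations in airway epithelial subsets.
    spec = [
        ("AT1", -0.05, -0.10),
        ("AT2", -0.06, -0.09),
        ("Club", -0.04, -0.08),
        ("Ciliated", -0.07, -0.07),
    ]
    out = []
    for cell_type, r_never, r_smoker in spec:
        out.append(StratumSpec(cell_type, "never", 1500, r_never))
        out.append(StratumSpec(cell_type, "smoker", 1500, r_smoker))
    return out


@dataclass
class GeneratorConfig:
    """Knobs of all four generators; defaults encode the study conditions.

    Fold changes are linear ratios (> 0); ``mrna_fc`` and ``cohort_down_fc``
    are applied as repression (treated or tumor value divided by the fold).
    ``noise_sd`` is a log2-scale standard deviation shared by the array and
    cohort generators.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 40_000_000, "chr2": 40_000_000}
    )
    n_coding: int = 28
    n_lnc: int = 28
    n_planted_pairs: int = 3
    planted_max_distance: int = 500_000
    lnc_fc: float = 2.5
    mrna_fc: float = 3.6
    noise_sd: float = 0.25
    probes_per_probeset: int = 3
    below_floor_baseline: tuple[float, float] = (3.0, 12.0)  # log2 uniform, decoys
    # Planted features sit inside the support of the intensity distribution
    # (as on a genome-wide array), where quantile normalization is locally
    # rank-linear; the planted coding genes are ~4x brighter than the planted
    # lncRNAs (typical of arrays), which also makes their downward shift
    # offset the lncRNAs' upward rank displacement during normalization.
    planted_lnc_baseline: tuple[float, float] = (8.0, 9.0)  # log2 uniform
    planted_mrna_baseline: tuple[float, float] = (10.0, 11.0)  # log2 uniform
    cohort_n: int = 51
    smoker_fraction: float = 42 / 51
    cohort_up_fc: float = 5.9
    cohort_down_fc: float = 7.4
    cohort_sd: float = 0.6  # log2 sd of patient-level tumor expression
    target_r: float = -0.27
    strata_spec: list[StratumSpec] = field(default_factory=_default_strata)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise GeneratorError("chrom_sizes must be nonempty")
        if min(self.n_coding, self.n_lnc, self.n_planted_pairs) < 0:
            raise GeneratorError("counts must be non-negative")
        if self.n_planted_pairs > min(self.n_coding, self.n_lnc):
            raise GeneratorError(
                "n_planted_pairs must be <= min(n_coding, n_lnc)"
            )
        for name in ("lnc_fc", "mrna_fc", "cohort_up_fc", "cohort_down_fc"):
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be > 0")
        if abs(self.target_r) >= 1:
            raise GeneratorError("|target_r| must be < 1")
        if self.planted_max_distance <= 0:
            raise GeneratorError("planted_max_distance must be > 0")


def _rng(config: GeneratorConfig, call_name: str) -> np.random.Generator:
    """One stream per (seed, call-name): streams are mutually independent."""
    tag = zlib.crc32(call_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


# ---------------------------------------------------------------------------
# Annotation


def generate_annotation(config: GeneratorConfig) -> AnnotationSet:
    """Lay out planted divergent pairs and decoy transcripts on chromosomes.

    Each planted pair is a lncRNA on the minus strand and a coding gene on
    the plus strand with adjacent, divergently oriented TSSs closer than
    ``planted_max_distance``.  Every decoy transcript occupies its own locus
    spaced so that its TSS is at least ``planted_max_distance`` from every
    coding TSS on the same chromosome.

    Returns an :class:`AnnotationSet` whose ``truth`` maps planted pair ids
    to their chromosome and TSS distance.
    """
    rng = _rng(config, "generate_annotation")
    n_pairs = config.n_planted_pairs
    n_decoy_coding = config.n_coding - n_pairs
    n_decoy_lnc = config.n_lnc - n_pairs

    gap_hi = min(_PLANTED_TSS_GAP[1], config.planted_max_distance - 1)
    gap_lo = min(_PLANTED_TSS_GAP[0], gap_hi)
    # Slot size guarantees >= planted_max_distance between TSSs of adjacent
    # loci even in the worst within-locus placement.
    extent = gap_hi + 2 * _MAX_LEN
    slot = config.planted_max_distance + extent + _LOCUS_MARGIN

    loci: list[tuple] = []
    for i in range(n_pairs):
        loci.append(("pair", i))
    for i in range(n_decoy_coding):
        loci.append(("decoy_coding", i))
    for i in range(n_decoy_lnc):
        loci.append(("decoy_lnc", i))

    chrom_names = list(config.chrom_sizes)
    capacities = {}
    for name in chrom_names:
        size = config.chrom_sizes[name]
        cap = (size - _MAX_LEN) // slot
        if cap < 1:
            raise GeneratorError(
                f"chromosome {name} (length {size}) is too small to host a "
                f"locus with decoy spacing {slot} bp"
            )
        capacities[name] = int(cap)
    if sum(capacities.values()) < len(loci):
        raise GeneratorError(
            f"chromosomes {chrom_names} cannot host {len(loci)} loci with "
            f"decoy spacing {slot} bp (capacity {sum(capacities.values())})"
        )

    placements: list[tuple[str, int, tuple]] = []  # (chrom, slot base, locus)
    ci, used = 0, 0
    for locus in loci:
        while used >= capacities[chrom_names[ci]]:
            ci += 1
            used = 0
        base = used * slot + _MAX_LEN + 1
        placements.append((chrom_names[ci], base, locus))
        used += 1

    records: list[TranscriptAnnotation] = []
    planted = []
    for chrom, base, (kind, i) in placements:
        if kind == "pair":
            d = int(rng.integers(gap_lo, gap_hi + 1))
            lnc_len = int(rng.integers(*_LNC_LEN))
            cod_len = int(rng.integers(*_CODING_LEN))
            lnc_tss = base  # minus strand: tss == end
            lnc = TranscriptAnnotation(
                f"LNC{i:04d}", "lncRNA", chrom, "-",
                max(1, lnc_tss - lnc_len + 1), lnc_tss,
            )
            cod = TranscriptAnnotation(
                f"PCG{i:04d}", "coding", chrom, "+",
                lnc_tss + d, lnc_tss + d + cod_len - 1,
            )
            records.extend([lnc, cod])
            planted.append(
                {
                    "lnc_id": lnc.transcript_id,
                    "mrna_id": cod.transcript_id,
                    "chromosome": chrom,
                    "distance": d,
                }
            )
        elif kind == "decoy_coding":
            length = int(rng.integers(*_CODING_LEN))
            strand = "+" if rng.random() < 0.5 else "-"
            start = base
            records.append(
                TranscriptAnnotation(
                    f"PCG{n_pairs + i:04d}", "coding", chrom, strand,
                    start, start + length - 1,
                )
            )
        else:
            length = int(rng.integers(*_LNC_LEN))
            strand = "+" if rng.random() < 0.5 else "-"
            start = base
            records.append(
                TranscriptAnnotation(
                    f"LNC{n_pairs + i:04d}", "lncRNA", chrom, strand,
                    start, start + length - 1,
                )
            )

    for r in records:
        if r.end > config.chrom_sizes[r.chromosome]:
            raise GeneratorError(
                f"chromosome {r.chromosome} too small for {r.transcript_id}"
            )

    truth = {
        "planted_pairs": planted,
        "planted_max_distance": config.planted_max_distance,
        "decoy_ids": [
            r.transcript_id
            for r in records
            if not any(
                r.transcript_id in (p["lnc_id"], p["mrna_id"]) for p in planted
            )
        ],
    }
    return AnnotationSet.from_records(records, truth)


# ---------------------------------------------------------------------------
# Array experiment


def generate_array_experiment(
    annotation: AnnotationSet, config: GeneratorConfig
) -> ExpressionMatrix:
    """Probe-level intensities for a duplicate two-condition array design.

    log2 intensity = baseline + probe affinity + effect * treated + noise.
    Planted lncRNAs carry a multiplicative treated/control effect of
    ``lnc_fc``; their partner mRNAs carry ``1/mrna_fc``; decoys carry no
    systematic effect.  Decoy baselines are drawn log2-uniform over a range
    whose lower tail sits below the 50.0 intensity floor, so presence
    filtering is exercised without a separate knob; planted features are
    drawn from the expressed upper range so the signal survives filtering.

    The returned matrix carries ``probe_map`` (probe id -> feature id) and
    ``truth`` attributes.
    """
    rng = _rng(config, "generate_array_experiment")
    planted = annotation.truth.get("planted_pairs", [])
    lnc_up = {p["lnc_id"] for p in planted}
    mrna_down = {p["mrna_id"] for p in planted}

    samples = ["control_1", "control_2", "treated_1", "treated_2"]
    treated = np.array([0.0, 0.0, 1.0, 1.0])
    k = config.probes_per_probeset

    feature_ids = [r.transcript_id for r in annotation.records()]
    probe_ids: list[str] = []
    probe_map: dict[str, str] = {}
    rows = []
    for fid in feature_ids:
        if fid in lnc_up:
            baseline = rng.uniform(*config.planted_lnc_baseline)
            effect = math.log2(config.lnc_fc)
        elif fid in mrna_down:
            baseline = rng.uniform(*config.planted_mrna_baseline)
            effect = -math.log2(config.mrna_fc)
        else:
            baseline = rng.uniform(*config.below_floor_baseline)
            effect = 0.0
        affinities = rng.normal(0.0, 0.3, size=k)
        for j in range(k):
            pid = f"{fid}:p{j + 1}"
            probe_ids.append(pid)
            probe_map[pid] = fid
            log2_i = (
                baseline
                + affinities[j]
                + effect * treated
                + rng.normal(0.0, config.noise_sd, size=4)
            )
            rows.append(np.exp2(log2_i))

    values = pd.DataFrame(np.array(rows), index=probe_ids, columns=samples)
    design = pd.DataFrame(
        {
            "condition": ["control", "control", "treated", "treated"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    matrix = ExpressionMatrix(values, design)
    matrix.probe_map = probe_map
    matrix.truth = {
        "lnc_up": sorted(lnc_up),
        "mrna_down": sorted(mrna_down),
        "lnc_fc": config.lnc_fc,
        "mrna_fc": config.mrna_fc,
    }
    return matrix


# ---------------------------------------------------------------------------
# Paired cohort


def generate_paired_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Paired tumor/normal two-gene cohort with planted folds and correlation.

    Tumor values of the two genes are bivariate lognormal.  The latent
    normal correlation is chosen by inverting the lognormal correlation
    identity r_linear = (exp(rho * s^2) - 1) / (exp(s^2) - 1), so the
    linear-scale Pearson correlation of the tumor values equals
    ``target_r`` in expectation.  Normal-tissue values are derived so the
    tumor/normal ratio is centered on ``cohort_up_fc`` for gene A and
    1/``cohort_down_fc`` for gene B, with log2-normal ratio noise of sd
    ``noise_sd`` (``noise_sd=0`` makes every ratio exact).

    Columns: patient, smoking, tumor_a, normal_a, tumor_b, normal_b.
    """
    if config.cohort_n < 3:
        raise GeneratorError("cohort_n must be >= 3")
    rng = _rng(config, "generate_paired_cohort")
    n = config.cohort_n
    s = config.cohort_sd * math.log(2)  # natural-log sd
    s2 = s * s
    r = config.target_r
    arg = 1.0 + r * math.expm1(s2)
    if arg <= 0:
        raise GeneratorError(
            f"target_r={r} unreachable for lognormal sd {config.cohort_sd} log2"
        )
    rho = math.log(arg) / s2 if s2 > 0 else r
    rho = float(np.clip(rho, -1.0, 1.0))

    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n
    )
    mu_a, mu_b = math.log(40.0), math.log(40.0)
    tumor_a = np.exp(mu_a + s * z[:, 0])
    tumor_b = np.exp(mu_b + s * z[:, 1])
    ln2 = math.log(2)
    ratio_a = config.cohort_up_fc * np.exp(
        rng.normal(0.0, config.noise_sd * ln2, size=n)
    )
    ratio_b = config.cohort_down_fc * np.exp(
        rng.normal(0.0, config.noise_sd * ln2, size=n)
    )
    normal_a = tumor_a / ratio_a  # gene A up in tumor
    normal_b = tumor_b * ratio_b  # gene B down in tumor

    n_smokers = int(round(config.smoker_fraction * n))
    smoking = np.array(["never"] * n, dtype=object)
    smoking[rng.permutation(n)[:n_smokers]] = "smoker"

    table = pd.DataFrame(
        {
            "patient": [f"P{i + 1:03d}" for i in range(n)],
            "smoking": smoking,
            "tumor_a": tumor_a,
            "normal_a": normal_a,
            "tumor_b": tumor_b,
            "normal_b": normal_b,
        }
    )
    table.attrs["truth"] = {
        "cohort_up_fc": config.cohort_up_fc,
        "cohort_down_fc": config.cohort_down_fc,
        "target_r": r,
        "latent_rho": rho,
    }
    return table


# ---------------------------------------------------------------------------
# Single cell


def _exclusivity_params(target_r: float) -> tuple[float, float]:
    """(dominance increment delta, uniform-noise width c) for r = target_r < 0.

    With a fair dominance coin, values a = base + delta*I + U(0, c) and
    b = base + delta*(1-I) + U(0, c):  cov = -delta^2/4 and
    var = delta^2/4 + c^2/12, so  r = -(delta^2/4) / (delta^2/4 + c^2/12).
    Solving on the unit-variance scale (delta^2/4 = |r|, c^2/12 = 1 - |r|)
    is exact; every stratum then has variance 1, and strata means are
    equalized so the pooled coefficient is the stratum average rather than
    a between-strata artifact.
    """
    q = abs(target_r)
    delta = 2.0 * math.sqrt(q)
    c = math.sqrt(12.0 * (1.0 - q))
    return delta, c


def generate_single_cell(config: GeneratorConfig) -> pd.DataFrame:
    """Two-gene expression over labeled cells with planted per-stratum r.

    Negative correlations arise from an exclusivity mixture: each cell
    draws a fair dominance indicator, the dominant gene receives a fixed
    expression increment and the dominated gene does not, and uniform
    background noise is scaled so that the stratum's Pearson correlation
    equals its ``target_r`` exactly in expectation.  A positive
    ``target_r`` cannot arise from exclusivity, so such strata fall back
    to a shared-latent (common uniform component) construction and a
    warning is logged.

    Columns: cell_id, cell_type, exposure, value_a, value_b.
    """
    if not config.strata_spec:
        raise GeneratorError("strata_spec must be nonempty")
    for st in config.strata_spec:
        if abs(st.target_r) >= 1:
            raise GeneratorError(
                f"stratum ({st.cell_type}, {st.exposure}): |target_r| must be < 1"
            )
    rng = _rng(config, "generate_single_cell")

    mean_level = 3.0  # common stratum mean; keeps all values positive
    frames = []
    cell_counter = 0
    for st in config.strata_spec:
        n = st.n_cells
        r = st.target_r
        if r < 0:
            delta, c = _exclusivity_params(r)
            base = mean_level - delta / 2.0 - c / 2.0
            dom = rng.random(n) < 0.5
            a = base + delta * dom + rng.uniform(0.0, c, size=n)
            b = base + delta * (~dom) + rng.uniform(0.0, c, size=n)
        elif r == 0:
            c = math.sqrt(12.0)
            a = mean_level - c / 2.0 + rng.uniform(0.0, c, size=n)
            b = mean_level - c / 2.0 + rng.uniform(0.0, c, size=n)
        else:
            logger.warning(
                "stratum (%s, %s): positive target_r=%.3f cannot come from an "
                "exclusivity mixture; using a shared-latent construction",
                st.cell_type, st.exposure, r,
            )
            lam = math.sqrt(r / (1.0 - r))
            s = math.sqrt(12.0 / (1.0 + lam * lam))
            g = rng.uniform(-0.5, 0.5, size=n)
            a = mean_level + s * (rng.uniform(-0.5, 0.5, size=n) + lam * g)
            b = mean_level + s * (rng.uniform(-0.5, 0.5, size=n) + lam * g)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [
                        f"cell{cell_counter + i:06d}" for i in range(n)
                    ],
                    "cell_type": st.cell_type,
                    "exposure": st.exposure,
                    "value_a": a,
                    "value_b": b,
                }
            )
        )
        cell_counter += n
    cells = pd.concat(frames, ignore_index=True)
    cells.attrs["truth"] = {
        f"{st.cell_type}|{st.exposure}": {
            "n_cells": st.n_cells,
            "target_r": st.target_r,
        }
        for st in config.strata_spec
    }
    return cells
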