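"""Synthetic SNP-array data with embedded copy-number deletions.

The generator emulates the statistical structure of Illumina-style tumor
SNP arrays: a panel of rs-identified loci, integer copy number per
(sample, locus) in {0, 1, 2}, Gaussian log-R-ratio (LRR) emission centered
on a copy-number-dependent mean, and B-allele-frequency (BAF) emission with
genotype-dependent cluster centers. A designated contiguous block of the
panel plays the role of the MACROD2 locus on chromosome 20: samples carry
no deletion there (wild-type), a hemizygous segment (heterozygous
deletion), or a segment with both alleles lost (homozygous deletion), and
the sample-level state label is derived from the emitted copy numbers.

Default class sizes reproduce the 651-tumor colorectal-cancer cohort the
package models: 441 wild-type / 137 heterozygous / 73 homozygous for
MACROD2 status, and 60/208/297/86 for the four Dukes stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataio import LabeledDataset, SignalKind, SignalMatrix, SNPMarker

__all__ = [
    "WILD_TYPE",
    "HET_DEL",
    "HOM_DEL",
    "STATE_CLASS_NAMES",
    "MACROD2_CLASS_SIZES",
    "DUKES_CLASS_NAMES",
    "DUKES_CLASS_SIZES",
    "COHORT_SIZE",
    "SimulationConfig",
    "CopyNumberProfile",
    "simulate_markers",
    "simulate_copy_number",
    "derive_state_label",
    "simulate_lrr",
    "simulate_baf",
    "simulate_dataset",
    "simulate_dukes_dataset",
]

WILD_TYPE = "Wild-type"
HET_DEL = "Heterozygous deletion"
HOM_DEL = "Homozygous deletion"
STATE_CLASS_NAMES: tuple[str, ...] = (WILD_TYPE, HET_DEL, HOM_DEL)

#: Study-cohort composition the defaults emulate (651 colorectal tumors).
MACROD2_CLASS_SIZES: dict[str, int] = {WILD_TYPE: 441, HET_DEL: 137, HOM_DEL: 73}
DUKES_CLASS_NAMES: tuple[str, ...] = ("Dukes A", "Dukes B", "Dukes C", "Dukes D")
DUKES_CLASS_SIZES: dict[str, int] = {
    "Dukes A": 60,
    "Dukes B": 208,
    "Dukes C": 297,
    "Dukes D": 86,
}
COHORT_SIZE = 651


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the copy-number and signal-emission model.

    ``lrr_means`` maps copy number to the LRR cluster center; the defaults
    (CN2 -> 0.0, CN1 -> -0.45, CN0 -> -1.0) reflect the attenuated response
    of tumor arrays, where published deletion thresholds sit near -0.25 to
    -0.5. ``del_frac_range`` bounds the per-sample deleted segment length
    as a fraction of the gene region; the 0.6 lower bound guarantees that
    every deleted sample shares a common core of deleted markers.
    """

    n_samples: Mapping[str, int] = field(
        default_factory=lambda: dict(MACROD2_CLASS_SIZES)
    )
    n_markers: int = 2000
    gene_region: tuple[int, int] = (975, 1025)  # half-open marker index range
    lrr_means: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.0, 1: -0.45, 0: -1.0}
    )
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    allele_freq: np.ndarray | None = None  # per-marker B-allele freq; drawn U[0.1, 0.9] if None
    background_cnv_rate: float = 0.01  # expected fraction of off-region markers altered
    background_segment_mean_len: float = 5.0
    del_frac_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_samples.values()):
            raise ValueError("class sizes must be non-negative")
        if sum(self.n_samples.values()) == 0:
            raise ValueError("zero samples in every class")
        if self.n_markers < 1:
            raise ValueError("n_markers must be positive")
        lo, hi = self.gene_region
        if not (0 <= lo < hi <= self.n_markers):
            raise ValueError(
                f"gene_region {self.gene_region} must be a non-empty range within "
                f"[0, {self.n_markers})"
            )
        if not (self.lrr_means[0] < self.lrr_means[1] < self.lrr_means[2]):
            raise ValueError("lrr_means must decrease strictly with copy number loss")
        if self.lrr_sd < 0 or self.baf_sd < 0:
            raise ValueError("noise sds must be >= 0")
        f0, f1 = self.del_frac_range
        if not (0 < f0 <= f1 <= 1):
            raise ValueError("del_frac_range must satisfy 0 < lo <= hi <= 1")
        if self.allele_freq is not None:
            af = np.asarray(self.allele_freq, float)
            if af.shape != (self.n_markers,) or af.min() <= 0 or af.max() >= 1:
                raise ValueError("allele_freq must be per-marker values in (0, 1)")

    @property
    def region_size(self) -> int:
        return self.gene_region[1] - self.gene_region[0]


@dataclass
class CopyNumberProfile:
    """Integer copy number per (sample, marker), plus the gene-region bounds."""

    matrix: np.ndarray  # int, values in {0, 1, 2}
    gene_region: tuple[int, int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("copy-number matrix must be 2-D")
        if not np.isin(self.matrix, (0, 1, 2)).all():
            raise ValueError("copy numbers must be in {0, 1, 2}")
        lo, hi = self.gene_region
        if not (0 <= lo < hi <= self.matrix.shape[1]):
            raise ValueError("gene_region out of panel bounds or empty")

    @property
    def region_slice(self) -> slice:
        return slice(*self.gene_region)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, seed-deterministic streams per emission stage
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def simulate_markers(config: SimulationConfig) -> list[SNPMarker]:
    """Panel metadata: gene-region markers sit on chromosome 20 at ~14.5 Mb
    (the MACROD2 locus), the rest are spread over the remaining autosomes."""
    config.validate()
    lo, hi = config.gene_region
    others = [c for c in range(1, 23) if c != 20]
    markers: list[SNPMarker] = []
    off = 0
    for i in range(config.n_markers):
        if lo <= i < hi:
            markers.append(SNPMarker(f"rs{1000000 + i}", "20", 14_500_000 + 30_000 * (i - lo)))
        else:
            chrom = others[off % len(others)]
            markers.append(SNPMarker(f"rs{1000000 + i}", str(chrom), 1 + 25_000 * (off + 1)))
            off += 1
    return markers


def _deletion_segment(rng: np.random.Generator, region_len: int, frac_range) -> tuple[int, int]:
    lmin = max(1, math.ceil(frac_range[0] * region_len))
    lmax = max(lmin, math.floor(frac_range[1] * region_len))
    length = int(rng.integers(lmin, lmax + 1))
    start = int(rng.integers(0, region_len - length + 1))
    return start, start + length


def simulate_copy_number(config: SimulationConfig) -> CopyNumberProfile:
    """Draw the integer copy-number matrix.

    Samples are laid out class-by-class in ``config.n_samples`` order:
    wild-type samples keep CN=2 across the gene region, heterozygous ones
    get CN=1 on a random contiguous sub-segment, homozygous ones CN=0.
    Off-region background CNV segments (deletions) are sprinkled at
    ``background_cnv_rate`` to give feature selection distractors; they
    never touch the gene region, so state labels derived from the matrix
    always match the intended classes.
    """
    config.validate()
    rng = _rng(config, 0)
    n = sum(config.n_samples.values())
    cn = np.full((n, config.n_markers), 2, dtype=np.int8)
    lo, hi = config.gene_region
    region_len = hi - lo

    # background segmental deletions outside the gene region
    if config.background_cnv_rate > 0:
        mean_len = config.background_segment_mean_len
        lam = config.background_cnv_rate * (config.n_markers - region_len) / mean_len
        for i in range(n):
            for _ in range(rng.poisson(lam)):
                seg_len = 1 + rng.geometric(1.0 / mean_len)
                start = int(rng.integers(0, config.n_markers))
                state = 1 if rng.random() < 0.8 else 0
                cn[i, start : start + seg_len] = state
        cn[:, lo:hi] = 2  # background never overlaps the gene region

    row = 0
    for cls, size in config.n_samples.items():
        for _ in range(size):
            if cls == HET_DEL:
                s, e = _deletion_segment(rng, region_len, config.del_frac_range)
                cn[row, lo + s : lo + e] = 1
            elif cls == HOM_DEL:
                s, e = _deletion_segment(rng, region_len, config.del_frac_range)
                cn[row, lo + s : lo + e] = 0
            elif cls != WILD_TYPE:
                raise ValueError(
                    f"unknown state class {cls!r}; expected one of {STATE_CLASS_NAMES}"
                )
            row += 1
    return CopyNumberProfile(cn, config.gene_region)


def derive_state_label(profile: CopyNumberProfile) -> list[str]:
    """Per-sample deletion-state label from the gene-region copy numbers.

    Homozygous wins over heterozygous: any CN=0 marker in the region calls
    homozygous deletion, else any CN=1 calls heterozygous, else wild-type.
    """
    region = profile.matrix[:, profile.region_slice]
    labels = []
    for row in region:
        if (row == 0).any():
            labels.append(HOM_DEL)
        elif (row == 1).any():
            labels.append(HET_DEL)
        else:
            labels.append(WILD_TYPE)
    return labels


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def simulate_lrr(
    profile: CopyNumberProfile,
    config: SimulationConfig,
    markers: Sequence[SNPMarker] | None = None,
) -> SignalMatrix:
    """LRR emission: Gaussian around the copy-number-dependent mean."""
    rng = _rng(config, 1)
    means = np.array([config.lrr_means[0], config.lrr_means[1], config.lrr_means[2]])
    values = means[profile.matrix] + rng.normal(0.0, 1.0, profile.matrix.shape) * config.lrr_sd
    markers = list(markers) if markers is not None else simulate_markers(config)
    return SignalMatrix(_sample_ids(profile.matrix.shape[0]), markers, values, SignalKind.LRR)


def _allele_freqs(config: SimulationConfig) -> np.ndarray:
    if config.allele_freq is not None:
        return np.asarray(config.allele_freq, float)
    return _rng(config, 3).uniform(0.1, 0.9, config.n_markers)


def simulate_baf(
    profile: CopyNumberProfile,
    config: SimulationConfig,
    markers: Sequence[SNPMarker] | None = None,
) -> SignalMatrix:
    """BAF emission.

    CN=2: genotype drawn Hardy-Weinberg from the marker's B-allele
    frequency, cluster centers 0 / 0.5 / 1 for AA / AB / BB plus clipped
    Gaussian noise. CN=1: the single remaining allele gives center 0 or 1.
    CN=0: no allele hybridizes, so the value is uniform noise on [0, 1].
    """
    rng = _rng(config, 2)
    cn = profile.matrix
    p = _allele_freqs(config)[np.newaxis, :]  # B-allele frequency per marker
    u = rng.random(cn.shape)

    centers = np.empty(cn.shape, dtype=float)
    # CN=2: AA w.p. (1-p)^2, AB w.p. 2p(1-p), BB w.p. p^2
    aa = (1 - p) ** 2
    ab = 2 * p * (1 - p)
    centers[:] = np.where(u < aa, 0.0, np.where(u < aa + ab, 0.5, 1.0))
    # CN=1: remaining allele is B w.p. p
    centers = np.where(cn == 1, (u < p).astype(float), centers)

    noise = rng.normal(0.0, 1.0, cn.shape) * config.baf_sd
    values = np.clip(centers + noise, 0.0, 1.0)
    values = np.where(cn == 0, rng.random(cn.shape), values)
    markers = list(markers) if markers is not None else simulate_markers(config)
    return SignalMatrix(_sample_ids(cn.shape[0]), markers, values, SignalKind.BAF)


def simulate_dataset(
    config: SimulationConfig, signal_kind: SignalKind | str = SignalKind.LRR
) -> tuple[LabeledDataset, CopyNumberProfile]:
    """End-to-end draw: copy numbers, signal emission, derived state labels."""
    kind = SignalKind.coerce(signal_kind)
    profile = simulate_copy_number(config)
    markers = simulate_markers(config)
    if kind is SignalKind.LRR:
        matrix = simulate_lrr(profile, config, markers)
    else:
        matrix = simulate_baf(profile, config, markers)
    labels = derive_state_label(profile)
    return LabeledDataset(matrix, labels, STATE_CLASS_NAMES), profile


def simulate_dukes_dataset(
    config: SimulationConfig,
    class_sizes: Mapping[str, int] | None = None,
    signal_kind: SignalKind | str = SignalKind.LRR,
) -> tuple[LabeledDataset, CopyNumberProfile]:
    """A four-stage cohort with a stylized monotone deletion burden.

    Stage labels are not derivable from a single gene state, so each stage
    deletes (CN=1) a stage-specific prefix of the gene region: none for
    stage A, one third for B, two thirds for C, the full region for D.
    This keeps the stages separable through the same CNV signal channel
    while preserving the cohort's class imbalance.
    """
    config.validate()
    sizes = dict(class_sizes) if class_sizes is not None else dict(DUKES_CLASS_SIZES)
    names = tuple(sizes)
    n = sum(sizes.values())
    base = replace(config, n_samples={WILD_TYPE: n})
    profile = simulate_copy_number(base)  # background CNVs only
    lo, hi = config.gene_region
    region_len = hi - lo
    labels: list[str] = []
    row = 0
    for stage_idx, (cls, size) in enumerate(sizes.items()):
        extent = round(region_len * stage_idx / (len(sizes) - 1))
        for _ in range(size):
            if extent:
                profile.matrix[row, lo : lo + extent] = 1
            labels.append(cls)
            row += 1
    markers = simulate_markers(config)
    kind = SignalKind.coerce(signal_kind)
    if kind is SignalKind.LRR:
        matrix = simulate_lrr(profile, config, markers)
    else:
        matrix = simulate_baf(profile, config, markers)
    return LabeledDataset(matrix, labels, names), profile
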