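"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage of the pipeline (scan, clade partition, CNV phasing,
isoform regression, transcript counting) can be exercised hermetically on
data produced here:

* a bespoke Kingman-coalescent / infinite-sites simulator provides neutral
  10 kb windows for the genome-wide null distribution of Tajima's D;
* a two-clade "balanced region" is built structurally — d fixed inter-clade
  differences plus independent within-clade coalescent variation — emulating
  a deep haplotype split at intermediate frequency rather than simulating a
  selection trajectory;
* clade-conditional multiallelic repeat-allele spectra are dropped through
  parent-offspring trios and three-generation pedigrees with Mendelian
  transmission and optional +/-1 measurement error on diploid totals;
* protein isoform sizes are linear in diploid copy number with a secretor
  offset and Gaussian noise;
* long-read transcript exon chains tile a repeat array, with a configurable
  fraction of reads truncated at a random 5' or 3' point.

All randomness flows from one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical config implies bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .selscan import HaplotypeMatrix
from .txrepeats import RepeatAnnotation, TranscriptAlignment

SHORT, LONG = "short", "long"
#: tag-SNP allele carried by each clade: the short-repeat clade rides on the
#: C allele, the long-repeat clade on the A allele.
TAG_ALLELE = {SHORT: "C", LONG: "A"}

#: mock coordinates mirroring the 16.5 kb footprint region (GRCh38 chr10).
REGION_CHROM = "chr10"
REGION_START = 122_555_466      # 1-based
REGION_LEN = 16_500

#: band sizes (kDa) of the four salivary protein size classes; class IV shows
#: a double band.
ISOFORM_BANDS = {"I": (345.0,), "II": (375.0,), "III": (389.0,),
                 "IV": (287.0, 345.0)}


class DegenerateConfigError(ValueError):
    """Clade frequency rounds to an empty or full clade."""


def _as_spectrum(d: Mapping[int, float]) -> dict[int, float]:
    total = float(sum(d.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probability vector sums to {total}, not 1")
    if any(v < 0 for v in d.values()):
        raise ValueError("negative probability in spectrum")
    return {int(k): float(v) for k, v in d.items()}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the structure of the real inputs: ~100 haplotypes per
    population window, a deep two-clade split at intermediate frequency over
    a 16.5 kb region, repeat alleles between 7 and 21 units with the short
    clade centred on 8 and the long clade on 13, CEPH-style three-generation
    families plus parent-offspring trios, and isoform sizes on the kDa scale
    of the saliva panel.
    """

    seed: int = 0
    n_haplotypes: int = 100
    theta: float = 5.0                  # scaled mutation rate per window
    n_neutral_windows: int = 1000
    window_bp: int = 10_000
    clade_freq: float = 0.5             # fraction of haplotypes in the short clade
    clade_divergence: int = 20          # fixed inter-clade differences
    theta_within: float = 2.0
    cnv_spectrum_by_clade: dict[str, dict[int, float]] = field(
        default_factory=lambda: {
            SHORT: {8: 0.60, 9: 0.15, 11: 0.20, 13: 0.05},
            LONG: {8: 0.05, 11: 0.20, 13: 0.55, 14: 0.20},
        })
    kmin: int = 7
    kmax: int = 21
    n_trios: int = 65
    n_pedigrees: int = 10               # three-generation, CEPH-like
    pedigree_children: int = 8
    cn_measurement_error: float = 0.0   # P(+/-1 on a diploid total)
    isoform_slope: float = 6.0          # kDa per diploid repeat unit
    isoform_intercept: float = 228.0    # kDa
    secretor_effect: float = 10.0       # kDa added for Se+
    isoform_noise_sd: float = 5.0
    secretor_null_freq: float = 0.45    # FUT2 null allele frequency
    n_reads: int = 1000
    truncation_rate: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.clade_freq < 1:
            raise ValueError("clade_freq must lie strictly between 0 and 1")
        if self.kmin < 1 or self.kmax < self.kmin:
            raise ValueError("need 1 <= kmin <= kmax")
        for clade, spec in self.cnv_spectrum_by_clade.items():
            spec = _as_spectrum(spec)
            if any(k < self.kmin or k > self.kmax for k in spec):
                raise ValueError(f"{clade} spectrum outside [{self.kmin}, {self.kmax}]")
            self.cnv_spectrum_by_clade[clade] = spec
        for name in ("theta", "theta_within"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("cn_measurement_error", "truncation_rate",
                     "secretor_null_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth accompanying simulated data."""

    clade_labels: np.ndarray | None = None      # per haplotype
    cnv_alleles: pd.DataFrame | None = None     # per-haplotype repeat alleles
    isoform_sizes: np.ndarray | None = None
    transcript_units: int | None = None


# --------------------------------------------------------------------------
# Kingman coalescent with infinite-sites mutations
# --------------------------------------------------------------------------

def _coalescent_carriers(n: int, theta: float,
                         rng: np.random.Generator) -> list[np.ndarray]:
    """Simulate one genealogy; return one boolean carrier vector per mutation.

    Time is in units of 2N generations: with j active lineages the waiting
    time to the next coalescence is Exponential(rate j(j-1)/2), and each
    branch accumulates Poisson(theta/2 * length) mutations, every mutation
    marking the leaves below its branch.
    """
    lineages: list[tuple[np.ndarray, float]] = [
        (np.eye(1, n, i, dtype=bool)[0], 0.0) for i in range(n)]
    branches: list[tuple[np.ndarray, float]] = []
    j = n
    while j > 1:
        dt = rng.exponential(2.0 / (j * (j - 1)))
        lineages = [(lv, ln + dt) for lv, ln in lineages]
        i1, i2 = rng.choice(j, size=2, replace=False)
        i1, i2 = (int(i1), int(i2)) if i1 < i2 else (int(i2), int(i1))
        leaves2, len2 = lineages.pop(i2)
        leaves1, len1 = lineages.pop(i1)
        branches.append((leaves1, len1))
        branches.append((leaves2, len2))
        lineages.append((leaves1 | leaves2, 0.0))
        j -= 1
    carriers: list[np.ndarray] = []
    for leaves, length in branches:
        for _ in range(rng.poisson(theta / 2.0 * length)):
            carriers.append(leaves.copy())
    return carriers


def _place_sites(carriers: list[np.ndarray], n: int, start_1based: int,
                 span: int, rng: np.random.Generator,
                 chrom: str) -> HaplotypeMatrix:
    """Assign distinct uniform positions to mutation columns and sort."""
    S = len(carriers)
    if S > span:
        raise ValueError("more mutations than available positions in window")
    offsets = rng.choice(span, size=S, replace=False) if S else np.empty(0, int)
    order = np.argsort(offsets)
    positions = start_1based + np.sort(offsets)
    alleles = np.zeros((n, S), dtype=np.uint8)
    for col, idx in enumerate(order):
        alleles[carriers[idx], col] = 1
    return HaplotypeMatrix(chrom, positions, alleles)


def simulate_neutral_window(n: int, theta: float, seed: int | np.random.Generator,
                            window_bp: int = 10_000,
                            chrom: str = "chrSim",
                            start: int = 1) -> HaplotypeMatrix:
    """One neutral 10 kb window under the standard coalescent.

    E[S] = theta * sum_{i<n} 1/i; E[Tajima's D] ~ 0.  Positions are uniform
    and distinct inside the window (1-based ``start``).
    """
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    carriers = _coalescent_carriers(n, theta, rng)
    return _place_sites(carriers, n, start, window_bp, rng, chrom)


def simulate_balanced_region(n: int, clade_freq: float, clade_divergence: int,
                             theta_within: float,
                             seed: int | np.random.Generator,
                             chrom: str = REGION_CHROM,
                             start: int = REGION_START,
                             span: int = REGION_LEN,
                             ) -> tuple[HaplotypeMatrix, SimTruth]:
    """Two deeply diverged haplotype clades over a 16.5 kb mock region.

    ``round(clade_freq * n)`` haplotypes form the short clade; the region
    carries ``clade_divergence`` sites fixed between clades plus independent
    within-clade coalescent variation.  ``theta_within`` is the regional
    scaled mutation rate; each clade's coalescent runs at ``theta_within``
    times its frequency, since an allelic class maintained at frequency f
    has effective size f N.  An intermediate-frequency deep split inflates
    pi relative to S/a1, producing the strongly positive Tajima's D the scan
    is designed to detect.
    """
    if not 0 < clade_freq < 1:
        raise ValueError("clade_freq must lie strictly between 0 and 1")
    if clade_divergence < 1:
        raise ValueError("clade_divergence must be >= 1")
    n_short = int(round(clade_freq * n))
    if n_short in (0, n):
        raise DegenerateConfigError(
            f"clade_freq {clade_freq} with n {n} leaves one clade empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.array([SHORT] * n_short + [LONG] * (n - n_short))

    carriers: list[np.ndarray] = []
    for _ in range(clade_divergence):
        carriers.append(labels == SHORT)        # fixed inter-clade difference
    for clade, mask in ((SHORT, labels == SHORT), (LONG, labels == LONG)):
        clade_theta = theta_within * mask.sum() / n
        if clade_theta > 0 and mask.sum() >= 2:
            sub = _coalescent_carriers(int(mask.sum()), clade_theta, rng)
            idx = np.flatnonzero(mask)
            for leaves in sub:
                col = np.zeros(n, dtype=bool)
                col[idx[leaves]] = True
                carriers.append(col)
    mat = _place_sites(carriers, n, start, span, rng, chrom)
    return mat, SimTruth(clade_labels=labels)


# --------------------------------------------------------------------------
# CNV alleles through families
# --------------------------------------------------------------------------

def _draw_allele(spectrum: Mapping[int, float], rng: np.random.Generator) -> int:
    ks = sorted(spectrum)
    ps = np.array([spectrum[k] for k in ks])
    return int(rng.choice(ks, p=ps / ps.sum()))


def _founder_haplotype(config: SimConfig, rng: np.random.Generator) -> tuple[str, str, int]:
    clade = SHORT if rng.random() < config.clade_freq else LONG
    k = _draw_allele(config.cnv_spectrum_by_clade[clade], rng)
    return clade, TAG_ALLELE[clade], k


@dataclass
class FamilyPanel:
    """Simulated pedigree cohort: observables plus per-haplotype ground truth.

    ``pedigree``: family, individual, father, mother, sex (0 marks founders'
    absent parents).  ``observations``: individual, diploid_total (with
    measurement error applied), true_total.  ``tag_phase``: phased tag-SNP
    alleles with parental origin, treated as known from SNP phasing.
    ``transmissions``: which parental haplotype (slot) each non-founder
    haplotype descends from — the observable counterpart of region-scale SNP
    phase, which identifies transmitted haplotypes in real pedigrees.
    ``truth``: per-haplotype (individual, origin, clade, tag_allele, allele,
    is_founder) records.
    """

    pedigree: pd.DataFrame
    observations: pd.DataFrame
    tag_phase: pd.DataFrame
    transmissions: pd.DataFrame
    truth: pd.DataFrame


def simulate_cnv_and_families(config: SimConfig,
                              truth: SimTruth | None = None,
                              rng: np.random.Generator | None = None) -> FamilyPanel:
    """Draw clade-linked repeat alleles and push them through families.

    Founder haplotypes take (clade, tag allele, repeat allele) from the
    clade-conditional spectra — or from ``truth.clade_labels`` when a
    balanced-region simulation is supplied, consuming two labels per founder.
    Non-founders receive one random haplotype from each parent (Mendelian
    transmission).  Diploid totals are reported with probability
    ``cn_measurement_error`` of a +/-1 error.
    """
    rng = config.rng() if rng is None else rng
    label_iter = iter(truth.clade_labels) if truth is not None and truth.clade_labels is not None else None

    ped_rows, obs_rows, phase_rows, trans_rows, truth_rows = [], [], [], [], []
    haplotypes: dict[str, dict[str, tuple[str, str, int]]] = {}

    def new_founder(fam: str, ind: str, sex: int) -> None:
        haps = {}
        for origin in ("pat", "mat"):
            if label_iter is not None:
                try:
                    clade = str(next(label_iter))
                    k = _draw_allele(config.cnv_spectrum_by_clade[clade], rng)
                    hap = (clade, TAG_ALLELE[clade], k)
                except StopIteration:
                    hap = _founder_haplotype(config, rng)
            else:
                hap = _founder_haplotype(config, rng)
            haps[origin] = hap
        haplotypes[ind] = haps
        ped_rows.append((fam, ind, "0", "0", sex))
        _emit(fam, ind, founder=True)

    def new_child(fam: str, ind: str, father: str, mother: str, sex: int) -> None:
        pat_src = "pat" if rng.random() < 0.5 else "mat"
        mat_src = "pat" if rng.random() < 0.5 else "mat"
        haplotypes[ind] = {"pat": haplotypes[father][pat_src],
                           "mat": haplotypes[mother][mat_src]}
        trans_rows.append((ind, pat_src, mat_src))
        ped_rows.append((fam, ind, father, mother, sex))
        _emit(fam, ind, founder=False)

    def _emit(fam: str, ind: str, founder: bool) -> None:
        haps = haplotypes[ind]
        total = haps["pat"][2] + haps["mat"][2]
        observed = total
        if config.cn_measurement_error > 0 and rng.random() < config.cn_measurement_error:
            observed += int(rng.choice([-1, 1]))
        obs_rows.append((ind, observed, total))
        phase_rows.append((ind, haps["pat"][1], haps["mat"][1]))
        for origin in ("pat", "mat"):
            clade, tag, k = haps[origin]
            truth_rows.append((fam, ind, origin, clade, tag, k, founder))

    for t in range(config.n_trios):
        fam = f"T{t:04d}"
        new_founder(fam, f"{fam}_F", 1)
        new_founder(fam, f"{fam}_M", 2)
        new_child(fam, f"{fam}_C", f"{fam}_F", f"{fam}_M",
                  int(rng.integers(1, 3)))

    for p in range(config.n_pedigrees):
        fam = f"P{p:04d}"
        new_founder(fam, f"{fam}_GF1", 1)
        new_founder(fam, f"{fam}_GM1", 2)
        new_founder(fam, f"{fam}_GF2", 1)
        new_founder(fam, f"{fam}_GM2", 2)
        new_child(fam, f"{fam}_F", f"{fam}_GF1", f"{fam}_GM1", 1)
        new_child(fam, f"{fam}_M", f"{fam}_GF2", f"{fam}_GM2", 2)
        for c in range(config.pedigree_children):
            new_child(fam, f"{fam}_C{c}", f"{fam}_F", f"{fam}_M",
                      int(rng.integers(1, 3)))

    pedigree = pd.DataFrame(ped_rows, columns=["family", "individual",
                                               "father", "mother", "sex"])
    observations = pd.DataFrame(obs_rows, columns=["individual",
                                                   "diploid_total", "true_total"])
    tag_phase = pd.DataFrame(phase_rows, columns=["individual", "pat", "mat"])
    transmissions = pd.DataFrame(trans_rows, columns=["individual",
                                                      "pat_source", "mat_source"])
    truth_df = pd.DataFrame(truth_rows, columns=["family", "individual",
                                                 "origin", "clade",
                                                 "tag_allele", "allele",
                                                 "is_founder"])
    return FamilyPanel(pedigree, observations, tag_phase, transmissions,
                       truth_df)


# --------------------------------------------------------------------------
# Isoforms and transcripts
# --------------------------------------------------------------------------

def classify_isoform(size_kda: float) -> str:
    """Size class from a band size, by nearest canonical class midpoint.

    Class midpoints: IV = 316 (mean of its 287/345 double band), I = 345,
    II = 375, III = 389 kDa.
    """
    mids = {"IV": 316.0, "I": 345.0, "II": 375.0, "III": 389.0}
    return min(mids, key=lambda c: abs(mids[c] - size_kda))


def simulate_isoform_panel(diploid_cns: Sequence[int], config: SimConfig,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Protein sizes linear in diploid repeat copy number with secretor offset.

    size = intercept + slope * CN + secretor_effect * 1[Se+] + N(0, noise_sd).
    Secretor status is recessive in the FUT2 null allele: Se- with probability
    ``secretor_null_freq ** 2``.
    """
    if config.isoform_slope <= 0:
        raise ValueError("isoform_slope must be positive")
    rng = config.rng() if rng is None else rng
    rows = []
    for i, cn in enumerate(diploid_cns):
        se_pos = rng.random() >= config.secretor_null_freq ** 2
        size = (config.isoform_intercept + config.isoform_slope * cn
                + (config.secretor_effect if se_pos else 0.0)
                + (rng.normal(0.0, config.isoform_noise_sd)
                   if config.isoform_noise_sd > 0 else 0.0))
        cls = classify_isoform(size)
        rows.append((f"S{i+1}", int(cn), "+" if se_pos else "-", cls,
                     ",".join(f"{b:g}" for b in ISOFORM_BANDS[cls]), size))
    return pd.DataFrame(rows, columns=["sample", "srcr_diploid_cn", "secretor",
                                       "isoform", "bands", "size_kda"])


def make_repeat_annotation(n_units: int = 14, unit_len: int = 300,
                           gap: int = 100, contig: str = REGION_CHROM,
                           start: int = 10_000,
                           strand: str = "+") -> RepeatAnnotation:
    """Equally spaced repeat-unit exon annotation for a mock gene model."""
    units = [(start + i * (unit_len + gap), start + i * (unit_len + gap) + unit_len)
             for i in range(n_units)]
    return RepeatAnnotation(contig=contig, units=units, strand=strand)


def simulate_transcript_reads(annotation: RepeatAnnotation,
                              true_unit_count: int,
                              n_reads: int,
                              truncation_rate: float,
                              seed: int | np.random.Generator,
                              flank: int = 200) -> list[TranscriptAlignment]:
    """Exon chains of long reads over a transcript with a known unit count.

    The underlying transcript consists of a 5' flank exon, the first
    ``true_unit_count`` annotated units, and a 3' flank exon.  With
    probability ``truncation_rate`` a read loses a uniform-random prefix or
    suffix (in transcript coordinates) and the corresponding mappable-end
    flag is cleared.
    """
    if not 1 <= true_unit_count <= len(annotation.units):
        raise ValueError("true_unit_count outside the annotated array")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    units = annotation.units[:true_unit_count]
    five = (max(0, units[0][0] - flank), units[0][0])
    three = (units[-1][1], units[-1][1] + flank)
    model = [five] + list(units) + [three]
    total = sum(e - s for s, e in model)

    reads = []
    for r in range(n_reads):
        five_ok = three_ok = True
        lo, hi = 0, total          # retained transcript-coordinate interval
        if truncation_rate > 0 and rng.random() < truncation_rate:
            cut = float(rng.uniform(0, total))
            if rng.random() < 0.5:
                lo, five_ok = cut, False
            else:
                hi, three_ok = total - cut, False
        exons = _transcript_slice(model, lo, hi)
        if not exons:
            exons, five_ok, three_ok = [], False, False
        reads.append(TranscriptAlignment(
            transcript_id=f"read{r}", contig=annotation.contig, exons=exons,
            five_prime_mappable=five_ok, three_prime_mappable=three_ok))
    return reads


def _transcript_slice(model: list[tuple[int, int]], lo: float, hi: float
                      ) -> list[tuple[int, int]]:
    """Genomic exon intervals of the transcript-coordinate window [lo, hi)."""
    out = []
    offset = 0.0
    for s, e in model:
        length = e - s
        a = max(lo - offset, 0.0)
        b = min(hi - offset, float(length))
        if b - a > 0:
            gs = s + int(np.ceil(a))
            ge = s + int(np.floor(b)) if b < length else e
            if ge > gs:
                out.append((gs, ge))
        offset += length
    return out
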