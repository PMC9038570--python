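"""Windowed Tajima's D scan and haplotype-clade partitioning.

This module computes the classic site-frequency-spectrum summary statistics
(segregating sites S, mean pairwise diversity pi, Watterson's theta) from a
matrix of phased biallelic haplotypes, runs a non-overlapping window scan,
z-normalizes a focal window against the genome-wide distribution of window
D values, and splits the haplotypes of a focal region into the two deeply
diverged clades that carry a balancing-selection footprint.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

#: 16 kb region at the 5' end of DMBT1 (GRCh38) where the balancing-selection
#: footprint sits.  1-based inclusive coordinates, VCF convention.  Checking
#: the published CEU Tajima's D of 2.67 over this region requires external
#: genotype data and is an optional, non-hermetic verification.
FOCAL_REGION = ("chr10", 122555466, 122571966)
#: 10 kb scan window inside the focal region that is z-normalized against the
#: genome-wide window distribution.
FOCAL_WINDOW = ("chr10", 122560000, 122570000)


class NoStructureError(ValueError):
    """All haplotypes identical; no bipartition exists."""


class DegenerateDistributionError(ValueError):
    """Genome-wide D distribution has zero spread; z undefined."""


@dataclass
class HaplotypeMatrix:
    """Phased biallelic sites by haplotypes.

    Parameters
    ----------
    chrom : contig name.
    positions : 1-based site coordinates (VCF convention), strictly increasing.
    alleles : (H, L) matrix of 0/1, one row per haplotype.
    haplotype_ids : sample id plus phase index, e.g. ``"NA12878|0"``.
    meta : free-form provenance (e.g. skipped-record counters from VCF I/O).
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    haplotype_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x site matrix")
        if self.alleles.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions and allele columns disagree")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if not self.haplotype_ids:
            self.haplotype_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def segregating_mask(self) -> np.ndarray:
        """Boolean mask of polymorphic columns (monomorphic sites flagged off)."""
        counts = self.alleles.sum(axis=0)
        return (counts > 0) & (counts < self.n_hap)

    def slice_window(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sub-matrix of sites falling in the 0-based half-open [start, end)."""
        zero_based = self.positions - 1
        keep = (zero_based >= start) & (zero_based < end)
        return HaplotypeMatrix(
            self.chrom, self.positions[keep], self.alleles[:, keep],
            list(self.haplotype_ids),
        )


@dataclass
class WindowStat:
    """Summary statistics of one scan window."""

    chrom: str
    start: int          # 0-based half-open bounds
    end: int
    S: int              # segregating sites
    pi: float           # mean pairwise differences
    theta_w: float      # S / a1
    D: float            # Tajima's D; NaN when undefined (S == 0)
    n_hap: int

    @property
    def d_defined(self) -> bool:
        return not math.isnan(self.D)


@dataclass
class ZScan:
    """A focal window normalized against the genome-wide D distribution."""

    target: WindowStat
    genome_mean: float
    genome_sd: float
    z: float
    n_windows_used: int
    excluded: bool = False
    reason: str = ""


@dataclass
class CladePartition:
    """Bipartition of haplotypes into the two divergent clades."""

    assignment: np.ndarray          # 0/1 per haplotype
    between_divergence: float       # mean pairwise differences across clades
    within_divergence: float        # mean pairwise differences within clades
    concordant_sites: np.ndarray    # indices of sites perfectly separating clades

    def members(self, clade: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == clade)


@dataclass
class TagSnp:
    """Site chosen as a proxy for clade membership."""

    site_index: int
    position: int
    concordance: float
    allele_to_clade: Mapping[int, int]
    reliable: bool = True


def tajima_constants(n: int) -> dict[str, float]:
    """Normalizing constants of Tajima's D for sample size ``n`` haplotypes.

    a1 = sum 1/i, a2 = sum 1/i^2 (i = 1..n-1); b1, b2, c1, c2, e1, e2 follow
    the standard variance estimate of pi - S/a1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(hapmat: HaplotypeMatrix,
              start: int | None = None,
              end: int | None = None) -> WindowStat:
    """Compute S, pi, Watterson's theta and Tajima's D for one matrix.

    Monomorphic columns are ignored.  D is NaN (undefined) when S = 0.  pi is
    the mean number of pairwise differences, computed per site as
    2 j (n - j) / (n (n - 1)) with j the derived-allele count.
    """
    n = hapmat.n_hap
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if start is None:
        start = int(hapmat.positions[0] - 1) if hapmat.n_sites else 0
    if end is None:
        end = int(hapmat.positions[-1]) if hapmat.n_sites else 0

    seg = hapmat.segregating_mask()
    S = int(seg.sum())
    if S == 0:
        return WindowStat(hapmat.chrom, start, end, 0, 0.0, 0.0, float("nan"), n)

    j = hapmat.alleles[:, seg].sum(axis=0).astype(float)
    pi = float(np.sum(2.0 * j * (n - j) / (n * (n - 1))))
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi - theta_w) / math.sqrt(var) if var > 0 else float("nan")
    return WindowStat(hapmat.chrom, start, end, S, pi, theta_w, D, n)


def window_scan(hapmat: HaplotypeMatrix, window_bp: int = 10_000) -> list[WindowStat]:
    """Non-overlapping window scan; one WindowStat per window holding >= 1 site.

    Windows tile [0, contig length) as half-open [k*w, (k+1)*w); a 1-based VCF
    position p falls in window floor((p-1)/w).  Windows without sites are
    omitted from the result.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if hapmat.n_sites == 0:
        return []
    widx = (hapmat.positions - 1) // window_bp
    out: list[WindowStat] = []
    for w in np.unique(widx):
        sub = hapmat.alleles[:, widx == w]
        pos = hapmat.positions[widx == w]
        sm = HaplotypeMatrix(hapmat.chrom, pos, sub, list(hapmat.haplotype_ids))
        out.append(tajimas_d(sm, start=int(w) * window_bp,
                             end=(int(w) + 1) * window_bp))
    return out


def znormalize(target: WindowStat,
               genome: Sequence[WindowStat],
               min_variable_sites: int = 3) -> ZScan:
    """z-score of a focal window's D against the genome-wide D distribution.

    The null moments use windows with defined D and S >= ``min_variable_sites``
    (sample standard deviation, n-1 denominator).  A target with fewer than
    ``min_variable_sites`` variable sites is excluded rather than scored,
    mirroring the exclusion rule used for sparse populations.
    """
    usable = [w.D for w in genome
              if w.d_defined and w.S >= min_variable_sites]
    if len(usable) < 2:
        raise ValueError("need >= 2 usable genome windows with defined D")
    mean = float(np.mean(usable))
    sd = float(np.std(usable, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("genome-wide D distribution has sd 0")
    if target.S < min_variable_sites:
        return ZScan(target, mean, sd, float("nan"), len(usable),
                     excluded=True,
                     reason=f"fewer than {min_variable_sites} variable sites")
    if not target.d_defined:
        return ZScan(target, mean, sd, float("nan"), len(usable),
                     excluded=True, reason="Tajima's D undefined (S = 0)")
    return ZScan(target, mean, sd, (target.D - mean) / sd, len(usable))


def _pair_divergences(alleles: np.ndarray, assignment: np.ndarray) -> tuple[float, float]:
    n = alleles.shape[0]
    between, within = [], []
    A = alleles.astype(np.int16)
    for i, j in combinations(range(n), 2):
        d = int(np.sum(A[i] != A[j]))
        (within if assignment[i] == assignment[j] else between).append(d)
    b = float(np.mean(between)) if between else float("nan")
    w = float(np.mean(within)) if within else 0.0
    return b, w


def _concordant_sites(alleles: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    """Sites whose alleles perfectly separate the two clades."""
    g0 = alleles[assignment == 0]
    g1 = alleles[assignment == 1]
    fixed0 = (g0 == g0[0]).all(axis=0)
    fixed1 = (g1 == g1[0]).all(axis=0)
    differs = g0[0] != g1[0]
    return np.flatnonzero(fixed0 & fixed1 & differs)


def partition_clades(hapmat: HaplotypeMatrix) -> CladePartition:
    """Split haplotypes into two clades by complete-linkage clustering.

    Agglomeration on pairwise Hamming distance, cut into exactly two groups.
    Labels are normalized so the clade containing the lowest-index haplotype
    is clade 0, making the output deterministic up to clade relabeling.
    """
    if hapmat.n_hap < 4:
        raise ValueError("need at least 4 haplotypes to partition")
    seg = hapmat.segregating_mask()
    if not seg.any():
        raise NoStructureError("no segregating sites; all haplotypes identical")
    X = hapmat.alleles[:, seg].astype(float)
    if np.all(pdist(X, metric="hamming") == 0):
        raise NoStructureError("all haplotypes identical at segregating sites")
    Z = linkage(pdist(X, metric="hamming"), method="complete")
    labels = fcluster(Z, t=2, criterion="maxclust") - 1
    if labels[0] != 0:
        labels = 1 - labels
    if len(np.unique(labels)) < 2:
        raise NoStructureError("clustering produced a single clade")
    between, within = _pair_divergences(hapmat.alleles[:, seg], labels)
    conc_local = _concordant_sites(hapmat.alleles[:, seg], labels)
    conc = np.flatnonzero(seg)[conc_local]
    return CladePartition(np.asarray(labels), between, within, conc)


def select_tag_snp(partition: CladePartition, hapmat: HaplotypeMatrix) -> TagSnp:
    """Pick the site whose alleles best proxy clade membership.

    Concordance of a site is the fraction of haplotypes whose allele equals
    the majority allele of their own clade at that site.  Ties break to the
    leftmost position.  A best concordance <= 0.5 is flagged unreliable.
    """
    labels = partition.assignment
    A = hapmat.alleles
    best_idx, best_conc = -1, -1.0
    for s in range(hapmat.n_sites):
        col = A[:, s]
        conc = 0
        maj = {}
        for c in (0, 1):
            vals = col[labels == c]
            ones = int(vals.sum())
            maj_allele = 1 if ones * 2 >= vals.size else 0
            # strict majority tie (equal counts) resolves to allele 1; the
            # concordance count below is unaffected by which way ties break
            maj[c] = maj_allele
            conc += int(np.sum(vals == maj_allele))
        frac = conc / hapmat.n_hap
        if frac > best_conc + 1e-12:
            best_idx, best_conc, best_map = s, frac, dict(maj)
    if best_idx < 0:
        raise ValueError("matrix has no sites")
    allele_to_clade = {allele: clade for clade, allele in best_map.items()}
    return TagSnp(best_idx, int(hapmat.positions[best_idx]), best_conc,
                  allele_to_clade, reliable=best_conc > 0.5)


def read_phased_vcf(path: str,
                    region: str | None = None,
                    samples: Sequence[str] | None = None) -> HaplotypeMatrix:
    """Load phased biallelic SNPs from a VCF into a HaplotypeMatrix.

    Multiallelic, non-SNP, unphased and incomplete records are skipped; the
    counts land in ``meta`` (``n_skipped_unphased``, ``n_skipped_multiallelic``,
    ``n_skipped_nonsnp``).  Two haplotypes per sample, in sample order, named
    ``sample|0`` / ``sample|1``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    available = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in available]
        if missing:
            raise ValueError(f"samples absent from VCF: {missing}")
        vcf = VCF(path, samples=list(samples))
    used = list(vcf.samples)

    positions, columns = [], []
    skipped = {"n_skipped_unphased": 0, "n_skipped_multiallelic": 0,
               "n_skipped_nonsnp": 0}
    chrom = None
    manual_region = None
    iterator = vcf
    if region:
        import itertools as _it
        try:
            indexed = vcf(region)
            first = next(indexed, None)
            iterator = _it.chain([first], indexed) if first is not None else iter(())
        except Exception:
            # plain VCF without a tabix index: stream and filter instead
            vcf = VCF(path, samples=list(samples)) if samples else VCF(path)
            iterator = vcf
            rchrom, _, span = region.partition(":")
            lo, _, hi = span.partition("-")
            manual_region = (rchrom, int(lo) if lo else 1,
                             int(hi) if hi else 2**62)
    for rec in iterator:
        if manual_region is not None:
            mc, lo, hi = manual_region
            if rec.CHROM != mc or not lo <= rec.POS <= hi:
                continue
        if len(rec.ALT) != 1:
            skipped["n_skipped_multiallelic"] += 1
            continue
        if not rec.is_snp:
            skipped["n_skipped_nonsnp"] += 1
            continue
        gts = rec.genotypes  # [allele0, allele1, phased] per sample
        if any((len(g) < 3) or (not g[2]) or g[0] < 0 or g[1] < 0 for g in gts):
            skipped["n_skipped_unphased"] += 1
            continue
        chrom = rec.CHROM
        positions.append(rec.POS)
        col = np.empty(2 * len(gts), dtype=np.uint8)
        for i, g in enumerate(gts):
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        columns.append(col)
    if not columns:
        raise ValueError(f"no phased biallelic SNPs in {path} region={region!r}")
    alleles = np.column_stack(columns)
    ids = [f"{s}|{k}" for s in used for k in (0, 1)]
    order = np.argsort(positions, kind="stable")
    mat = HaplotypeMatrix(chrom, np.asarray(positions)[order],
                          alleles[:, order], ids, meta=skipped)
    log.info("read %d sites from %s (skipped: %s)", mat.n_sites, path, skipped)
    return mat
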