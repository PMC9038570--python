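"""Integer copy-number calling and multiallelic CNV-to-haplotype phasing.

Only diploid repeat totals are directly measurable (paralogue ratio tests
report a continuous ratio that calibrates linearly to copy number); the
underlying per-haplotype repeat alleles are recovered either

* by constraint propagation through pedigrees — each individual starts with
  every (paternal, maternal) allele pair summing to its total, and Mendelian
  transmission prunes the candidate sets to a fixpoint, refined by exhaustive
  enumeration in small families — or
* by an EM algorithm over population allele frequencies using
  parent-offspring trios: alleles i.i.d. from an unknown frequency vector
  under random mating, transmissions equiprobable, the E-step scoring every
  trio configuration consistent with the three observed totals.

Resolved alleles attach to the phased tag-SNP allele carried by the same
parental haplotype, yielding the per-haplotype (tag allele, repeat allele)
records that the clade association tests consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Calibration line unusable (non-positive slope or too few points)."""


@dataclass(frozen=True)
class AlleleRange:
    """Inclusive bounds of per-haplotype repeat alleles (7..21 by default)."""

    kmin: int = 7
    kmax: int = 21

    def __post_init__(self) -> None:
        if self.kmin < 1 or self.kmax < self.kmin:
            raise ValueError("need 1 <= kmin <= kmax")

    def __contains__(self, k: int) -> bool:
        return self.kmin <= k <= self.kmax


@dataclass
class CNVObservation:
    individual: str
    diploid_total: int
    continuous_estimate: float | None = None
    per_assay: dict[str, float] = field(default_factory=dict)
    quality_flag: bool = False

    def in_range(self, rng: AlleleRange) -> bool:
        return 2 * rng.kmin <= self.diploid_total <= 2 * rng.kmax


@dataclass
class HaplotypeAlleleAssignment:
    """Per-haplotype repeat-allele call with phase provenance."""

    individual: str
    origin: str                      # "pat" | "mat"
    alleles: tuple[int, ...]         # candidate set, sorted
    status: str                      # unique | ambiguous | inconsistent
    method: str                      # pedigree | trio_em
    tag_allele: str | None = None
    posterior: float | None = None
    is_founder: bool = True

    @property
    def haplotype_id(self) -> str:
        return f"{self.individual}:{self.origin}"


@dataclass
class CNVAlleleFreqs:
    """Population repeat-allele frequency vector with its log-likelihood."""

    freqs: dict[int, float]
    n_haplotypes: int
    log_likelihood: float
    n_iter: int = 0


def call_integer_cn(ratios: Mapping[str, float],
                    calibration: Mapping[str, Sequence[tuple[float, int]]],
                    individual: str = "",
                    flag_threshold: float = 0.35) -> CNVObservation:
    """Convert per-assay PRT ratios to an integer diploid copy number.

    A least-squares line CN = a + b * ratio is fitted per assay on reference
    samples of known copy number; assay estimates are averaged (unweighted)
    before rounding.  Half-integers round away from zero.  The call is
    quality-flagged when the consensus sits more than ``flag_threshold`` from
    the nearest integer.
    """
    estimates = {}
    for assay, ratio in ratios.items():
        pts = calibration.get(assay)
        if pts is None or len(pts) < 2:
            raise CalibrationError(f"assay {assay!r}: need >= 2 calibration points")
        x = np.array([p[0] for p in pts], float)
        y = np.array([p[1] for p in pts], float)
        if np.unique(y).size < 2:
            raise CalibrationError(f"assay {assay!r}: calibration CNs not distinct")
        b, a = np.polyfit(x, y, 1)
        if b <= 0:
            raise CalibrationError(f"assay {assay!r}: non-positive slope {b:.3g}")
        estimates[assay] = a + b * ratio
    if not estimates:
        raise CalibrationError("no assay ratios supplied")
    consensus = float(np.mean(list(estimates.values())))
    rounded = int(math.floor(abs(consensus) + 0.5)) * (1 if consensus >= 0 else -1)
    return CNVObservation(
        individual=individual, diploid_total=rounded,
        continuous_estimate=consensus, per_assay=estimates,
        quality_flag=abs(consensus - rounded) > flag_threshold)


def enumerate_allele_pairs(total: int, rng: AlleleRange) -> list[tuple[int, int]]:
    """All unordered {a, b} with kmin <= a <= b <= kmax and a + b = total."""
    return [(a, total - a)
            for a in range(rng.kmin, total // 2 + 1)
            if rng.kmin <= total - a <= rng.kmax and a <= total - a]


# --------------------------------------------------------------------------
# Pedigree constraint propagation
# --------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Family structure: individual ids with father/mother ids ('0' = absent)."""

    members: pd.DataFrame    # columns family, individual, father, mother, sex

    def __post_init__(self) -> None:
        df = self.members
        ids = set(df["individual"])
        if len(ids) != len(df):
            raise ValueError("duplicate individual ids")
        for col in ("father", "mother"):
            bad = [p for p in df[col] if p != "0" and p not in ids]
            if bad:
                raise ValueError(f"referenced {col}s missing from pedigree: {bad}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {r.individual: (r.father, r.mother)
                   for r in self.members.itertuples()}
        state: dict[str, int] = {}

        def visit(ind: str) -> None:
            if state.get(ind) == 1:
                raise ValueError(f"pedigree cycle at {ind}")
            if state.get(ind) == 2:
                return
            state[ind] = 1
            for p in parents.get(ind, ("0", "0")):
                if p != "0":
                    visit(p)
            state[ind] = 2

        for ind in parents:
            visit(ind)

    def families(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.members.groupby("family", sort=True)

    def topological(self, fam_df: pd.DataFrame) -> list[str]:
        """Members ordered founders-first within one family."""
        parents = {r.individual: (r.father, r.mother)
                   for r in fam_df.itertuples()}
        out, seen = [], set()

        def visit(ind: str) -> None:
            if ind in seen or ind not in parents:
                return
            seen.add(ind)
            for p in parents[ind]:
                if p != "0":
                    visit(p)
            out.append(ind)

        for ind in parents:
            visit(ind)
        return out

    def is_founder(self, ind: str) -> bool:
        row = self.members[self.members["individual"] == ind].iloc[0]
        return row["father"] == "0" and row["mother"] == "0"


@dataclass
class FamilyReport:
    family: str
    consistent: bool
    offending_individual: str | None = None


def _ordered_pairs(total: int, rng: AlleleRange) -> set[tuple[int, int]]:
    pairs = set()
    for a, b in enumerate_allele_pairs(total, rng):
        pairs.add((a, b))
        pairs.add((b, a))
    return pairs


def _alleles_of(pairs: set[tuple[int, int]]) -> set[int]:
    return {a for p in pairs for a in p}


def _allowed_slots(child: str, side: int, parent: str,
                   tags: Mapping[str, Mapping[str, str]],
                   trans: Mapping[str, Mapping[str, str]]) -> tuple[int, ...]:
    """Parent haplotype slots the child's haplotype can descend from.

    A known transmission record (from region-scale SNP phase) pins the slot
    outright.  Failing that, when both the child's transmitted tag allele
    and the parent's tag phase are known, a tag-heterozygous parent pins the
    transmission; otherwise both slots remain possible.  Returns () on a
    tag-level Mendelian contradiction.
    """
    origin = "pat" if side == 0 else "mat"
    source = trans.get(child, {}).get(f"{origin}_source")
    if source in ("pat", "mat"):
        return (0,) if source == "pat" else (1,)
    child_tag = tags.get(child, {}).get(origin)
    ptags = tags.get(parent)
    if child_tag is None or ptags is None:
        return (0, 1)
    slots = tuple(s for s, o in ((0, "pat"), (1, "mat"))
                  if ptags.get(o) == child_tag)
    return slots


def _propagate(cands: dict[str, set[tuple[int, int]]],
               parents: dict[str, tuple[str, str]],
               allowed: Mapping[tuple[str, int], tuple[int, ...]]) -> None:
    """Arc-consistency over transmission constraints, to fixpoint."""
    changed = True
    while changed:
        changed = False
        for ind, (fa, mo) in parents.items():
            for side, parent in ((0, fa), (1, mo)):
                if parent == "0" or parent not in cands:
                    continue
                slots = allowed[(ind, side)]
                avail = {pp[s] for pp in cands[parent] for s in slots}
                keep = {p for p in cands[ind] if p[side] in avail}
                if keep != cands[ind]:
                    cands[ind] = keep
                    changed = True
                # parent pair must be able to serve every child
                child_alleles = {p[side] for p in cands[ind]}
                keep_par = {pp for pp in cands[parent]
                            if any(pp[s] in child_alleles for s in slots)}
                if keep_par != cands[parent]:
                    cands[parent] = keep_par
                    changed = True


def _exhaustive_refine(cands: dict[str, set[tuple[int, int]]],
                       parents: dict[str, tuple[str, str]],
                       order: list[str],
                       allowed: Mapping[tuple[str, int], tuple[int, ...]],
                       ) -> dict[str, set[tuple[int, int]]]:
    """Candidate pairs surviving in at least one globally consistent assignment.

    Depth-first search over joint assignments in founders-first order; the
    transmission constraint (a child's haplotype allele must sit on a
    tag-compatible haplotype of the corresponding parent) is checked
    incrementally.
    """
    surviving: dict[str, set[tuple[int, int]]] = {i: set() for i in order}
    assign: dict[str, tuple[int, int]] = {}

    def compatible(child: str, side: int, child_pair: tuple[int, int],
                   parent_pair: tuple[int, int]) -> bool:
        return any(parent_pair[s] == child_pair[side]
                   for s in allowed[(child, side)])

    def feasible(ind: str, pair: tuple[int, int]) -> bool:
        fa, mo = parents[ind]
        for side, parent in ((0, fa), (1, mo)):
            if parent in assign and not compatible(ind, side, pair, assign[parent]):
                return False
        for child, (cfa, cmo) in parents.items():
            if child not in assign:
                continue
            if cfa == ind and not compatible(child, 0, assign[child], pair):
                return False
            if cmo == ind and not compatible(child, 1, assign[child], pair):
                return False
        return True

    def dfs(i: int) -> None:
        if i == len(order):
            for ind, pair in assign.items():
                surviving[ind].add(pair)
            return
        ind = order[i]
        for pair in sorted(cands[ind]):
            if feasible(ind, pair):
                assign[ind] = pair
                dfs(i + 1)
                del assign[ind]

    dfs(0)
    return surviving


def pedigree_phase(ped: Pedigree,
                   observations: Mapping[str, int] | pd.DataFrame,
                   tag_phase: pd.DataFrame | None = None,
                   transmissions: pd.DataFrame | None = None,
                   allele_range: AlleleRange = AlleleRange(),
                   exhaustive_limit: int = 14,
                   ) -> tuple[list[HaplotypeAlleleAssignment], list[FamilyReport]]:
    """Phase diploid repeat totals onto haplotypes by pedigree segregation.

    Every individual starts with all ordered (paternal, maternal) allele
    pairs summing to its observed total; transmission constraints prune the
    sets to a fixpoint, and families of at most ``exhaustive_limit`` members
    are refined by exhaustive enumeration of joint assignments.  Haplotypes
    whose candidate set remains larger than one are ``ambiguous``; an empty
    set anywhere marks the family ``inconsistent`` with the offending
    individual named in the report (no exception raised).

    ``tag_phase`` (columns individual, pat, mat) supplies the phased tag-SNP
    allele of each parental haplotype.  Besides being copied onto resolved
    records, it sharpens the transmission constraints: a tag-heterozygous
    parent's transmitted haplotype is identified by the tag allele the child
    received.  ``transmissions`` (columns individual, pat_source, mat_source,
    values "pat"/"mat") identifies outright which parental haplotype each
    non-founder haplotype descends from — the information carried by phased
    SNP haplotypes over the surrounding region — and makes the propagation
    far more decisive.  For a founder whose two haplotypes carry the same tag allele
    the paternal/maternal labels are observationally exchangeable; when such
    a founder's allele multiset is uniquely resolved, the pair is reported in
    canonical (sorted) slot order and both haplotypes count as unique.
    """
    if isinstance(observations, pd.DataFrame):
        observations = dict(zip(observations["individual"],
                                observations["diploid_total"]))
    tags: dict[str, dict[str, str]] = {}
    if tag_phase is not None:
        for r in tag_phase.itertuples():
            tags[r.individual] = {"pat": r.pat, "mat": r.mat}
    trans: dict[str, dict[str, str]] = {}
    if transmissions is not None:
        for r in transmissions.itertuples():
            trans[r.individual] = {"pat_source": r.pat_source,
                                   "mat_source": r.mat_source}

    assignments: list[HaplotypeAlleleAssignment] = []
    reports: list[FamilyReport] = []
    for fam, fam_df in ped.families():
        parents = {r.individual: (r.father, r.mother)
                   for r in fam_df.itertuples()}
        missing = [i for i in parents if i not in observations]
        if missing:
            raise ValueError(f"family {fam}: no CN observation for {missing}")
        cands = {i: _ordered_pairs(int(observations[i]), allele_range)
                 for i in parents}
        allowed = {(ind, side): _allowed_slots(ind, side, parent, tags, trans)
                   for ind, (fa, mo) in parents.items()
                   for side, parent in ((0, fa), (1, mo)) if parent != "0"}
        offender = next((ind for (ind, _), slots in allowed.items()
                         if not slots), None)
        if offender is None:
            _propagate(cands, parents, allowed)
            offender = next((i for i in ped.topological(fam_df)
                             if not cands[i]), None)
        if offender is None and len(parents) <= exhaustive_limit:
            cands = _exhaustive_refine(cands, parents, ped.topological(fam_df),
                                       allowed)
            offender = next((i for i in ped.topological(fam_df)
                             if not cands[i]), None)
        consistent = offender is None
        # canonicalize founders whose haplotypes are tag-exchangeable and
        # whose allele multiset is fully resolved
        for ind in parents:
            if parents[ind] != ("0", "0") or not cands.get(ind):
                continue
            t = tags.get(ind)
            if t is not None and t.get("pat") != t.get("mat"):
                continue
            multisets = {tuple(sorted(pair)) for pair in cands[ind]}
            if len(multisets) == 1:
                cands[ind] = {next(iter(multisets))}
        reports.append(FamilyReport(fam, consistent, offender))
        for ind in ped.topological(fam_df):
            founder = parents[ind] == ("0", "0")
            for side, origin in ((0, "pat"), (1, "mat")):
                values = tuple(sorted({p[side] for p in cands[ind]}))
                if not consistent:
                    status = "inconsistent"
                elif len(values) == 1:
                    status = "unique"
                else:
                    status = "ambiguous"
                assignments.append(HaplotypeAlleleAssignment(
                    individual=ind, origin=origin, alleles=values,
                    status=status, method="pedigree",
                    tag_allele=tags.get(ind, {}).get(origin),
                    is_founder=founder))
    n_bad = sum(not r.consistent for r in reports)
    if n_bad:
        log.warning("%d/%d families Mendelian-inconsistent", n_bad, len(reports))
    return assignments, reports


# --------------------------------------------------------------------------
# Trio EM over population allele frequencies
# --------------------------------------------------------------------------

@dataclass
class TrioConfiguration:
    father: tuple[int, int]
    mother: tuple[int, int]
    child: tuple[int, int]     # (paternal, maternal) transmitted alleles


@dataclass
class TrioMAP:
    index: int
    configuration: TrioConfiguration | None
    posterior: float
    ambiguous: bool = False
    inconsistent: bool = False


def _trio_configs(f_total: int, m_total: int, c_total: int,
                  rng: AlleleRange) -> list[TrioConfiguration]:
    out = []
    for fp in enumerate_allele_pairs(f_total, rng):
        for mp in enumerate_allele_pairs(m_total, rng):
            for x in sorted(set(fp)):
                y = c_total - x
                if y in set(mp) and y in rng:
                    out.append(TrioConfiguration(fp, mp, (x, y)))
    return out


def _config_weight(cfg: TrioConfiguration, p: dict[int, float]) -> float:
    a, b = cfg.father
    c, d = cfg.mother
    g_f = (2 if a != b else 1) * p.get(a, 0.0) * p.get(b, 0.0)
    g_m = (2 if c != d else 1) * p.get(c, 0.0) * p.get(d, 0.0)
    t_f = 1.0 if a == b else 0.5
    t_m = 1.0 if c == d else 0.5
    return g_f * g_m * t_f * t_m


def _em_run(configs: list[list[TrioConfiguration]], usable: list[int],
            support: list[int], p: dict[int, float], tol: float,
            max_iter: int) -> tuple[dict[int, float], float, int]:
    """One EM ascent from a given starting frequency vector."""
    prev_ll = -math.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        counts = {k: 0.0 for k in support}
        ll = 0.0
        for i in usable:
            weights = np.array([_config_weight(c, p) for c in configs[i]])
            tot = float(weights.sum())
            if tot <= 0:
                continue
            ll += math.log(tot)
            post = weights / tot
            for c, w in zip(configs[i], post):
                for allele in (*c.father, *c.mother):
                    counts[allele] += w
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        total_counts = sum(counts.values())
        p = {k: v / total_counts for k, v in counts.items()}
        if ll - prev_ll < tol and n_iter > 1:
            prev_ll = ll
            break
        prev_ll = ll
    return p, prev_ll, n_iter


def trio_em(trios: Sequence[tuple[int, int, int]],
            allele_range: AlleleRange = AlleleRange(),
            tol: float = 1e-8,
            max_iter: int = 1000,
            n_restarts: int = 8,
            seed: int = 0,
            ) -> tuple[CNVAlleleFreqs, list[TrioMAP]]:
    """EM estimate of repeat-allele frequencies from trio diploid totals.

    Model: founder alleles i.i.d. from frequency vector p (random mating);
    each parent transmits one of its two alleles with probability 1/2; a trio
    configuration must reproduce all three observed totals.  The E-step
    computes the posterior over configurations per trio, the M-step
    re-estimates p from expected founder-allele counts (four per trio).  The
    log-likelihood is non-decreasing every iteration (asserted).  Trios with
    no consistent configuration are flagged and excluded from the likelihood.

    The uniform starting vector is a symmetric point at which every trio
    configuration carries equal weight, so the ascent runs from
    ``n_restarts`` seeded Dirichlet(1) starting vectors and keeps the fit
    with the best final log-likelihood (deterministic given ``seed``).

    Returns the frequency estimate and the per-trio MAP configuration (ties
    broken to the lexicographically smallest configuration and flagged).
    """
    if not trios:
        raise ValueError("need at least one trio")
    configs = [_trio_configs(*t, allele_range) for t in trios]
    usable = [i for i, c in enumerate(configs) if c]
    for i, c in enumerate(configs):
        if not c:
            log.warning("trio %d (totals %s) has no consistent configuration; "
                        "excluded", i, trios[i])
    if not usable:
        raise ValueError("no trio admits a consistent configuration")

    support = sorted({a for i in usable for cfg in configs[i]
                      for a in (*cfg.father, *cfg.mother)})
    rng = np.random.default_rng(seed)
    best: tuple[dict[int, float], float, int] | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            start = {k: 1.0 / len(support) for k in support}
        else:
            draw = rng.dirichlet(np.ones(len(support)))
            start = {k: float(v) for k, v in zip(support, draw)}
        p_r, ll_r, it_r = _em_run(configs, usable, support, start, tol, max_iter)
        if best is None or ll_r > best[1] + 1e-12:
            best = (p_r, ll_r, it_r)
    p, prev_ll, n_iter = best

    maps: list[TrioMAP] = []
    for i, cfgs in enumerate(configs):
        if not cfgs:
            maps.append(TrioMAP(i, None, 0.0, inconsistent=True))
            continue
        weights = np.array([_config_weight(c, p) for c in cfgs])
        tot = float(weights.sum())
        post = weights / tot if tot > 0 else np.full(len(cfgs), 1.0 / len(cfgs))
        best = float(post.max())
        tied = [c for c, w in zip(cfgs, post) if w >= best - 1e-12]
        tied.sort(key=lambda c: (c.father, c.mother, c.child))
        maps.append(TrioMAP(i, tied[0], best, ambiguous=len(tied) > 1))

    freqs = CNVAlleleFreqs(freqs=dict(sorted(p.items())),
                           n_haplotypes=4 * len(usable),
                           log_likelihood=prev_ll, n_iter=n_iter)
    return freqs, maps


def attach_to_haplotypes(assignments: Sequence[HaplotypeAlleleAssignment],
                         founders_only: bool = True) -> pd.DataFrame:
    """Per-haplotype (tag allele, repeat allele) records for association tests.

    Only uniquely resolved haplotypes with a known tag allele contribute;
    non-founders are excluded by default so population-level allele spectra
    are not double-counted through transmission.  Exclusion counts are logged.
    """
    rows, n_excluded = [], {"ambiguous": 0, "inconsistent": 0,
                            "no_tag": 0, "non_founder": 0}
    for a in assignments:
        if founders_only and not a.is_founder:
            n_excluded["non_founder"] += 1
            continue
        if a.status != "unique":
            n_excluded[a.status if a.status in n_excluded else "ambiguous"] += 1
            continue
        if a.tag_allele is None:
            n_excluded["no_tag"] += 1
            continue
        rows.append((a.haplotype_id, a.tag_allele, a.alleles[0]))
    log.info("attached %d haplotype records (excluded: %s)", len(rows), n_excluded)
    df = pd.DataFrame(rows, columns=["haplotype", "tag_allele", "allele"])
    df.attrs["n_excluded"] = n_excluded
    return df
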