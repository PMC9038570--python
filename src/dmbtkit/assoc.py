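"""Association tests linking clades, repeat copy number, protein size and expression.

Three questions, three tools:

* do the repeat-allele distributions differ between the two tag-SNP clades?
  — Wilcoxon rank-sum test with mid-ranks, tie-corrected variance and a 0.5
  continuity correction (an exact permutation mode is available for small n);
* does diploid repeat copy number predict salivary protein isoform size?
  — ordinary least squares of band size (kDa) on copy number, optionally with
  a secretor-status indicator, plus Kendall's rank correlation;
* does tag-SNP dosage predict normalized expression?
  — one-way ANOVA across genotype classes and a two-tailed F-test of the
  linear dosage term.

Secretor (Se) status is inferred from the FUT2 null variant: homozygous null
individuals are Se-.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: size-class band assignments (kDa) of the salivary protein isoforms; class
#: IV runs as a double band.
ISOFORM_BANDS = {"I": (345.0,), "II": (375.0,), "III": (389.0,),
                 "IV": (287.0, 345.0)}
#: rank order of the classes by electrophoretic size (smallest first).
ISOFORM_SIZE_RANK = {"IV": 1, "I": 2, "II": 3, "III": 4}


@dataclass
class RankTestResult:
    """Wilcoxon rank-sum result on the two clade allele distributions."""

    W: float                 # rank-sum statistic of the first group (U form)
    z: float                 # normal deviate with continuity correction
    p: float                 # two-sided
    n_a: int
    n_c: int
    method: str = "normal"


@dataclass
class LinearFit:
    intercept: float
    slopes: dict[str, float]
    r_squared: float
    overall_p: float
    coef_p: dict[str, float]
    kendall_tau: float
    kendall_p: float
    n: int


@dataclass
class TrendTestResult:
    anova_p: float
    trend_p: float
    slope: float

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))


def rank_sum_test(group_a: Sequence[float], group_c: Sequence[float],
                  method: str = "normal") -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test between the two clades' alleles.

    ``method='normal'`` uses mid-ranks, the tie-corrected variance and a 0.5
    continuity correction — the large-sample form appropriate at the cohort
    scale of a few hundred haplotypes.  ``method='exact'`` enumerates all
    group relabelings (total n <= 20 only) and needs no normal approximation.
    Swapping the groups negates z and preserves p.
    """
    a = np.asarray(group_a, float)
    c = np.asarray(group_c, float)
    if a.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, c.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, c]))
    w_rank = float(ranks[:n1].sum())
    U = w_rank - n1 * (n1 + 1) / 2.0        # Mann-Whitney U of the first group

    if method == "exact":
        if n > 20:
            raise ValueError("exact mode supported for total n <= 20 only")
        observed = w_rank
        mu = n1 * (n + 1) / 2.0
        count = total = 0
        for idx in itertools.combinations(range(n), n1):
            s = float(ranks[list(idx)].sum())
            total += 1
            if abs(s - mu) >= abs(observed - mu) - 1e-12:
                count += 1
        p = count / total
        z = float("nan")
        return RankTestResult(U, z, p, n1, n2, method="exact")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankTestResult(U, 0.0, 1.0, n1, n2)
    diff = U - mu
    correction = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - correction) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return RankTestResult(U, float(z), float(p), n1, n2)


def records_to_groups(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split phased haplotype records into A-clade and C-clade allele arrays."""
    a = records.loc[records["tag_allele"] == "A", "allele"].to_numpy(float)
    c = records.loc[records["tag_allele"] == "C", "allele"].to_numpy(float)
    return a, c


def _encode_bands(bands: Iterable[float], encoding: str) -> float:
    b = sorted(float(x) for x in bands)
    if encoding == "mean":
        return float(np.mean(b))
    if encoding == "upper":
        return b[-1]
    if encoding == "lower":
        return b[0]
    raise ValueError(f"unknown band encoding {encoding!r}")


def isoform_response(records: pd.DataFrame, encoding: str = "mean") -> np.ndarray:
    """Numeric response per sample from its isoform band sizes.

    Encodings: ``mean`` (average of the bands; the declared default
    convention), ``upper`` / ``lower`` (largest / smallest band), ``rank``
    (size order of the class, IV < I < II < III), ``size`` (a measured
    continuous ``size_kda`` column, for densitometry-style data).  Samples
    with a single band are identical under mean/upper/lower; only the
    double-band class IV differs.
    """
    if encoding == "size":
        return records["size_kda"].to_numpy(float)
    if encoding == "rank":
        return records["isoform"].map(ISOFORM_SIZE_RANK).to_numpy(float)
    out = []
    for _, row in records.iterrows():
        if "bands" in records.columns and isinstance(row["bands"], str):
            bands = [float(x) for x in row["bands"].split(",")]
        else:
            bands = list(ISOFORM_BANDS[row["isoform"]])
        out.append(_encode_bands(bands, encoding))
    return np.asarray(out, float)


def isoform_model(records: pd.DataFrame,
                  include_secretor: bool = False,
                  encoding: str = "mean") -> LinearFit:
    """OLS of protein size on diploid repeat copy number (plus secretor).

    ``records`` needs columns ``srcr_diploid_cn``, ``isoform`` (or ``bands``)
    and, when ``include_secretor``, ``secretor`` in {'+', '-'}.  Reports r²,
    the overall F-test p, per-coefficient t-test p values, and Kendall's tau
    of the response against copy number.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    y = isoform_response(records, encoding)
    cn = records["srcr_diploid_cn"].to_numpy(float)
    if np.unique(cn).size < 2:
        raise ValueError("copy-number predictor is constant")
    names = ["srcr_diploid_cn"]
    X = cn[:, None]
    if include_secretor:
        se = records["secretor"].astype(str)
        if (se == "unknown").any():
            raise ValueError("records with unknown secretor status")
        X = np.column_stack([cn, (se == "+").astype(float)])
        names.append("secretor")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    tau, tau_p = stats.kendalltau(cn, y)
    return LinearFit(
        intercept=float(fit.params[0]),
        slopes={nm: float(v) for nm, v in zip(names, fit.params[1:])},
        r_squared=float(fit.rsquared),
        overall_p=float(fit.f_pvalue),
        coef_p={nm: float(v) for nm, v in zip(names, fit.pvalues[1:])},
        kendall_tau=float(tau), kendall_p=float(tau_p), n=len(records))


def infer_secretor(genotype: Sequence[str] | str | None,
                   null_allele: str = "A") -> str:
    """Secretor status from the FUT2 null variant (recessive rule).

    Homozygous null -> 'Se-' ('-'); any functional allele -> '+'; missing
    genotype -> 'unknown'.  The variant is configurable; the default null
    allele is the A of the common European nonsense polymorphism (G>A).
    """
    if genotype is None:
        return "unknown"
    if isinstance(genotype, str):
        for sep in ("/", "|"):
            if sep in genotype:
                genotype = genotype.split(sep)
                break
        else:
            genotype = list(genotype)
    alleles = [str(g) for g in genotype]
    if len(alleles) != 2 or any(g in (".", "", "N") for g in alleles):
        return "unknown"
    return "-" if all(g == null_allele for g in alleles) else "+"


def dosage_trend_test(records: pd.DataFrame) -> TrendTestResult:
    """Expression vs genotype dosage: one-way ANOVA and a linear-trend F-test.

    ``records`` needs columns ``dosage`` (count of the focal allele, 0/1/2)
    and ``expression`` (target / reference concentration).  The trend p is a
    two-tailed F-test of the dosage slope in an OLS of expression on dosage.
    """
    dosage = records["dosage"].to_numpy(float)
    expr = records["expression"].to_numpy(float)
    classes = np.unique(dosage)
    if classes.size < 2:
        raise ValueError("trend undefined with a single genotype class")
    groups = [expr[dosage == d] for d in classes]
    anova = stats.f_oneway(*groups)
    fit = sm.OLS(expr, sm.add_constant(dosage)).fit()
    # t^2 of the slope is F(1, n-2); its two-sided p equals the F-test p
    return TrendTestResult(anova_p=float(anova.pvalue),
                           trend_p=float(fit.pvalues[1]),
                           slope=float(fit.params[1]))
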