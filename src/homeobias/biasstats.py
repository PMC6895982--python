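"""Statistics for homoeolog expression bias, qPCR quantification and heterosis.

Three independent pieces:

* an exact two-sided binomial test of subgenome expression bias — under the
  null each informative read comes from either homoeolog with probability
  p0 = 0.5, and the two-sided p-value sums P(X = k) over all outcomes no
  more likely than the observed one (the minimum-likelihood convention used
  by R's ``binom.test``);
* relative qPCR expression by the 2^−ΔΔCt method, normalising the target Ct
  to the arithmetic mean of the reference-gene Cts (equivalently, the
  geometric mean of the reference quantities 2^−Ct);
* mid-parent heterosis, MPH% = (polyploid mean − mid-parent mean) /
  mid-parent mean × 100, where the mid-parent mean averages the two
  parental genotype means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homeocount import AlleleCountTable

# R's binom.test treats probabilities within a 1e-7 relative band of the
# observed point probability as "equally likely"; kept for floating safety.
_REL_TOL = 1 + 1e-7


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Exact binomial bias test
# ---------------------------------------------------------------------------


def binom_exact_two_sided(h: int, c: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for counts (h, c), success = c.

    Sums P(X = k) over every k in 0..n whose point probability does not
    exceed that of the observed count, X ~ Binomial(n = h + c, p0).  No
    normal approximation is used.
    """
    if h < 0 or c < 0:
        raise InputError("counts must be non-negative")
    n = h + c
    if n == 0:
        raise InputError("binomial test undefined for zero total count")
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    p = float(pmf[pmf <= pmf[c] * _REL_TOL].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class BiasTestResult:
    """Outcome of the bias test for one (replicate, SNP) count pair."""

    replicate: str
    snp: str
    h_count: int
    c_count: int
    p0: float
    p_value: float
    direction: str  # "maternal" | "paternal" | "none"
    log2_ratio: float  # log2(c / h)
    p_adjusted: float | None = None


def bias_test(h: int, c: int, replicate: str = "", snp: str = "",
              p0: float = 0.5) -> BiasTestResult:
    p = binom_exact_two_sided(h, c, p0)
    if c > h:
        direction = "paternal"
    elif h > c:
        direction = "maternal"
    else:
        direction = "none"
    if h == 0 and c == 0:
        ratio = math.nan
    elif h == 0:
        ratio = math.inf
    elif c == 0:
        ratio = -math.inf
    else:
        ratio = math.log2(c / h)
    return BiasTestResult(replicate=replicate, snp=str(snp), h_count=h,
                          c_count=c, p0=p0, p_value=p, direction=direction,
                          log2_ratio=ratio)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adj[i] = running
    return adj.tolist()


def aggregate_bias(table: AlleleCountTable, p0: float = 0.5) -> pd.DataFrame:
    """Bias tests for every (replicate × SNP) pair plus per-replicate pools.

    Per-SNP tests carry BH-adjusted p-values across the per-SNP family; raw
    p-values remain the primary output.  Pooled rows (snp = ``"pooled"``)
    sum the parental counts over SNPs within a replicate.
    """
    if not table.replicates:
        raise InputError("count table has no replicates")
    per_snp: list[BiasTestResult] = []
    for rep in table.replicates:
        for pos in sorted(table.counts[rep]):
            s = table.counts[rep][pos]
            per_snp.append(bias_test(s.maternal, s.paternal, rep, pos, p0))
    adjusted = benjamini_hochberg([r.p_value for r in per_snp])
    rows = [
        {"replicate": r.replicate, "snp": r.snp, "h": r.h_count, "c": r.c_count,
         "total": r.h_count + r.c_count, "p_raw": r.p_value, "p_adj": adj,
         "direction": r.direction, "log2_ratio": r.log2_ratio}
        for r, adj in zip(per_snp, adjusted)
    ]
    for rep in table.replicates:
        pool = table.pooled(rep)
        r = bias_test(pool.maternal, pool.paternal, rep, "pooled", p0)
        rows.append({"replicate": rep, "snp": "pooled", "h": r.h_count,
                     "c": r.c_count, "total": r.h_count + r.c_count,
                     "p_raw": r.p_value, "p_adj": math.nan,
                     "direction": r.direction, "log2_ratio": r.log2_ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 2^-ddCt relative expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target Ct plus one or more reference-gene Cts."""

    sample_id: str
    target_ct: float
    reference_cts: Mapping[str, float]

    def __post_init__(self):
        if not self.reference_cts:
            raise InputError(f"{self.sample_id}: at least one reference gene required")
        for name, ct in list(self.reference_cts.items()) + [("target", self.target_ct)]:
            if not math.isfinite(ct) or ct <= 0:
                raise InputError(f"{self.sample_id}: Ct for {name} must be finite and > 0")

    @property
    def delta_ct(self) -> float:
        """Target Ct minus the arithmetic mean of reference Cts.

        Averaging Cts is the log-domain equivalent of normalising to the
        geometric mean of the reference quantities.
        """
        return self.target_ct - float(np.mean(list(self.reference_cts.values())))


def ddct_expression(sample: CtRecord, calibrator: CtRecord) -> float:
    """Relative expression of the sample vs the calibrator, 2^−ΔΔCt."""
    if set(sample.reference_cts) != set(calibrator.reference_cts):
        raise InputError("sample and calibrator use different reference-gene sets")
    return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)


# ---------------------------------------------------------------------------
# Mid-parent heterosis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitTable:
    """Replicate trait values for the two parents and the polyploid."""

    trait: str
    maternal: tuple[float, ...]
    polyploid: tuple[float, ...]
    paternal: tuple[float, ...]
    units: str = ""

    def __post_init__(self):
        for name in ("maternal", "polyploid", "paternal"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise InputError(f"{self.trait}: no {name} replicates")
            object.__setattr__(self, name, vals)


@dataclass(frozen=True)
class HeterosisResult:
    trait: str
    means: dict  # genotype -> mean
    standard_errors: dict  # genotype -> SE (None when n < 2)
    mid_parent: float
    mph_percent: float
    units: str = ""


def _se(values: Sequence[float]) -> float | None:
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def mid_parent_heterosis(trait: TraitTable) -> HeterosisResult:
    """Mid-parent heterosis of the polyploid for one trait.

    MPH% = (polyploid mean − mid-parent mean) / mid-parent mean × 100, the
    mid-parent mean being the average of the two parental means.  Genotype
    means are reported with SE = sd / √n (sample sd, n−1 denominator).
    """
    means = {g: float(np.mean(getattr(trait, g)))
             for g in ("maternal", "polyploid", "paternal")}
    mid = (means["maternal"] + means["paternal"]) / 2
    if mid == 0:
        raise InputError(f"{trait.trait}: mid-parental value is zero; MPH undefined")
    mph = (means["polyploid"] - mid) / mid * 100
    ses = {g: _se(getattr(trait, g)) for g in ("maternal", "polyploid", "paternal")}
    return HeterosisResult(trait=trait.trait, means=means, standard_errors=ses,
                           mid_parent=mid, mph_percent=mph, units=trait.units)


def heterosis_from_tidy(df: pd.DataFrame) -> list[HeterosisResult]:
    """MPH for every trait in a tidy table (trait, genotype, replicate, value).

    ``genotype`` must be ``maternal``, ``polyploid`` or ``paternal``;
    optional ``units`` column is carried through.
    """
    out = []
    for trait, sub in df.groupby("trait", sort=False):
        groups = {g: tuple(sub.loc[sub.genotype == g, "value"])
                  for g in ("maternal", "polyploid", "paternal")}
        units = str(sub["units"].iloc[0]) if "units" in sub else ""
        out.append(mid_parent_heterosis(TraitTable(
            trait=str(trait), units=units, **groups)))
    return out


def heterosis_to_dataframe(results: Sequence[HeterosisResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"trait": r.trait, "units": r.units,
         "maternal_mean": r.means["maternal"],
         "polyploid_mean": r.means["polyploid"],
         "paternal_mean": r.means["paternal"],
         "maternal_se": r.standard_errors["maternal"],
         "polyploid_se": r.standard_errors["polyploid"],
         "paternal_se": r.standard_errors["paternal"],
         "mid_parent": r.mid_parent,
         "mph_percent": round(r.mph_percent, 2)}
        for r in results
    ])
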