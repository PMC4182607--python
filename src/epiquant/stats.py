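"""Paired inner-vs-outer inference.

Wilcoxon matched-pairs signed-rank tests (exact or normal approximation
with tie correction), analyte ratio-vs-1 tests on the log scale,
Benjamini-Hochberg step-up adjustment over a declared comparison family
(the family size may exceed the number of supplied p-values), the
hemoglobin explant-contamination QC filter, and median/IQR summaries.

The exact two-sided p-value is the tail probability of the signed-rank
statistic W⁺ under the null that each |difference| carries a random
sign — the distribution over all 2ⁿ sign assignments — computed by the
subset-sum recursion over the (mid-)ranks, which handles ties exactly.
Zero differences are dropped before ranking; ties among |differences|
get mid-ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._core import ValidationError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25  # auto mode: exact enumeration distribution up to here

SIGNIFICANT_P = 0.05
TREND_P = 0.10


@dataclass(frozen=True)
class PairedSample:
    """Per-subject (inner, outer) pairs for one metric.  Subjects missing
    either side must be dropped upstream (with a log entry)."""

    metric_name: str
    inner: tuple
    outer: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "inner", tuple(float(v) for v in self.inner))
        object.__setattr__(self, "outer", tuple(float(v) for v in self.outer))
        if len(self.inner) != len(self.outer):
            raise ValidationError(f"{self.metric_name}: unequal pair lengths")
        if len(self.inner) == 0:
            raise ValidationError(f"{self.metric_name}: no pairs")

    @property
    def n(self) -> int:
        return len(self.inner)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.inner) - np.asarray(self.outer)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = min(W+, W-)
    w_plus: float
    n_used: int  # pairs after dropping zero differences
    p_value: float
    method: str  # "exact" or "normal"


@lru_cache(maxsize=512)
def _signed_rank_counts(doubled_ranks: tuple) -> np.ndarray:
    """Counts of 2·W⁺ over all sign assignments of the given ranks
    (ranks doubled so mid-ranks become integers)."""
    total = sum(doubled_ranks)
    f = np.zeros(total + 1)
    f[0] = 1.0
    for r in doubled_ranks:
        f[r:] += f[: total + 1 - r]
    return f


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    doubled = tuple(int(round(2 * r)) for r in ranks)
    counts = _signed_rank_counts(doubled)
    n_total = 2.0 ** len(doubled)
    w2 = int(round(2 * w_plus))
    lower = counts[: w2 + 1].sum() / n_total
    upper = counts[w2:].sum() / n_total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_signed_rank(
    sample: PairedSample | Sequence[float],
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    ``sample`` is a :class:`PairedSample` or a sequence of paired
    differences.  ``mode``: ``"exact"`` (sign-assignment distribution),
    ``"normal"`` (approximation with tie correction), or ``"auto"``
    (exact up to n = 25).  All-zero differences give p = 1 with a
    warning.
    """
    if isinstance(sample, PairedSample):
        d = sample.differences
    else:
        d = np.asarray(sample, dtype=float)
    if d.size == 0:
        raise ValidationError("wilcoxon_signed_rank: no differences")
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; returning p = 1")
        return WilcoxonResult(0.0, 0.0, 0, 1.0, "degenerate")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError("mode must be auto|exact|normal")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        p = _exact_two_sided_p(ranks, w_plus)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (w_plus - mu) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(min(w_plus, w_minus), w_plus, n, p, method)


def ratio_test(ratios: Sequence[float], mode: str = "auto") -> WilcoxonResult:
    """Signed-rank test of whether per-subject inner/outer ratios differ
    from 1, performed on log(ratio) vs 0 (rank-equivalent to ratio vs 1)."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValidationError("ratio_test: no ratios")
    if (r <= 0).any():
        raise ValidationError("ratio_test: ratios must be > 0")
    return wilcoxon_signed_rank(np.log(r), mode=mode)


def bh_adjust(raw_p: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``family_size`` m may exceed the number of supplied p-values when the
    declared family is larger than the list at hand (as with a family of
    53 comparisons adjusted in batches); it defaults to the list length
    and must not be smaller.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    if m < p.size:
        raise ValidationError(
            f"bh_adjust: family_size {m} smaller than number of p-values {p.size}"
        )
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Explant QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExplantRecord:
    """One explant culture's analyte panel plus hemoglobin QC fields.

    Hemoglobin in epidermal cultures flags dermal (blood) contamination;
    cultures at or above LOD + 1 CI are excluded.
    """

    subject_id: str
    site: str
    compartment: str = "epidermis"
    analytes: Mapping = field(default_factory=dict)
    hemoglobin_concentration: float | None = None
    lod: float | None = None
    lod_ci: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.analytes.values()):
            raise ValidationError("analyte concentrations must be >= 0")


@dataclass(frozen=True)
class Exclusion:
    record: ExplantRecord
    reason: str


def filter_explants(records: Iterable[ExplantRecord]) -> tuple[list, list]:
    """Apply the hemoglobin contamination rule to epidermal cultures.

    Epidermal records with hemoglobin ≥ LOD + 1·CI are excluded
    (inclusive at the boundary); dermal records pass through.  Missing
    QC fields on an epidermal record are an error.
    """
    kept, excluded = [], []
    for rec in records:
        if rec.compartment != "epidermis":
            kept.append(rec)
            continue
        if rec.hemoglobin_concentration is None or rec.lod is None or rec.lod_ci is None:
            raise ValidationError(
                f"{rec.subject_id}/{rec.site}: missing hemoglobin QC fields"
            )
        cutoff = rec.lod + rec.lod_ci
        if rec.hemoglobin_concentration >= cutoff:
            excluded.append(
                Exclusion(
                    rec,
                    f"hemoglobin {rec.hemoglobin_concentration:.3g} >= "
                    f"LOD + 1 CI ({cutoff:.3g})",
                )
            )
        else:
            kept.append(rec)
    return kept, excluded


def summarize(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """(median, (Q1, Q3)) with linear interpolation between order
    statistics — the convention behind 'median, 15.69; IQR, 11.50–18.76'
    style reporting."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("summarize: empty input")
    return float(np.median(v)), (
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


# ---------------------------------------------------------------------------
# Comparison family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Comparison:
    """One declared comparison: a paired inner-vs-outer metric test or an
    analyte inner/outer ratio-vs-1 test."""

    name: str
    kind: str = "paired"  # "paired" | "ratio"

    def __post_init__(self) -> None:
        if self.kind not in ("paired", "ratio"):
            raise ValidationError("Comparison.kind must be 'paired' or 'ratio'")


@dataclass(frozen=True)
class FamilyDeclaration:
    """The multiple-comparison family: its members, its size m (which may
    exceed the member count), and the significance/trend thresholds on
    the FDR-adjusted p-value."""

    comparisons: tuple
    family_size: int | None = None
    significant_p: float = SIGNIFICANT_P
    trend_p: float = TREND_P

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(self.comparisons))
        if not self.comparisons:
            raise ValidationError("family has no comparisons")
        if self.family_size is not None and self.family_size < len(self.comparisons):
            raise ValidationError(
                "family_size smaller than the number of declared comparisons"
            )

    @property
    def m(self) -> int:
        return self.family_size if self.family_size is not None else len(self.comparisons)


@dataclass(frozen=True)
class ComparisonResult:
    metric_name: str
    kind: str
    statistic: float
    n: int
    raw_p: float
    adjusted_p: float
    family_size: int
    verdict: str  # significant | trend | ns


def _verdict(adj_p: float, family: FamilyDeclaration) -> str:
    if adj_p < family.significant_p:
        return "significant"
    if adj_p < family.trend_p:
        return "trend"
    return "ns"


def paired_sample_from_frame(
    df: pd.DataFrame, metric: str, value_col: str = "value"
) -> PairedSample:
    """Build a PairedSample for ``metric`` from a long frame with columns
    subject_id, site, metric, value.  Subjects missing a side are dropped
    with a log entry."""
    sub = df[df["metric"] == metric]
    if sub.empty:
        raise ValidationError(f"metric {metric!r} not present in dataset")
    wide = sub.pivot_table(index="subject_id", columns="site", values=value_col, aggfunc="first")
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.info("%s: dropping incomplete subjects %s", metric, list(incomplete))
        wide = wide.dropna()
    if wide.empty:
        raise ValidationError(f"metric {metric!r}: no complete pairs")
    return PairedSample(metric, tuple(wide["inner"]), tuple(wide["outer"]))


def run_comparison_family(
    cohort,
    family: FamilyDeclaration,
    mode: str = "auto",
) -> list[ComparisonResult]:
    """Run every declared comparison on a cohort dataset and apply one BH
    adjustment over the declared family size.

    ``cohort`` is a :class:`~epiquant.synthetic.CohortData` or any object
    with ``summaries`` (subject_id, site, metric, value) and ``analytes``
    (subject_id, site, analyte, concentration) long frames.  Unresolvable
    comparisons raise before any p-value is computed.
    """
    summaries: pd.DataFrame = cohort.summaries
    analytes: pd.DataFrame = cohort.analytes

    # resolve everything first so failures precede computation
    samples = []
    for comp in family.comparisons:
        if comp.kind == "paired":
            samples.append((comp, paired_sample_from_frame(summaries, comp.name)))
        else:
            sub = analytes[analytes["analyte"] == comp.name]
            if sub.empty:
                raise ValidationError(f"analyte {comp.name!r} not present in dataset")
            wide = sub.pivot_table(
                index="subject_id", columns="site", values="concentration", aggfunc="first"
            ).dropna()
            if wide.empty:
                raise ValidationError(f"analyte {comp.name!r}: no complete pairs")
            samples.append((comp, tuple(wide["inner"] / wide["outer"])))

    results = []
    for comp, sample in samples:
        if comp.kind == "paired":
            res = wilcoxon_signed_rank(sample, mode=mode)
        else:
            res = ratio_test(sample, mode=mode)
        results.append((comp, res))

    adj = bh_adjust([r.p_value for _, r in results], family_size=family.m)
    return [
        ComparisonResult(
            metric_name=comp.name,
            kind=comp.kind,
            statistic=res.statistic,
            n=res.n_used,
            raw_p=res.p_value,
            adjusted_p=float(a),
            family_size=family.m,
            verdict=_verdict(float(a), family),
        )
        for (comp, res), a in zip(results, adj)
    ]


def default_family(cohort, family_size: int = 53) -> FamilyDeclaration:
    """Declare one comparison per metric and per analyte present in the
    cohort, adjusted for the given family size."""
    comps = [Comparison(m, "paired") for m in cohort.summaries["metric"].unique()]
    comps += [Comparison(a, "ratio") for a in cohort.analytes["analyte"].unique()]
    return FamilyDeclaration(tuple(comps), family_size=max(family_size, len(comps)))
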