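"""Confusion counts, sensitivity/specificity, and cohort statistics.

Sensitivity definitions follow the assay's reporting conventions:

* sensitivity (any dysfunction): fraction of biallelic-defective samples
  called dysfunctional, regardless of subtype;
* TP53 sensitivity: fraction of biallelic-TP53 samples called
  p53-dysfunctional (correct subtype required);
* ATM sensitivity: fraction of biallelic-ATM samples called
  ATM-dysfunctional (correct subtype required);
* specificity: fraction of WT samples called functional.

Percentages are displayed rounded half away from zero to integers; the
exact fractions are retained on the report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .panel_model import (
    CallValue,
    FunctionalCall,
    GenotypeLabel,
    MONOALLELIC_GENOTYPES,
    SampleMetadata,
)

DYSFUNCTIONAL_CALLS = (CallValue.P53_DYSFUNCTIONAL, CallValue.ATM_DYSFUNCTIONAL)


def round_percent(fraction: Fraction | float) -> int:
    """Round a fraction to an integer percent, half away from zero."""
    x = float(fraction) * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class EvaluationReport:
    """Confusion counts plus the four headline statistics as exact
    fractions (Fraction) with rounded integer-percent views."""

    counts: dict[tuple[GenotypeLabel, CallValue], int]
    sensitivity_any_dysfunction: Fraction | None
    sensitivity_tp53: Fraction | None
    sensitivity_atm: Fraction | None
    specificity: Fraction | None
    n_samples: int = 0

    def percent(self, name: str) -> int | None:
        value = getattr(self, name)
        return None if value is None else round_percent(value)

    def count(self, genotype: GenotypeLabel, call: CallValue) -> int:
        return self.counts.get((genotype, call), 0)

    def to_json(self, path) -> None:
        def frac(f: Fraction | None):
            if f is None:
                return None
            return {
                "numerator": f.numerator,
                "denominator": f.denominator,
                "percent": round_percent(f),
            }

        doc = {
            "n_samples": self.n_samples,
            "counts": [
                {"genotype": g.value, "call": c.value, "n": n}
                for (g, c), n in sorted(
                    self.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                )
            ],
            "sensitivity_any_dysfunction": frac(self.sensitivity_any_dysfunction),
            "sensitivity_tp53": frac(self.sensitivity_tp53),
            "sensitivity_atm": frac(self.sensitivity_atm),
            "specificity": frac(self.specificity),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")


def evaluate(
    calls: Sequence[FunctionalCall], metadata: Iterable[SampleMetadata]
) -> EvaluationReport:
    """Tally genotype x call counts and compute the four statistics.

    Statistics use WT and biallelic genotypes only; monoallelic samples
    contribute to counts but not to sensitivity/specificity (see
    monoallelic_breakdown). A statistic with an empty denominator is None.
    """
    meta = {m.sample_id: m for m in metadata}
    counts: dict[tuple[GenotypeLabel, CallValue], int] = {}
    for call in calls:
        if call.sample_id not in meta:
            raise ValueError(f"call for unknown sample {call.sample_id}")
        g = meta[call.sample_id].genotype
        key = (g, call.value)
        counts[key] = counts.get(key, 0) + 1

    def group_total(genotypes: Iterable[GenotypeLabel]) -> int:
        return sum(
            n for (g, _), n in counts.items() if g in set(genotypes)
        )

    def hits(genotypes: Iterable[GenotypeLabel], calls_ok: Iterable[CallValue]) -> int:
        gset, cset = set(genotypes), set(calls_ok)
        return sum(
            n for (g, c), n in counts.items() if g in gset and c in cset
        )

    biallelic = (GenotypeLabel.TP53_BIALLELIC, GenotypeLabel.ATM_BIALLELIC)

    def ratio(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den else None

    return EvaluationReport(
        counts=counts,
        sensitivity_any_dysfunction=ratio(
            hits(biallelic, DYSFUNCTIONAL_CALLS), group_total(biallelic)
        ),
        sensitivity_tp53=ratio(
            hits([GenotypeLabel.TP53_BIALLELIC], [CallValue.P53_DYSFUNCTIONAL]),
            group_total([GenotypeLabel.TP53_BIALLELIC]),
        ),
        sensitivity_atm=ratio(
            hits([GenotypeLabel.ATM_BIALLELIC], [CallValue.ATM_DYSFUNCTIONAL]),
            group_total([GenotypeLabel.ATM_BIALLELIC]),
        ),
        specificity=ratio(
            hits([GenotypeLabel.WT], [CallValue.FUNCTIONAL]),
            group_total([GenotypeLabel.WT]),
        ),
        n_samples=len(calls),
    )


def monoallelic_breakdown(
    calls: Sequence[FunctionalCall], metadata: Iterable[SampleMetadata]
) -> dict[GenotypeLabel, dict[CallValue, int]]:
    """Call counts per monoallelic genotype (sole mutation / sole
    deletion), the contingency layout used for prediction-only samples."""
    meta = {m.sample_id: m for m in metadata}
    table: dict[GenotypeLabel, dict[CallValue, int]] = {}
    for call in calls:
        g = meta[call.sample_id].genotype
        if g not in MONOALLELIC_GENOTYPES:
            continue
        row = table.setdefault(g, {c: 0 for c in CallValue})
        row[call.value] += 1
    return table


@dataclass
class CloneSizeCorrelation:
    rho: float  # NaN when undefined (constant input)
    p_value: float
    n: int


def correlate_clone_size(
    calls: Sequence[FunctionalCall],
    metadata: Iterable[SampleMetadata],
    use_margin: bool = False,
) -> CloneSizeCorrelation:
    """Spearman rank correlation between clone fraction and the
    dysfunctional verdict (0/1 indicator, or the stage-1 margin when
    ``use_margin``)."""
    meta = {m.sample_id: m for m in metadata}
    xs, ys = [], []
    for call in calls:
        m = meta.get(call.sample_id)
        if m is None or m.clone_fraction is None:
            continue
        xs.append(m.clone_fraction)
        ys.append(
            call.stage1_margin
            if use_margin
            else float(call.value in DYSFUNCTIONAL_CALLS)
        )
    if len(xs) < 3:
        raise ValueError("correlate_clone_size needs >=3 samples with clone size")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return CloneSizeCorrelation(rho=math.nan, p_value=math.nan, n=len(xs))
    rho, p = stats.spearmanr(xs, ys)
    return CloneSizeCorrelation(rho=float(rho), p_value=float(p), n=len(xs))


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn's post hoc


@dataclass
class DunnComparison:
    group_a: str
    group_b: str
    z: float
    p_adjusted: float


@dataclass
class KruskalDunnReport:
    H: float
    p_value: float
    pairwise: list[DunnComparison] = field(default_factory=list)

    def stars(self) -> str:
        """Significance band coding: * 0.01<=p<0.05, ** 0.001<=p<0.01,
        *** p<0.001, empty otherwise (overall test)."""
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> KruskalDunnReport:
    """Kruskal-Wallis H test across >=3 groups with Dunn's pairwise post
    hoc z-tests, Bonferroni-adjusted over the number of pairs.

    Dunn's z uses pooled mid-ranks with the standard tie correction of the
    rank variance.
    """
    names = list(groups)
    if len(names) < 3:
        raise ValueError("kruskal_dunn requires at least 3 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_dunn requires nonempty groups")

    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]):
        # scipy raises on all-identical input; H is identically zero there
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term for the variance of rank sums
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1)) if N > 1 else 0.0

    mean_ranks = {}
    start = 0
    for name, a in zip(names, arrays):
        mean_ranks[name] = ranks[start : start + a.size].mean()
        start += a.size

    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise: list[DunnComparison] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            na, nb = arrays[i].size, arrays[j].size
            se = math.sqrt(
                (N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
            )
            z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se if se else 0.0
            p_raw = 2.0 * stats.norm.sf(abs(z))
            pairwise.append(
                DunnComparison(
                    group_a=names[i],
                    group_b=names[j],
                    z=float(z),
                    p_adjusted=float(min(1.0, p_raw * n_pairs)),
                )
            )
    return KruskalDunnReport(H=float(H), p_value=float(p), pairwise=pairwise)


def kruskal_dunn_by_gene(
    fi_by_group: Mapping[str, Mapping[str, Sequence[float]]],
) -> dict[str, KruskalDunnReport]:
    """Run kruskal_dunn per gene on a gene -> group -> FI-list nesting."""
    return {gene: kruskal_dunn(groups) for gene, groups in fi_by_group.items()}
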