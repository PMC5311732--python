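"""Comparative statistics over mapped species: family cross-talk, rank
correlations with element age, location-count summaries, and the
expression-dominance ("zoning") diagnostic.

Cross-talk between two families A and B is the percentage

    100 * shared / (mapped_A + mapped_B - shared)

where mapped_A/mapped_B count species with at least one hit in each family
and shared counts species hitting both; the denominator is the non-redundant
species total of the pair. Contaminating fragments of one family nested in
elements of another inflate this percentage, which makes it a useful proxy
for annotation contamination.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CrosstalkCell:
    family_a: str
    family_b: str
    mapped_a: int
    mapped_b: int
    shared: int
    sum_ab: int
    non_redundant: int
    crosstalk_pct: float | None  # None when undefined (no mapped species)


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float | None
    p_value: float | None
    method: str  # "t" | "permutation"


@dataclass(frozen=True)
class DominanceReport:
    element_id: str
    region: str
    total_expression: float
    top_species: str
    top_expression: float
    dominance: float
    group: str  # "upper" | "lower"


def crosstalk_cell(family_a: str, family_b: str, mapped_a: int, mapped_b: int,
                   shared: int) -> CrosstalkCell:
    """Cross-talk arithmetic from per-pair species counts."""
    if shared > min(mapped_a, mapped_b):
        raise ValueError("shared species cannot exceed either family's mapped count")
    sum_ab = mapped_a + mapped_b
    non_redundant = sum_ab - shared
    pct = 100.0 * shared / non_redundant if non_redundant > 0 else None
    return CrosstalkCell(family_a, family_b, mapped_a, mapped_b, shared,
                         sum_ab, non_redundant, pct)


def crosstalk(species_families: Mapping[str, set[str]],
              families: Sequence[str] | None = None) -> list[CrosstalkCell]:
    """Cross-talk cells for every unordered family pair.

    `species_families` maps each species sequence to the set of families it
    has at least one hit in (species with no family hits may be omitted).
    """
    if families is None:
        families = sorted({f for fs in species_families.values() for f in fs})
    mapped = {f: 0 for f in families}
    shared: dict[tuple[str, str], int] = {
        pair: 0 for pair in itertools.combinations(families, 2)
    }
    for fams in species_families.values():
        hit = sorted(f for f in fams if f in mapped)
        for f in hit:
            mapped[f] += 1
        for pair in itertools.combinations(hit, 2):
            shared[pair] += 1
    return [
        crosstalk_cell(a, b, mapped[a], mapped[b], shared[(a, b)])
        for a, b in itertools.combinations(families, 2)
    ]


def rank_correlation(x: Sequence[float], y: Sequence[float],
                     method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling.

    The p-value uses the t-distribution approximation
    t = r * sqrt((n-2) / (1-r^2)); for n <= 10 (or method="permutation") an
    exact permutation p-value over all n! rank orderings is computed instead.
    Constant inputs have undefined r, reported as None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(n=n, r=None, p_value=None, method="t")
    if method == "auto":
        method = "permutation" if n <= 10 else "t"
    if method == "t":
        r, p = sps.spearmanr(x, y)
        return CorrelationResult(n=n, r=float(r), p_value=float(p), method="t")
    # exact permutation distribution of |rho|
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(ry):
        r_perm = float(np.corrcoef(rx, perm)[0, 1])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return CorrelationResult(n=n, r=r_obs, p_value=count / total,
                             method="permutation")


def location_summary(x_values_by_category: Mapping[str, Sequence[int]]
                     ) -> dict[str, dict[str, float | None]]:
    """Median and mean location count x per category, over M species only
    (x >= 2); a category with no multi-mappers reports missing values."""
    out: dict[str, dict[str, float | None]] = {}
    for cat, xs in x_values_by_category.items():
        m = [x for x in xs if x >= 2]
        if m:
            out[cat] = {"median": float(np.median(m)), "mean": float(np.mean(m)),
                        "n_multi": len(m)}
        else:
            out[cat] = {"median": None, "mean": None, "n_multi": 0}
    return out


def _otsu_split(values: np.ndarray) -> float:
    """1-D two-group split threshold maximising between-group variance of
    log-expression (ties broken toward the lower threshold)."""
    v = np.sort(np.log(values))
    n = len(v)
    best_t, best_var = v[0], -np.inf
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, n):
        n1, n2 = k, n - k
        m1 = csum[k - 1] / n1
        m2 = (total - csum[k - 1]) / n2
        var = n1 * n2 * (m1 - m2) ** 2
        if var > best_var:
            best_var = var
            best_t = (v[k - 1] + v[k]) / 2
    return float(np.exp(best_t))


def dominance_diagnostic(
    element_totals: Mapping[str, Mapping[str, float]],
    region: str = "LTR",
    collapse_factor: float = 1.5,
) -> tuple[list[DominanceReport], dict[str, object]]:
    """Detect "zoning": a bimodal element split driven by one species.

    `element_totals` maps element_id -> {species sequence: un-weighted
    expression contribution of that species to the element's region}.
    Elements with zero total expression are excluded from the split.

    Per element the dominance fraction of its top species is reported, and
    the population is split into upper/lower groups at the threshold
    maximising the between-group variance of log total expression. The
    zoning flag is raised when the upper/lower group-median ratio is at
    least `collapse_factor` with all species included, and falls below it
    after removing the single species with the highest total contribution
    across elements (the split is recomputed without that species).
    """
    totals = {e: sum(c.values()) for e, c in element_totals.items()}
    totals = {e: t for e, t in totals.items() if t > 0}
    if len(totals) < 2:
        raise ValueError("need at least 2 elements with expression")
    values = np.array(list(totals.values()))
    thresh = _otsu_split(values)
    reports = []
    for e, t in totals.items():
        contribs = element_totals[e]
        top_sp = max(contribs, key=lambda s: (contribs[s], s))
        reports.append(DominanceReport(
            element_id=e, region=region, total_expression=t,
            top_species=top_sp, top_expression=contribs[top_sp],
            dominance=contribs[top_sp] / t,
            group="upper" if t > thresh else "lower",
        ))
    ratio_before = _group_median_ratio(totals, thresh)
    # remove the globally top-contributing species and re-split
    sp_totals: dict[str, float] = {}
    for contribs in element_totals.values():
        for s, v in contribs.items():
            sp_totals[s] = sp_totals.get(s, 0.0) + v
    top_global = max(sp_totals, key=lambda s: (sp_totals[s], s))
    reduced = {
        e: sum(v for s, v in c.items() if s != top_global)
        for e, c in element_totals.items()
    }
    reduced = {e: t for e, t in reduced.items() if t > 0}
    if len(reduced) >= 2 and np.ptp(np.log(list(reduced.values()))) > 0:
        thresh2 = _otsu_split(np.array(list(reduced.values())))
        ratio_after = _group_median_ratio(reduced, thresh2)
    else:
        ratio_after = 1.0
    flag = ratio_before >= collapse_factor and ratio_after < collapse_factor
    summary = {
        "split_threshold": thresh,
        "group_median_ratio": ratio_before,
        "group_median_ratio_without_top": ratio_after,
        "top_species": top_global,
        "zoning_flag": bool(flag),
    }
    return sorted(reports, key=lambda r: r.element_id), summary


def _group_median_ratio(totals: Mapping[str, float], thresh: float) -> float:
    upper = [t for t in totals.values() if t > thresh]
    lower = [t for t in totals.values() if t <= thresh]
    if not upper or not lower:
        return 1.0
    return float(np.median(upper) / np.median(lower))
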