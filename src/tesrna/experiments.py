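"""Canned desk-scale experiments used for validation and reporting.

Each function simulates its own inputs from an explicit seed, runs the
relevant pipeline stages, and returns plain dictionaries of measured
quantities. They are deliberately self-contained so the same code backs the
test suite, the examples and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import pipelines as pl
from . import stats_report as sr
from . import synthetic_data as sd
from . import te_annotation as ta


def age_recovery(n_elements: int = 500, seed: int = 0,
                 age_range: tuple[float, float] = (1e5, 1.9e6),
                 ltr_length: int = 1000, model: str = "JC69") -> dict[str, float]:
    """Estimate insertion ages of clock-simulated elements and compare to truth.

    The simulation is substitution-only with a uniform clock (no elevated
    hotspot rate), spanning the low-divergence regime (2rT <= ~0.05) where
    the corrections are near-linear. Ages are estimated via the full
    align-then-correct path.
    """
    spec = sd.FamilySpec("clock", n_elements, ltr_length=ltr_length, int_length=60,
                         age_law="uniform", age_params=age_range,
                         hotspot_rate_factor=1.0, hotspot_variant_divergence=0.0)
    els = sd.simulate_family(spec, seed=seed)
    rel_err = []
    for el in els:
        est = ta.age_ltr_pair(el.sequence[slice(*el.ltr5)],
                              el.sequence[slice(*el.ltr3)], model=model)
        rel_err.append((est.T - el.age) / el.age)
    rel_err = np.asarray(rel_err)
    return {
        "n": n_elements,
        "mean_relative_bias": float(rel_err.mean()),
        "median_abs_relative_error": float(np.median(np.abs(rel_err))),
    }


def reference_set_directions(seed: int, copies_per_family: int = 100
                             ) -> dict[str, float]:
    """Population-vs-exemplar comparison on one simulated study.

    Measures mapped-species totals and U proportions on the annotated
    population and on N-masked exemplars, how many hotspot-origin species
    still map to exemplars, and the un-weighted Spearman correlation between
    element age and per-nt species density.
    """
    specs = [
        sd.FamilySpec("famA", copies_per_family, ltr_length=300, int_length=900),
        sd.FamilySpec("famB", copies_per_family, ltr_length=300, int_length=900),
    ]
    total_nt = sum(s.copy_number * s.element_length for s in specs)
    study = pl.simulate_study(specs, int(total_nt * 1.7), seed=seed)
    cmp = pl.reference_set_comparison(study)
    hot = study.species_truth[study.species_truth.hotspot_origin]
    ex_hits = cmp["exemplar_hits"]
    hot_mapped = sum(1 for s in set(hot.sequence) if ex_hits[s].x > 0)
    corr = pl.age_density_correlation(study)
    return {
        "n_elements": len(study.annotations),
        "population_mapped_species": cmp["population_mapped"],
        "exemplar_mapped_species": cmp["exemplar_mapped"],
        "population_U_proportion": cmp["population_um"]["U_proportion"],
        "exemplar_U_proportion": cmp["exemplar_um"]["U_proportion"],
        "hotspot_species": int(len(set(hot.sequence))),
        "hotspot_species_mapped_to_exemplars": int(hot_mapped),
        "age_density_spearman_r": corr.r,
        "age_density_spearman_p": corr.p_value,
    }


def crosstalk_contrast(seed: int, copies_per_family: int = 12,
                       nesting_rate: float = 0.8) -> dict[str, float]:
    """Cross-talk between two families with and without nested contamination."""
    specs = [
        sd.FamilySpec("famA", copies_per_family, ltr_length=300, int_length=900),
        sd.FamilySpec("famB", copies_per_family, ltr_length=300, int_length=900),
    ]
    total_nt = sum(s.copy_number * s.element_length for s in specs)
    out: dict[str, float] = {}
    for label, nesting in (("clean", 0.0), ("contaminated", nesting_rate)):
        study = pl.simulate_study(specs, int(total_nt * 2.2), seed=seed,
                                  nesting_rate=nesting)
        fams = pl.species_family_sets(study.genome_hits, study.annotations)
        (cell,) = sr.crosstalk(fams, families=["famA", "famB"])
        out[f"crosstalk_pct_{label}"] = (
            cell.crosstalk_pct if cell.crosstalk_pct is not None else 0.0
        )
        out[f"shared_{label}"] = cell.shared
    return out


def dominance_zoning(seed: int, n_elements: int = 30,
                     planted_expression: float = 1976.0) -> dict[str, object]:
    """Planted-truth zoning: one high-expression species on half the elements."""
    rng = np.random.default_rng(seed)
    contribs = {}
    for i in range(n_elements):
        base = {f"bg{i}_{j}": float(rng.integers(3, 9)) for j in range(6)}
        if i < n_elements // 2:
            base["PLANTED"] = planted_expression
        contribs[f"el{i:03d}"] = base
    reports, summary = sr.dominance_diagnostic(contribs)
    return {"reports": reports, "summary": summary}
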