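"""End-to-end helpers wiring the simulator, mapper and metrics together.

These are the workflows the individual modules exist for: compare reference
sets (annotated population vs exemplars), relate per-element sRNA density to
insertion age under different weighting schemes, and measure cross-talk with
and without nested contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import quantification as qt
from . import stats_report as sr
from . import synthetic_data as sd
from . import te_annotation as ta
from .io_formats import AnnotationRecord
from .mapping import ExactIndex, HitSet, map_table
from .quantification import WeightingScheme, UNWEIGHTED


def species_family_sets(
    hitsets: Mapping[str, HitSet], annotations: Sequence[AnnotationRecord]
) -> dict[str, set[str]]:
    """For each species, the set of families with at least one in-element hit.

    A hit belongs to an element when its full read span lies within the
    element's interval.
    """
    by_ref: dict[str, list[AnnotationRecord]] = {}
    for a in annotations:
        by_ref.setdefault(a.reference_id, []).append(a)
    for lst in by_ref.values():
        lst.sort(key=lambda a: a.interval)
    out: dict[str, set[str]] = {}
    for seq, hs in hitsets.items():
        fams: set[str] = set()
        L = len(seq)
        for h in hs.hits:
            for a in by_ref.get(h.reference_id, ()):
                s, e = a.interval
                if h.position >= s and h.position + L <= e:
                    fams.add(a.family)
                elif s > h.position:
                    break
        if fams:
            out[seq] = fams
    return out


@dataclass
class SimulatedStudy:
    """One synthetic study: genome, annotation, truth, library and hit sets."""

    genome: dict[str, str]
    annotations: list[AnnotationRecord]
    truth: sd.TruthTable
    elements_by_family: dict[str, list[sd.SimulatedElement]]
    species: dict[str, int]  # sequence -> expression
    species_truth: pd.DataFrame
    genome_hits: dict[str, HitSet]


def simulate_study(
    families: Sequence[sd.FamilySpec],
    background_length: int,
    seed: int,
    nesting_rate: float = 0.0,
    model: sd.SilencingModel | None = None,
) -> SimulatedStudy:
    """Simulate a genome and an sRNA library and map the library back to it."""
    model = model or sd.SilencingModel()
    rng = np.random.default_rng(seed)
    genome, annotations, truth, by_family = sd.assemble_genome(
        background_length, families, nesting_rate=nesting_rate,
        seed=int(rng.integers(2**31)),
    )
    elements = [el for fam in by_family.values() for el in fam]
    reads, species_truth = sd.simulate_srna_library(
        elements, model, seed=int(rng.integers(2**31))
    )
    species: dict[str, int] = {}
    for seq, count in reads:
        species[seq] = species.get(seq, 0) + count
    lengths = sorted({len(s) for s in species}) or [21]
    index = ExactIndex(genome, lengths, label="genome")
    genome_hits = map_table(species, index)
    return SimulatedStudy(genome, annotations, truth, by_family,
                          species, species_truth, genome_hits)


def per_element_density(
    study: SimulatedStudy,
    scheme: WeightingScheme = UNWEIGHTED,
    metric: str = "species",
    role: str = "full",
) -> pd.DataFrame:
    """Per-element density (species or expression per nt) plus the truth age.

    Weighted schemes use the genome hit sets as the 1/x denominator. A single
    pass over all hits assigns each to the (non-overlapping) element locus
    containing its full read span.
    """
    import bisect

    loci = []
    for a in study.annotations:
        interval = a.interval if role == "full" else a.sub_locus(role)
        loci.append((a, interval))
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for idx, (a, (s, _e)) in enumerate(loci):
        by_ref.setdefault(a.reference_id, []).append((s, idx))
    starts_by_ref = {}
    for ref, pairs in by_ref.items():
        pairs.sort()
        starts_by_ref[ref] = ([s for s, _ in pairs], [i for _, i in pairs])
    species_tally = np.zeros(len(loci))
    species_count = np.zeros(len(loci), dtype=int)
    expr_tally = np.zeros(len(loci))
    for seq, hs in study.genome_hits.items():
        if not hs.hits:
            continue
        w = qt.weight_hits(hs, scheme, study.genome_hits)
        expr = study.species.get(seq, 1)
        L = len(seq)
        seen: set[int] = set()
        for h in hs.hits:
            ref = starts_by_ref.get(h.reference_id)
            if ref is None:
                continue
            k = bisect.bisect_right(ref[0], h.position) - 1
            if k < 0:
                continue
            idx = ref[1][k]
            s, e = loci[idx][1]
            if h.position + L > e:
                continue
            if idx not in seen:
                seen.add(idx)
                species_count[idx] += 1
            species_tally[idx] += w if scheme.mode == "weighted" else 0.0
            expr_tally[idx] += w * expr
    ages = dict(zip(study.truth.elements.element_id, study.truth.elements.age))
    rows = []
    for idx, (a, (s, e)) in enumerate(loci):
        length = e - s
        sp_per_nt = (species_tally[idx] if scheme.mode == "weighted"
                     else species_count[idx]) / length
        rows.append({
            "element_id": a.element_id, "family": a.family,
            "age": ages[a.element_id], "length": length,
            "species_count": int(species_count[idx]),
            "species_per_nt": sp_per_nt,
            "expression_per_nt": expr_tally[idx] / length,
            "density": sp_per_nt if metric == "species" else expr_tally[idx] / length,
        })
    return pd.DataFrame(rows)


def age_density_correlation(
    study: SimulatedStudy, scheme: WeightingScheme = UNWEIGHTED,
    metric: str = "species",
) -> sr.CorrelationResult:
    """Spearman correlation between element age and per-nt density."""
    df = per_element_density(study, scheme=scheme, metric=metric)
    return sr.rank_correlation(df.age.values, df.density.values, method="t")


def estimated_ages(study: SimulatedStudy, model: str = "JC69") -> pd.DataFrame:
    """Insertion ages estimated from each element's LTR pair in the genome."""
    rows = []
    chrom = next(iter(study.genome))
    seq = study.genome[chrom]
    truth_age = dict(zip(study.truth.elements.element_id, study.truth.elements.age))
    for a in study.annotations:
        l5 = a.sub_locus("LTR5")
        l3 = a.sub_locus("LTR3")
        est = ta.age_ltr_pair(seq[l5[0]:l5[1]], seq[l3[0]:l3[1]],
                              model=model, element_id=a.element_id)
        rows.append({"element_id": a.element_id, "family": a.family,
                     "true_age": truth_age[a.element_id],
                     "K": est.K, "estimated_age": est.T})
    return pd.DataFrame(rows)


def reference_set_comparison(
    study: SimulatedStudy, mask_identity_threshold: float = 0.6
) -> dict[str, object]:
    """Map the library to the annotated population and to N-masked exemplars.

    Returns mapped-species counts and U-proportions per reference set, plus
    the exemplar sequences; recapitulates the exemplar-vs-population
    comparison (species loss on exemplars, inflated U fraction).
    """
    population = {}
    chrom = next(iter(study.genome))
    gseq = study.genome[chrom]
    for a in study.annotations:
        s, e = a.interval
        population[a.element_id] = gseq[s:e]
    exemplars = {
        f"{fam}_exemplar": sd.build_exemplar([el.sequence for el in els],
                                             mask_identity_threshold)
        for fam, els in study.elements_by_family.items()
        if len(els) >= 2
    }
    lengths = sorted({len(s) for s in study.species})
    pop_hits = map_table(study.species, ExactIndex(population, lengths, label="population"))
    ex_hits = map_table(study.species, ExactIndex(exemplars, lengths, label="exemplars"))
    return {
        "population_hits": pop_hits,
        "exemplar_hits": ex_hits,
        "exemplars": exemplars,
        "population_um": qt.um_ratio(pop_hits.values()),
        "exemplar_um": qt.um_ratio(ex_hits.values()),
        "population_mapped": sum(1 for h in pop_hits.values() if h.x > 0),
        "exemplar_mapped": sum(1 for h in ex_hits.values() if h.x > 0),
    }
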