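"""Per-locus metrics from hit sets: species counts, expression, 1/x
weighting, per-nucleotide densities, U:M ratios and windowed profiles.

Two counting schemes are supported throughout:

* un-weighted — every mapping location has value 1;
* weighted — every location of a species has value 1/x, where x is the
  species' total number of locations in a *denominator* reference set. The
  denominator set may differ from the set being tallied (e.g. genome-weighted
  counts tallied on an annotated TE population), which is exactly the
  contrast between "dataset-weighted" and "genome-weighted" analyses.

A hit lies in a locus only if its full read span lies within the locus
interval; reads straddling an LTR/INT border count for the full element but
for neither sub-locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .mapping import Hit, HitSet


@dataclass(frozen=True)
class WeightingScheme:
    """mode 'unweighted' or 'weighted'; weighted requires the label of the
    reference set supplying the denominator x."""

    mode: str = "unweighted"
    denominator_set: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("unweighted", "weighted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "weighted" and not self.denominator_set:
            raise ValueError("weighted mode requires denominator_set")


UNWEIGHTED = WeightingScheme("unweighted")


@dataclass
class LocusMetrics:
    element_id: str
    role: str  # full | LTR5 | LTR3 | INT
    length: int
    species_count: int
    species_per_nt: float
    expression_per_nt: float
    scheme: str


@dataclass
class ProfileMatrix:
    """Strand-resolved per-window densities along one locus.

    density[strand] has shape (n_windows,), in species (or reads) per nt;
    window_lengths sums to the locus length with entries differing by <= 1.
    """

    element_id: str
    role: str
    n_windows: int
    window_lengths: np.ndarray
    density: dict[str, np.ndarray]  # {"sense": ..., "antisense": ...}


def weight_hits(
    hitset: HitSet, scheme: WeightingScheme,
    denominator_hitsets: Mapping[str, HitSet] | None = None,
) -> float:
    """Return the per-location weight for a species under `scheme`.

    Un-weighted: 1.0. Weighted: 1/x with x taken from the species' HitSet on
    the denominator set (looked up in `denominator_hitsets` by species
    sequence; pass the tally hitset's own x only if the sets coincide).
    A species unmapped in the denominator universe has no defined weight.
    """
    if scheme.mode == "unweighted":
        return 1.0
    if denominator_hitsets is None:
        denom = hitset
    else:
        denom = denominator_hitsets.get(hitset.species)
    if denom is None or denom.x == 0:
        raise ValueError(
            f"species {hitset.species!r} unmapped in denominator set "
            f"{scheme.denominator_set!r}; 1/x undefined"
        )
    return 1.0 / denom.x


def hits_in_locus(hits: Iterable[Hit], reference_id: str,
                  interval: tuple[int, int], read_length: int) -> list[Hit]:
    """Hits whose full read span [position, position+read_length) lies within
    the locus interval on the given reference."""
    s, e = interval
    return [
        h for h in hits
        if h.reference_id == reference_id and h.position >= s and h.position + read_length <= e
    ]


def locus_metrics(
    element_id: str,
    role: str,
    reference_id: str,
    interval: tuple[int, int],
    hitsets: Mapping[str, HitSet],
    expressions: Mapping[str, int],
    scheme: WeightingScheme = UNWEIGHTED,
    denominator_hitsets: Mapping[str, HitSet] | None = None,
) -> LocusMetrics:
    """Species and expression densities of one locus.

    species_count counts each distinct species once, however many hits it has
    inside the locus. The weighted species density instead sums 1/x over the
    in-locus hits of every species (a species contributes the in-locus share
    of itself); under un-weighted counting the species density is
    species_count / length. expression_per_nt sums expression x weight over
    in-locus hits, divided by locus length.
    """
    length = interval[1] - interval[0]
    if length <= 0:
        raise ValueError(f"zero-length locus {element_id}/{role}")
    n_species = 0
    species_tally = 0.0
    expr_tally = 0.0
    for seq, hs in hitsets.items():
        inside = hits_in_locus(hs.hits, reference_id, interval, len(seq))
        if not inside:
            continue
        n_species += 1
        w = weight_hits(hs, scheme, denominator_hitsets)
        species_tally += len(inside) * w if scheme.mode == "weighted" else 1.0
        expr_tally += len(inside) * w * expressions.get(seq, 1)
    return LocusMetrics(
        element_id=element_id,
        role=role,
        length=length,
        species_count=n_species,
        species_per_nt=species_tally / length,
        expression_per_nt=expr_tally / length,
        scheme=scheme.mode if scheme.mode == "unweighted"
        else f"weighted:{scheme.denominator_set}",
    )


def window_bounds(length: int, n_windows: int) -> np.ndarray:
    """Window boundaries partitioning [0, length) into n contiguous windows
    of size floor(L/n) or ceil(L/n)."""
    return np.floor(np.arange(n_windows + 1) * length / n_windows).astype(int)


def window_profile(
    element_id: str,
    role: str,
    reference_id: str,
    interval: tuple[int, int],
    hitsets: Mapping[str, HitSet],
    expressions: Mapping[str, int],
    n_windows: int = 100,
    metric: str = "species",
    scheme: WeightingScheme = UNWEIGHTED,
    denominator_hitsets: Mapping[str, HitSet] | None = None,
) -> ProfileMatrix:
    """Strand-resolved windowed density profile of one locus.

    The locus is partitioned into `n_windows` contiguous windows whose sizes
    differ by at most one nucleotide. Each in-locus hit is assigned to the
    window containing its 5'-most coordinate within the locus (read start for
    sense hits, read end - 1 for antisense hits). Window values are totals
    divided by window length, separately per strand.
    """
    s, e = interval
    length = e - s
    if length < n_windows:
        raise ValueError(
            f"locus {element_id}/{role} is {length} nt < {n_windows} windows; "
            "use a smaller n_windows"
        )
    if metric not in ("species", "expression"):
        raise ValueError(f"unknown metric {metric!r}")
    bounds = window_bounds(length, n_windows)
    wlen = np.diff(bounds)
    totals = {st: np.zeros(n_windows) for st in ("sense", "antisense")}
    for seq, hs in hitsets.items():
        inside = hits_in_locus(hs.hits, reference_id, interval, len(seq))
        if not inside:
            continue
        w = weight_hits(hs, scheme, denominator_hitsets)
        value = w if metric == "species" else w * expressions.get(seq, 1)
        for h in inside:
            five_prime = h.position if h.strand == "sense" else h.position + len(seq) - 1
            offset = five_prime - s
            win = int(np.searchsorted(bounds, offset, side="right") - 1)
            totals[h.strand][win] += value
    return ProfileMatrix(
        element_id=element_id,
        role=role,
        n_windows=n_windows,
        window_lengths=wlen,
        density={st: totals[st] / wlen for st in totals},
    )


def um_ratio(hitsets: Iterable[HitSet]) -> dict[str, float | int | None]:
    """U and M species counts and proportions over mapped species.

    Unmapped species are excluded from the denominator. With zero mapped
    species the proportions are undefined and reported as None.
    """
    tags = [hs.um_tag for hs in hitsets]
    u = tags.count("U")
    m = tags.count("M")
    mapped = u + m
    return {
        "U": u,
        "M": m,
        "mapped": mapped,
        "U_proportion": (u / mapped) if mapped else None,
        "M_proportion": (m / mapped) if mapped else None,
    }
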