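"""Synthetic genomes, TE families, exemplars and sRNA libraries with truth
tables.

The generator produces, at desk scale, data with the statistical structure
that TE/sRNA mapping analyses assume:

* LTR retrotransposon families of differing copy number, where each copy's
  two LTRs start identical and diverge under a molecular clock (per-site
  substitution probability r*T on each LTR, so the expected LTR-LTR
  divergence is ~2rT);
* a hypervariable "palindrome-like" hotspot interval inside the LTR that
  mutates at an elevated rate, producing the high-variability columns that
  get N-masked in family consensus (exemplar) sequences;
* nested foreign-TE fragments ("contamination") inserted into a subset of
  elements, with a configurable median fragment length (default 189 nt);
* sRNA libraries of 21/22/24-nt perfect-substring reads whose per-element
  species production decays exponentially with element age, with hotspot
  positions over-sampled, and heavy-tailed read counts per species.

The mutation model is substitution-only (no indels), which keeps every copy
of a family positionally aligned to its ancestor: consensus building and
truth-table coordinates need no multiple alignment.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AnnotationRecord
from .mapping import revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one simulated LTR retrotransposon family."""

    name: str
    copy_number: int
    ltr_length: int = 1000
    int_length: int = 4000
    hotspot: tuple[int, int] = (100, 300)  # within the LTR
    age_law: str = "uniform"  # uniform | exponential
    age_params: tuple[float, ...] = (0.0, 3.0e6)  # years
    rate: float = 1.3e-8  # substitutions / site / year
    hotspot_rate_factor: float = 5.0
    # per-copy divergence of the hotspot from the family ancestor, applied
    # identically to both LTRs at insertion time: models the rapid turnover
    # of the palindrome-rich region between transposition events without
    # perturbing the LTR-pair clock
    hotspot_variant_divergence: float = 0.6

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.rate <= 0:
            raise ValueError("substitution rate must be positive")
        lo, hi = self.hotspot
        if not (0 <= lo < hi <= self.ltr_length):
            raise ValueError("hotspot must lie within [0, ltr_length)")

    @property
    def element_length(self) -> int:
        return 2 * self.ltr_length + self.int_length


@dataclass(frozen=True)
class SilencingModel:
    """How much sRNA an element of a given age produces.

    base_rate maps read length (nt) to expected species per nucleotide of an
    age-0 element; production decays as exp(-age_decay * T). Hotspot start
    positions are over-sampled by hotspot_enrichment. Read counts per species
    follow a geometric law with the given mean (heavy right tail).
    """

    base_rate: Mapping[int, float] = field(
        default_factory=lambda: {21: 0.010, 22: 0.010, 24: 0.020}
    )
    age_decay: float = 5.0e-7  # per year
    hotspot_enrichment: float = 5.0
    expression_mean: float = 5.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_rate.values()) or self.age_decay < 0:
            raise ValueError("rates must be >= 0")
        if self.hotspot_enrichment < 1:
            raise ValueError("hotspot enrichment must be >= 1")


@dataclass
class SimulatedElement:
    element_id: str
    family: str
    age: float  # years
    sequence: str  # full element, possibly with a nested fragment inserted
    ltr5: tuple[int, int]
    int_domain: tuple[int, int]
    ltr3: tuple[int, int]
    hotspot: tuple[int, int] = (100, 300)  # relative to each LTR start


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic FASTA/GFF/FASTQ."""

    elements: pd.DataFrame  # element_id, family, age, genome coords, sub-loci
    fragments: pd.DataFrame  # host element_id, donor family, genome interval
    species: pd.DataFrame | None = None  # per generated species: origin info


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(seq_arr: np.ndarray, p_site: np.ndarray | float,
            rng: np.random.Generator) -> np.ndarray:
    """Substitution-only mutation: each site flips to one of the other three
    bases with its per-site probability."""
    n = len(seq_arr)
    hit = rng.random(n) < p_site
    out = seq_arr.copy()
    idx = np.nonzero(hit)[0]
    if len(idx):
        # draw a base != current by offsetting 1..3 in base order
        cur = np.searchsorted(BASES, out[idx])
        offs = rng.integers(1, 4, size=len(idx))
        out[idx] = BASES[(cur + offs) % 4]
    return out


def simulate_family(spec: FamilySpec, seed: int) -> list[SimulatedElement]:
    """Simulate one family: an ancestral element and `copy_number` aged copies.

    Each copy draws an age T from the family's age law. Its hotspot first
    receives a copy-specific variant (per-site substitution probability
    `hotspot_variant_divergence` away from the ancestor), written identically
    into both LTRs — the variant the element carried at insertion, which
    makes the hotspot hypervariable *across* copies while leaving the
    LTR-pair identity at insertion intact. Both LTRs then independently
    accumulate clock substitutions at per-site probability r*T (hotspot
    sites at hotspot_rate_factor * r * T, capped at 1), and the internal
    domain at r*T. Copies stay the same length as, and positionally aligned
    to, the ancestor.
    """
    rng = np.random.default_rng(seed)
    anc_ltr = np.array(list(random_sequence(spec.ltr_length, rng)), dtype="S1")
    anc_int = np.array(list(random_sequence(spec.int_length, rng)), dtype="S1")
    if spec.age_law == "uniform":
        ages = rng.uniform(*spec.age_params, size=spec.copy_number)
    elif spec.age_law == "exponential":
        ages = rng.exponential(spec.age_params[0], size=spec.copy_number)
    else:
        raise ValueError(f"unknown age law {spec.age_law!r}")
    p_ltr_base = np.full(spec.ltr_length, 1.0)
    p_ltr_base[spec.hotspot[0] : spec.hotspot[1]] = spec.hotspot_rate_factor
    out = []
    L, I = spec.ltr_length, spec.int_length
    hot = slice(*spec.hotspot)
    for i, T in enumerate(ages):
        copy_anc = anc_ltr.copy()
        if spec.hotspot_variant_divergence > 0:
            copy_anc[hot] = _mutate(anc_ltr[hot], spec.hotspot_variant_divergence, rng)
        p_ltr = np.minimum(p_ltr_base * spec.rate * T, 1.0)
        p_int = min(spec.rate * T, 1.0)
        ltr5 = _mutate(copy_anc, p_ltr, rng)
        ltr3 = _mutate(copy_anc, p_ltr, rng)
        intd = _mutate(anc_int, p_int, rng)
        seq = np.concatenate([ltr5, intd, ltr3]).tobytes().decode()
        out.append(SimulatedElement(
            element_id=f"{spec.name}_{i:04d}",
            family=spec.name,
            age=float(T),
            sequence=seq,
            ltr5=(0, L),
            int_domain=(L, L + I),
            ltr3=(L + I, 2 * L + I),
            hotspot=spec.hotspot,
        ))
    return out


def assemble_genome(
    background_length: int,
    families: Sequence[FamilySpec],
    nesting_rate: float = 0.0,
    seed: int = 0,
    fragment_median: int = 189,
    fragment_sigma: float = 0.35,
) -> tuple[dict[str, str], list[AnnotationRecord], TruthTable, dict[str, list[SimulatedElement]]]:
    """Place simulated elements on a random background chromosome.

    Elements are placed in order at non-overlapping positions with random
    gaps. With probability `nesting_rate`, an element receives one nested
    fragment: a log-normally distributed length (median `fragment_median` nt)
    cut from the ancestral sequence of a *different* family and inserted at a
    random position inside the host's internal domain (LTRs stay intact so
    LTR-pair age estimation is unaffected). Fragments are recorded in the
    truth table; the GFF annotation spans each full element including any
    nested fragment.

    Returns (genome {chrom: seq}, annotations, truth, elements-by-family).
    The per-family element lists hold the *clean* (pre-nesting) sequences,
    e.g. for exemplar building.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[SimulatedElement]] = {}
    for k, spec in enumerate(families):
        by_family[spec.name] = simulate_family(spec, seed=int(rng.integers(2**31)))
    elements = [el for fam in by_family.values() for el in fam]
    rng.shuffle(elements)

    frag_rows = []
    final_seqs: list[str] = []
    sub_shifts: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = []
    fam_index = {spec.name: spec for spec in families}
    for el in elements:
        seq = el.sequence
        l5, intd, l3 = el.ltr5, el.int_domain, el.ltr3
        if len(families) > 1 and rng.random() < nesting_rate:
            donor_names = [f.name for f in families if f.name != el.family]
            donor_name = donor_names[int(rng.integers(len(donor_names)))]
            donor_copies = by_family[donor_name]
            donor_seq = donor_copies[int(rng.integers(len(donor_copies)))].sequence
            flen = int(round(fragment_median * np.exp(rng.normal(0.0, fragment_sigma))))
            flen = max(30, min(flen, len(donor_seq)))
            fstart = int(rng.integers(0, len(donor_seq) - flen + 1))
            frag = donor_seq[fstart : fstart + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            ins = int(rng.integers(intd[0], intd[1]))
            seq = seq[:ins] + frag + seq[ins:]
            intd = (intd[0], intd[1] + flen)
            l3 = (l3[0] + flen, l3[1] + flen)
            frag_rows.append({
                "host_id": el.element_id, "donor_family": donor_name,
                "offset_in_element": ins, "length": flen,
            })
        final_seqs.append(seq)
        sub_shifts.append((l5, intd, l3))

    total = sum(len(s) for s in final_seqs)
    if total > background_length:
        raise ValueError(
            f"background of {background_length} nt cannot host {total} nt of elements"
        )
    free = background_length - total
    starts_in_free = np.sort(rng.integers(0, free + 1, size=len(final_seqs)))
    chrom_parts: list[str] = []
    annotations: list[AnnotationRecord] = []
    elem_rows = []
    cursor = 0  # in free-background coordinates
    gpos = 0
    chrom = "chr1"
    frag_by_host = {r["host_id"]: r for r in frag_rows}
    for el, seq, (l5, intd, l3), fs in zip(elements, final_seqs, sub_shifts,
                                           starts_in_free):
        gap = int(fs) - cursor
        chrom_parts.append(random_sequence(gap, rng))
        gpos += gap
        cursor = int(fs)
        start = gpos
        chrom_parts.append(seq)
        gpos += len(seq)
        annotations.append(AnnotationRecord(
            element_id=el.element_id, family=el.family, reference_id=chrom,
            interval=(start, start + len(seq)), strand="+",
            sub_loci=[
                ("LTR5", (start + l5[0], start + l5[1])),
                ("INT", (start + intd[0], start + intd[1])),
                ("LTR3", (start + l3[0], start + l3[1])),
            ],
        ))
        row = {
            "element_id": el.element_id, "family": el.family, "age": el.age,
            "reference_id": chrom, "start": start, "end": start + len(seq),
        }
        if el.element_id in frag_by_host:
            fr = frag_by_host[el.element_id]
            fr["reference_id"] = chrom
            fr["start"] = start + fr["offset_in_element"]
            fr["end"] = fr["start"] + fr["length"]
        elem_rows.append(row)
    chrom_parts.append(random_sequence(background_length - total - cursor, rng))
    genome = {chrom: "".join(chrom_parts)}
    truth = TruthTable(
        elements=pd.DataFrame(elem_rows),
        fragments=pd.DataFrame(frag_rows, columns=[
            "host_id", "donor_family", "offset_in_element", "length",
            "reference_id", "start", "end",
        ]),
    )
    return genome, sorted(annotations, key=lambda a: a.interval), truth, by_family


def build_exemplar(sequences: Sequence[str], mask_identity_threshold: float = 0.6) -> str:
    """Column-majority consensus with N at unresolved columns.

    All input sequences must have equal length (the simulator's
    substitution-only model guarantees positional alignment). Per column the
    majority base is emitted if its frequency is >= the threshold, else N;
    hypervariable regions therefore surface as runs of N, as in real exemplar
    consensuses.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences for a consensus")
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("sequences must have equal length")
    arr = np.array([list(s.upper()) for s in sequences], dtype="S1")
    n, L = arr.shape
    out = np.empty(L, dtype="S1")
    for j in range(L):
        col = arr[:, j]
        bases, counts = np.unique(col, return_counts=True)
        k = int(np.argmax(counts))  # ties: first in sorted base order
        out[j] = bases[k] if counts[k] / n >= mask_identity_threshold else b"N"
    return out.tobytes().decode()


def simulate_srna_library(
    elements: Sequence[SimulatedElement],
    model: SilencingModel,
    seed: int,
    read_lengths: Sequence[int] | None = None,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Generate an sRNA library from simulated elements.

    For each element and read length L, the number of generated species is
    Poisson with mean base_rate[L] * element length * exp(-age_decay * T).
    Start positions are drawn with hotspot starts (both LTR copies) weighted
    by the enrichment factor; each species is the exact substring on the
    sense strand or its reverse complement (probability 1/2 each). Expression
    is 1 + Geometric (mean `expression_mean`). Elements shorter than L are
    skipped.

    Returns (reads as [(sequence, count)...] aggregated per generation event,
    species truth table with generating element, locus role, strand, offset,
    and a hotspot-origin flag).
    """
    rng = np.random.default_rng(seed)
    lengths = sorted(read_lengths or model.base_rate.keys())
    rows = []
    reads: list[tuple[str, int]] = []
    for el in elements:
        seq = el.sequence
        n_nt = len(seq)
        agefac = float(np.exp(-model.age_decay * el.age))
        # start-position weights: hotspot starts (in both LTRs) enriched
        for L in lengths:
            if n_nt < L:
                continue
            lam = model.base_rate.get(L, 0.0) * n_nt * agefac
            n_species = int(rng.poisson(lam))
            if n_species == 0:
                continue
            weights = np.ones(n_nt - L + 1)
            for ltr_iv in (el.ltr5, el.ltr3):
                lo = max(0, ltr_iv[0] + el.hotspot[0])
                hi = min(n_nt - L + 1, ltr_iv[0] + el.hotspot[1] - L + 1)
                if hi > lo:
                    weights[lo:hi] *= model.hotspot_enrichment
            weights /= weights.sum()
            starts = rng.choice(len(weights), size=n_species, p=weights)
            for st in starts:
                st = int(st)
                sub = seq[st : st + L]
                strand = "sense" if rng.random() < 0.5 else "antisense"
                read = sub if strand == "sense" else revcomp(sub)
                expr = int(rng.geometric(1.0 / model.expression_mean))
                reads.append((read, expr))
                rows.append({
                    "sequence": read, "element_id": el.element_id,
                    "family": el.family, "length": L, "offset": st,
                    "strand": strand, "role": _role_of(st, L, el),
                    "hotspot_origin": _in_hotspot(st, L, el),
                    "expression": expr,
                })
    truth = pd.DataFrame(rows, columns=[
        "sequence", "element_id", "family", "length", "offset", "strand",
        "role", "hotspot_origin", "expression",
    ])
    return reads, truth


def _role_of(start: int, L: int, el: SimulatedElement) -> str:
    for role, iv in (("LTR5", el.ltr5), ("INT", el.int_domain), ("LTR3", el.ltr3)):
        if start >= iv[0] and start + L <= iv[1]:
            return role
    return "boundary"


def _in_hotspot(start: int, L: int, el: SimulatedElement) -> bool:
    for iv in (el.ltr5, el.ltr3):
        if start >= iv[0] + el.hotspot[0] and start + L <= iv[0] + el.hotspot[1]:
            return True
    return False


def write_fastq(reads: Iterable[tuple[str, int]], path) -> int:
    """Expand (sequence, count) species into a FASTQ; returns reads written."""
    n = 0
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads):
            for j in range(count):
                fh.write(f"@r{i}_{j}\n{seq}\n+\n{'I' * len(seq)}\n")
                n += 1
    return n
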