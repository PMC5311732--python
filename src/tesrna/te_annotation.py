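"""Full-length element selection, LTR divergence and insertion age, and
foreign-fragment (contamination) screening.

The insertion age of an LTR retrotransposon follows from the molecular-clock
property of its long terminal repeats: the two LTRs are identical at
insertion and diverge independently afterwards, so for divergence K between
the LTR pair and substitution rate r (substitutions/site/year),

    T = K / (2 r)

with r defaulting to 1.3e-8 substitutions per site per year, the rate
commonly applied to grass LTR retrotransposons. K may be the raw p-distance
or a multiple-hit correction (Jukes-Cantor 1969 or Kimura 2-parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .mapping import VALID_BASES, revcomp

DEFAULT_SUBSTITUTION_RATE = 1.3e-8  # substitutions / site / year

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class LengthPeak:
    mode_length: float
    window: tuple[float, float]
    count: int


@dataclass(frozen=True)
class AgeEstimate:
    element_id: str
    n_sites: int
    n_diff: int
    p_distance: float
    model: str  # p | JC69 | K2P
    K: float | None  # None when divergence is undefined (saturation)
    rate: float
    T: float | None  # years


@dataclass(frozen=True)
class ContaminationHit:
    host_id: str
    donor_id: str
    donor_family: str
    host_interval: tuple[int, int]
    match_length: int
    identity: float


# ---------------------------------------------------------------------------
# length-distribution peak picking


def length_peaks(lengths: Sequence[int], bin_width: int = 100,
                 min_prominence: int = 0) -> list[LengthPeak]:
    """Find peaks in a length frequency distribution.

    The lengths are histogrammed at `bin_width`; a peak is a bin whose count
    strictly exceeds both neighbouring bins (absent neighbours count 0) and
    exceeds `min_prominence`. The suggested full-length selection window is
    the peak bin +/- one bin; the choice of final window is the caller's.
    """
    if not len(lengths):
        raise ValueError("need at least one length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = (min(lengths) // bin_width) * bin_width
    hi = (max(lengths) // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    padded = np.concatenate([[0], counts, [0]])
    peaks = []
    for i in range(len(counts)):
        c = padded[i + 1]
        if c > padded[i] and c > padded[i + 2] and c > min_prominence:
            centre = edges[i] + bin_width / 2
            peaks.append(LengthPeak(
                mode_length=centre,
                window=(float(edges[i] - bin_width), float(edges[i + 1] + bin_width)),
                count=int(c),
            ))
    return peaks


def select_fulllength_candidates(annotations: Iterable, window: tuple[float, float]) -> list:
    """Elements whose length falls in [low, high] inclusive.

    Accepts AnnotationRecord-like objects (with .length) or plain ints.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window low must be < high")
    out = []
    for a in annotations:
        L = a.length if hasattr(a, "length") else a
        if lo <= L <= hi:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# LTR pair alignment and divergence

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -1


def align_ltr_pair(ltr5: str, ltr3: str) -> tuple[str, str]:
    """Global pairwise alignment of the two LTRs of one element.

    Affine gap costs (match +1, mismatch -1, gap open -4, extend -1); the
    first optimal alignment under the aligner's deterministic traversal order
    is returned as a pair of gapped strings of equal length.
    """
    a, b = ltr5.upper(), ltr3.upper()
    if not a or not b:
        raise ValueError("LTR sequences must be non-empty")
    aln = _aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


def alignment_score(ltr5: str, ltr3: str) -> float:
    """Optimal global alignment score under the aligner's scoring scheme."""
    return float(_aligner.score(ltr5.upper(), ltr3.upper()))


def ltr_divergence(aligned5: str, aligned3: str, model: str = "K2P",
                   element_id: str = "", rate: float = DEFAULT_SUBSTITUTION_RATE,
                   ) -> AgeEstimate:
    """Divergence K of an aligned LTR pair, with the chosen correction.

    Columns containing a gap or an ambiguous base are excluded from the site
    count n. p = differing/n. Corrections:

    * ``p``    — K = p (no correction);
    * ``JC69`` — K = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4;
    * ``K2P``  — K = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q) with P the transition
      and Q the transversion proportion; undefined when an argument is
      non-positive.

    Saturated alignments yield K = None (and T = None downstream); the
    divergence is never silently clamped.
    """
    if len(aligned5) != len(aligned3):
        raise ValueError("aligned sequences must have equal length")
    n = diff = transitions = transversions = 0
    for c5, c3 in zip(aligned5.upper(), aligned3.upper()):
        if c5 not in VALID_BASES or c3 not in VALID_BASES:
            continue
        n += 1
        if c5 != c3:
            diff += 1
            if (c5 in _PURINES) == (c3 in _PURINES):
                transitions += 1
            else:
                transversions += 1
    if n == 0:
        raise ValueError("no comparable sites in alignment")
    p = diff / n
    K: float | None
    if model == "p":
        K = p
    elif model == "JC69":
        arg = 1 - 4 * p / 3
        K = -0.75 * math.log(arg) if arg > 0 else None
    elif model == "K2P":
        P, Q = transitions / n, transversions / n
        a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
        K = (-0.5 * math.log(a1) - 0.25 * math.log(a2)) if (a1 > 0 and a2 > 0) else None
    else:
        raise ValueError(f"unknown model {model!r}")
    T = estimate_age(K, rate) if K is not None else None
    return AgeEstimate(element_id=element_id, n_sites=n, n_diff=diff,
                       p_distance=p, model=model, K=K, rate=rate, T=T)


def estimate_age(K: float, rate: float = DEFAULT_SUBSTITUTION_RATE) -> float:
    """Insertion age in years, T = K / (2 r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if K < 0:
        raise ValueError("divergence K must be non-negative")
    return K / (2 * rate)


def age_ltr_pair(ltr5: str, ltr3: str, model: str = "K2P",
                 element_id: str = "",
                 rate: float = DEFAULT_SUBSTITUTION_RATE) -> AgeEstimate:
    """Convenience: align an LTR pair and estimate its insertion age."""
    a5, a3 = align_ltr_pair(ltr5, ltr3)
    return ltr_divergence(a5, a3, model=model, element_id=element_id, rate=rate)


# ---------------------------------------------------------------------------
# contamination screening


_XDROP = 10  # stop extending once the score falls this far below its maximum


def _extend_side(host: str, donor: str, hpos: int, dpos: int, step: int) -> tuple[int, int]:
    """Score-maximising ungapped extension on one side of a seed.

    Walks away from the seed one base at a time (step = -1 left, +1 right)
    scoring +1/match, -1/mismatch, and keeps the prefix with the maximum
    score; gives up once the running score drops _XDROP below the maximum.
    Returns (extension length, matches within it).
    """
    best_len = best_matches = 0
    score = best_score = 0
    matches = 0
    i = 1
    while 0 <= hpos + step * i < len(host) and 0 <= dpos + step * i < len(donor):
        if host[hpos + step * i] == donor[dpos + step * i]:
            matches += 1
            score += 1
        else:
            score -= 1
        if score > best_score:
            best_score, best_len, best_matches = score, i, matches
        if score < best_score - _XDROP:
            break
        i += 1
    return best_len, best_matches


def _extend(host: str, donor: str, hpos: int, dpos: int, seed_len: int,
            min_identity: float) -> tuple[int, int, int] | None:
    """Ungapped extension of an exact seed match in both directions.

    Each side is extended to its score maximum (X-drop); the extended match
    is kept only if its overall identity is >= min_identity. Returns
    (host_start, host_end, n_matches) or None.
    """
    left, ml = _extend_side(host, donor, hpos, dpos, -1)
    right, mr = _extend_side(host, donor, hpos + seed_len - 1, dpos + seed_len - 1, +1)
    start, end = hpos - left, hpos + seed_len + right
    nmatch = seed_len + ml + mr
    if nmatch / (end - start) < min_identity:
        return None
    return start, end, nmatch


def contamination_screen(
    hosts: Mapping[str, str],
    donors: Mapping[str, str],
    donor_families: Mapping[str, str] | None = None,
    seed_length: int = 20,
    min_match: int = 100,
    min_identity: float = 0.8,
) -> list[ContaminationHit]:
    """Screen host elements for nested fragments of foreign (donor) families.

    Internal seed-and-extend: every exact `seed_length`-mer shared between a
    host and a donor (either donor strand) is extended ungapped in both
    directions while the running identity stays >= `min_identity`; extended
    matches of at least `min_match` nt are reported, with overlapping matches
    per (host, donor) pair merged. Donor seeds containing N are skipped.
    """
    donor_families = donor_families or {}
    seed_index: dict[str, list[tuple[str, int, str]]] = {}
    for did, dseq in donors.items():
        for strand, seq in (("+", dseq.upper()), ("-", revcomp(dseq.upper()))):
            for pos in range(len(seq) - seed_length + 1):
                word = seq[pos : pos + seed_length]
                if set(word) <= VALID_BASES:
                    seed_index.setdefault(word, []).append((did, pos, strand))
    raw: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for hid, hseq in hosts.items():
        hseq = hseq.upper()
        for hpos in range(len(hseq) - seed_length + 1):
            word = hseq[hpos : hpos + seed_length]
            for did, dpos, strand in seed_index.get(word, ()):
                dseq = donors[did].upper() if strand == "+" else revcomp(donors[did].upper())
                ext = _extend(hseq, dseq, hpos, dpos, seed_length, min_identity)
                if ext is not None and ext[1] - ext[0] >= min_match:
                    raw.setdefault((hid, did), []).append(ext)
    hits: list[ContaminationHit] = []
    for (hid, did), spans in raw.items():
        spans.sort()
        # merge overlapping extended matches; identity of a merged span is
        # the best identity among its components
        merged: list[list[float]] = []
        for start, end, nmatch in spans:
            ident = nmatch / (end - start)
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
                merged[-1][2] = max(merged[-1][2], ident)
            else:
                merged.append([start, end, ident])
        for start, end, ident in merged:
            hits.append(ContaminationHit(
                host_id=hid,
                donor_id=did,
                donor_family=donor_families.get(did, did),
                host_interval=(int(start), int(end)),
                match_length=int(end - start),
                identity=min(1.0, ident),
            ))
    hits.sort(key=lambda h: (h.host_id, h.donor_id, h.host_interval))
    return hits


def import_blast_hits(path, max_evalue: float = 1e-20,
                      donor_families: Mapping[str, str] | None = None,
                      min_match: int = 0) -> list[ContaminationHit]:
    """Import external BLASTN tabular (12-column, -outfmt 6) foreign-fragment
    hits, keeping those with E-value <= max_evalue (default 1e-20).

    Column convention: query = donor exemplar, subject = host element.
    """
    import pandas as pd

    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    donor_families = donor_families or {}
    hits = []
    for row in df.itertuples(index=False):
        if row.evalue > max_evalue or row.length < min_match:
            continue
        lo, hi = sorted((int(row.sstart), int(row.send)))
        hits.append(ContaminationHit(
            host_id=str(row.sseqid),
            donor_id=str(row.qseqid),
            donor_family=donor_families.get(str(row.qseqid), str(row.qseqid)),
            host_interval=(lo - 1, hi),
            match_length=int(row.length),
            identity=float(row.pident) / 100.0,
        ))
    return hits
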