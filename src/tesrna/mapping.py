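"""Exact, zero-mismatch, all-hits mapping of read species to reference sets.

Reads are matched as perfect substrings of the references on both strands,
mirroring an aligner run with zero mismatches and all alignments reported.
At desk scale a hash index over the requested read lengths suffices: for each
length L every L-substring of every reference (not containing N) is recorded
with all of its (reference, position) occurrences.

Conventions:

* positions are 0-based starts on the reference forward strand;
* an antisense hit means the reverse complement of the species occurs at
  that position (the species matches the minus strand);
* a species that equals its own reverse complement (a palindrome) yields
  both a sense and an antisense hit at the same position — two distinct
  locations;
* x, the location count of a species in a reference set, is the number of
  distinct (reference, position, strand) triples; U means x == 1, M means
  x > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Hit:
    """One zero-mismatch mapping location."""

    reference_id: str
    position: int
    strand: str  # "sense" | "antisense"


@dataclass
class HitSet:
    """All locations of one species in one reference set, with its U/M tag."""

    species: str
    reference_set: str
    hits: list[Hit] = field(default_factory=list)

    @property
    def x(self) -> int:
        """Total number of mapping locations."""
        return len(self.hits)

    @property
    def um_tag(self) -> str:
        if self.x == 0:
            return "unmapped"
        return "U" if self.x == 1 else "M"


class ExactIndex:
    """Hash index of all L-mers of a reference collection, for L in `lengths`.

    Substrings containing any non-ACGT character are not indexed, so species
    containing N can never map — consistent with exact matching over A/C/G/T.
    """

    def __init__(self, references: Mapping[str, str], lengths: Iterable[int],
                 label: str = "custom"):
        self.label = label
        self.lengths = sorted(set(int(L) for L in lengths))
        if not self.lengths:
            raise ValueError("at least one read length is required")
        self.reference_lengths = {name: len(seq) for name, seq in references.items()}
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}
        for L in self.lengths:
            table: dict[str, list[tuple[str, int]]] = {}
            for name, seq in references.items():
                seq = seq.upper()
                if len(seq) < L:
                    logger.info("reference %s shorter than %d nt; skipped for this length",
                                name, L)
                    continue
                # positions of invalid characters, to skip windows overlapping them
                bad = [i for i, c in enumerate(seq) if c not in VALID_BASES]
                bad_ptr = 0
                next_bad = bad[0] if bad else len(seq)
                for pos in range(len(seq) - L + 1):
                    while bad_ptr < len(bad) and bad[bad_ptr] < pos:
                        bad_ptr += 1
                    next_bad = bad[bad_ptr] if bad_ptr < len(bad) else len(seq)
                    if next_bad < pos + L:
                        continue
                    table.setdefault(seq[pos : pos + L], []).append((name, pos))
            self._tables[L] = table

    def occurrences(self, word: str) -> list[tuple[str, int]]:
        """All (reference, position) occurrences of `word` on the forward strand."""
        L = len(word)
        if L not in self._tables:
            raise KeyError(f"length {L} not indexed (have {self.lengths})")
        return self._tables[L].get(word, [])


def map_species(sequence: str, index: ExactIndex) -> HitSet:
    """Map one species against an index: all-hits, both strands, x and tag.

    Sense hits are forward-strand occurrences of the sequence; antisense hits
    are forward-strand occurrences of its reverse complement, reported at the
    occurrence position with strand="antisense". x = 0 is a valid outcome.
    """
    seq = sequence.upper()
    hits: set[Hit] = set()
    if set(seq) <= VALID_BASES and len(seq) in index._tables:
        for ref, pos in index.occurrences(seq):
            hits.add(Hit(ref, pos, "sense"))
        for ref, pos in index.occurrences(revcomp(seq)):
            hits.add(Hit(ref, pos, "antisense"))
    return HitSet(species=sequence, reference_set=index.label, hits=sorted(hits))


def map_table(species: Iterable[str], index: ExactIndex) -> dict[str, HitSet]:
    """Map many species; returns {sequence: HitSet}."""
    return {seq: map_species(seq, index) for seq in species}


def classify_um(hitsets: Mapping[str, HitSet]) -> dict[str, str]:
    """Per-reference-set U/M tags for one species.

    Input maps a reference-set label to the HitSet computed on that set; tags
    are independent per set (the same species may be U on exemplars and M on
    the genome).
    """
    return {label: hs.um_tag for label, hs in hitsets.items()}


def filter_blocklist(
    species: Sequence, blocklist: Iterable[str]
) -> tuple[list, int]:
    """Drop species whose sequence exactly matches a blocklist entry on
    either strand (miRNA/tRNA/rRNA/snoRNA removal).

    Accepts SpeciesRecord-like objects (with .sequence) or plain strings.
    Returns (kept, n_removed).
    """
    block = {s.upper() for s in blocklist}
    block |= {revcomp(s) for s in block}
    kept, removed = [], 0
    for rec in species:
        seq = (rec.sequence if hasattr(rec, "sequence") else rec).upper()
        if seq in block:
            removed += 1
        else:
            kept.append(rec)
    if removed:
        logger.info("filter_blocklist: removed %d species", removed)
    return kept, removed
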