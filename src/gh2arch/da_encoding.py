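"""Binary encoding of protein domain architectures.

A domain architecture (DA) is the N-terminal to C-terminal ordered list
of identified domains on a protein. Across a dataset, the distinct
(domain, occurrence-ordinal) pairs form a repeat-aware vocabulary: slot
``(d, k)`` stands for "at least k tandem copies of domain d". Each
protein is then summarised as a binary vector over those slots — bit
``(d, k)`` is set iff the protein carries k or more copies of ``d``.

Order along the protein is carried by the :class:`Architecture` itself;
the vocabulary's canonical slot order reflects the typical N→C position
of each domain across the dataset, so that the vector layout reads
roughly N-terminal to C-terminal even though presence bits alone cannot
encode arbitrary per-protein orderings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .annot_io import DomainHit

# Hits overlapping by more than this fraction of the shorter span are
# treated as competing models for the same region.
OVERLAP_FRACTION = 0.5


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class Architecture:
    """Ordered (N→C) domain composition of one protein after overlap
    resolution."""

    seq_id: str
    elements: tuple[str, ...]
    element_spans: tuple[tuple[int, int], ...]
    seq_length: int = 0

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.element_spans):
            raise EncodingError("elements and spans length mismatch")
        starts = [s for s, _ in self.element_spans]
        if starts != sorted(starts):
            raise EncodingError("architecture elements not sorted by start")
        # minor envelope overlaps survive resolution; only majority
        # overlap (the competing-model case) violates the invariant
        for (s1, e1), (s2, e2) in zip(self.element_spans, self.element_spans[1:]):
            ov = min(e1, e2) - max(s1, s2) + 1
            shorter = min(e1 - s1 + 1, e2 - s2 + 1)
            if ov > OVERLAP_FRACTION * shorter:
                raise EncodingError(
                    f"{self.seq_id}: majority-overlapping spans after "
                    f"resolution ({s1}-{e1} vs {s2}-{e2})"
                )

    def occurrences(self) -> Counter:
        """Multiset of domain names, e.g. {'A': 2, 'B': 1}."""
        return Counter(self.elements)

    @property
    def last_domain_end(self) -> int:
        """1-based end of the C-terminal-most identified domain (0 if none)."""
        return self.element_spans[-1][1] if self.element_spans else 0


@dataclass(frozen=True)
class DomainVocabulary:
    """Canonically ordered (domain, ordinal) slots covering a dataset."""

    slots: tuple[tuple[str, int], ...]
    _index: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        seen = set(self.slots)
        if len(seen) != len(self.slots):
            raise EncodingError("duplicate vocabulary slots")
        for domain, k in self.slots:
            if k > 1 and (domain, k - 1) not in seen:
                raise EncodingError(
                    f"slot ({domain}, {k}) present without ({domain}, {k - 1})"
                )
        object.__setattr__(
            self, "_index", {slot: i for i, slot in enumerate(self.slots)}
        )

    def __len__(self) -> int:
        return len(self.slots)

    def index_of(self, domain: str, ordinal: int) -> int:
        try:
            return self._index[(domain, ordinal)]
        except KeyError:
            raise EncodingError(
                f"slot ({domain}, {ordinal}) not in vocabulary"
            ) from None

    def labels(self) -> list[str]:
        """Slot labels in the ``Domain_k`` style used for matrix export."""
        return [f"{d}_{k}" for d, k in self.slots]


@dataclass(frozen=True)
class DAVector:
    seq_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise EncodingError("vector bits must be 0/1")


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy overlap resolution among hits of one sequence.

    Hits are ranked by (model_coverage desc, span desc, domain name asc);
    a hit is kept unless it overlaps an already-kept hit by more than
    half of the shorter span.
    """
    ranked = sorted(
        hits, key=lambda h: (-h.model_coverage, -h.span, h.domain, h.env_start)
    )
    kept: list[DomainHit] = []
    for hit in ranked:
        clash = False
        for other in kept:
            ov = min(hit.env_end, other.env_end) - max(hit.env_start, other.env_start) + 1
            if ov > 0 and ov > OVERLAP_FRACTION * min(hit.span, other.span):
                clash = True
                break
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.env_start, h.env_end, h.domain))
    return kept


def build_architecture(
    hits: Sequence[DomainHit], seq_length: int = 0
) -> Architecture:
    """Order one sequence's hits N→C and resolve overlapping annotations.

    Tandem repeats survive as repeated elements. An empty hit list gives
    an empty architecture.
    """
    if not hits:
        return Architecture("", (), (), seq_length)
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) != 1:
        raise EncodingError(f"hits from multiple sequences: {sorted(seq_ids)}")
    resolved = resolve_overlaps(hits)
    return Architecture(
        seq_id=hits[0].seq_id,
        elements=tuple(h.domain for h in resolved),
        element_spans=tuple((h.env_start, h.env_end) for h in resolved),
        seq_length=seq_length,
    )


def build_vocabulary(architectures: Iterable[Architecture]) -> DomainVocabulary:
    """Derive the repeat-aware slot vocabulary from a set of architectures.

    One slot per (domain, ordinal) up to the maximum tandem count seen.
    Domains are ordered by their median relative midpoint position
    (midpoint / sequence length) across the dataset, so the slot layout
    tracks typical N→C placement; ordinals ascend within a domain. The
    result is invariant to the input order of the architectures.
    """
    archs = list(architectures)
    if not archs:
        raise EncodingError("cannot build a vocabulary from zero architectures")
    max_repeat: dict[str, int] = {}
    rel_positions: dict[str, list[float]] = {}
    for arch in archs:
        for domain, count in arch.occurrences().items():
            max_repeat[domain] = max(max_repeat.get(domain, 0), count)
        length = arch.seq_length or (arch.element_spans[-1][1] if arch.element_spans else 1)
        for domain, (start, end) in zip(arch.elements, arch.element_spans):
            rel_positions.setdefault(domain, []).append(
                ((start + end) / 2) / max(length, 1)
            )
    ordered = sorted(
        max_repeat, key=lambda d: (median(rel_positions[d]), d)
    )
    slots = tuple(
        (domain, k) for domain in ordered for k in range(1, max_repeat[domain] + 1)
    )
    return DomainVocabulary(slots)


def encode(architecture: Architecture, vocabulary: DomainVocabulary) -> DAVector:
    """Binary vector: bit (d, k) = 1 iff the protein has ≥ k copies of d."""
    occ = architecture.occurrences()
    bits = [0] * len(vocabulary)
    for domain, count in occ.items():
        if (domain, 1) not in vocabulary._index:
            raise EncodingError(
                f"{architecture.seq_id}: domain {domain!r} not in vocabulary"
            )
        for k in range(1, count + 1):
            bits[vocabulary.index_of(domain, k)] = 1
    return DAVector(architecture.seq_id, tuple(bits))


def decode(vector: DAVector, vocabulary: DomainVocabulary) -> Counter:
    """Recover the occurrence multiset encoded in a vector."""
    if len(vector.bits) != len(vocabulary):
        raise EncodingError("vector length does not match vocabulary size")
    counts: Counter = Counter()
    for bit, (domain, k) in zip(vector.bits, vocabulary.slots):
        if bit:
            if k > 1 and counts[domain] != k - 1:
                raise EncodingError(
                    f"non-monotone repeat bits for {domain!r} in {vector.seq_id}"
                )
            counts[domain] = k
    return counts


def write_vector_matrix(
    vectors: Iterable[DAVector], vocabulary: DomainVocabulary, path
) -> None:
    """Export the binary matrix as TSV: header = slot labels, one row per
    sequence."""
    with open(path, "w") as fh:
        fh.write("seq_id\t" + "\t".join(vocabulary.labels()) + "\n")
        for vec in vectors:
            fh.write(vec.seq_id + "\t" + "\t".join(map(str, vec.bits)) + "\n")
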