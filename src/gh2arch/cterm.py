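"""C-terminal extension analysis.

Type-4 and type-5 architectures end in stretches with no identified
domain. This module extracts those stretches, tags ones resembling the
bacterial Ig-like module BIG1 (global-alignment identity > 40% to a
reference BIG1 exemplar with > 60% coverage of the reference — both
bounds strict), and partitions extensions into ``Ct_<band>_<index>``
subgroups: first by length band, then by single-linkage clustering on
pairwise global-alignment identity. Identity and coverage for the BIG1
rule are computed against the reference, since the rule compares
candidate regions to reference modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annot_io import SequenceRecord
from .da_encoding import Architecture
from .msa import GAP, ScoringScheme, nw_align

DEFAULT_LENGTH_BANDS = ((60, 300), (301, 1100))
DEFAULT_ID_THRESHOLD = 0.30


@dataclass(frozen=True)
class CtExtension:
    """The unannotated residue stretch downstream of the last identified
    domain. ``start`` is 1-based."""

    seq_id: str
    start: int
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Big1Rule:
    """Tagging thresholds for BIG1-like modules. Both bounds are strict
    (identity must exceed ``min_identity``, coverage must exceed
    ``min_coverage``)."""

    references: list
    min_identity: float = 0.40
    min_coverage: float = 0.60

    def __post_init__(self) -> None:
        for value, name in ((self.min_identity, "min_identity"),
                            (self.min_coverage, "min_coverage")):
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class Big1Tag:
    tagged: bool
    identity: float
    coverage: float
    reference_id: str


@dataclass
class CtCluster:
    label: str
    members: list
    band: tuple


def extract_ct_extension(
    sequence: SequenceRecord,
    architecture: Architecture,
    min_length: int = 60,
) -> CtExtension | None:
    """Residues downstream of the last identified domain, if there are at
    least ``min_length`` of them; ``None`` otherwise."""
    start = architecture.last_domain_end + 1
    tail = sequence.residues[start - 1 :]
    if len(tail) < min_length:
        return None
    return CtExtension(seq_id=sequence.id, start=start, residues=tail)


def _align_to_reference(
    region: str, reference: SequenceRecord, scheme: ScoringScheme
) -> tuple[float, float]:
    """(identity, coverage) of a region against one reference module.

    The reference is the first alignment row. Identity = matches /
    aligned reference positions; coverage = aligned reference positions
    / reference length.
    """
    (ref_row, reg_row), _ = nw_align(reference.residues, region, scheme)
    aligned_ref = sum(
        1 for r, q in zip(ref_row, reg_row) if r != GAP and q != GAP
    )
    if aligned_ref == 0:
        return 0.0, 0.0
    matches = sum(
        1 for r, q in zip(ref_row, reg_row) if r == q and r != GAP
    )
    return matches / aligned_ref, aligned_ref / len(reference.residues)


def tag_big1(
    region: str, rule: Big1Rule, scheme: ScoringScheme | None = None
) -> Big1Tag:
    """Tag a region as BIG1-like if some reference exceeds both
    thresholds; reports the best (identity, coverage, reference)."""
    if not rule.references:
        raise ValueError("BIG1 tagging requires at least one reference module")
    if not region:
        raise ValueError("cannot tag an empty region")
    scheme = scheme or ScoringScheme()
    best = Big1Tag(False, -1.0, 0.0, "")
    for ref in rule.references:
        identity, coverage = _align_to_reference(region, ref, scheme)
        hit = identity > rule.min_identity and coverage > rule.min_coverage
        better = (hit and not best.tagged) or (
            hit == best.tagged and (identity, coverage) > (best.identity, best.coverage)
        )
        if better:
            best = Big1Tag(hit, identity, coverage, ref.id)
    return best


def pairwise_identity_matrix(
    extensions: Sequence[CtExtension], scheme: ScoringScheme | None = None
) -> dict:
    scheme = scheme or ScoringScheme()
    idents: dict = {}
    for i, a in enumerate(extensions):
        for b in extensions[i + 1 :]:
            aln, _ = nw_align(a.residues, b.residues, scheme)
            matches = sum(
                1 for x, y in zip(*aln) if x == y and x != GAP
            )
            comparable = sum(
                1 for x, y in zip(*aln) if x != GAP and y != GAP
            )
            ident = matches / comparable if comparable else 0.0
            idents[(a.seq_id, b.seq_id)] = ident
            idents[(b.seq_id, a.seq_id)] = ident
    return idents


def cluster_extensions(
    extensions: Sequence[CtExtension],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    length_bands: Sequence[tuple] = DEFAULT_LENGTH_BANDS,
    scheme: ScoringScheme | None = None,
) -> list[CtCluster]:
    """Partition extensions into labelled ``Ct_<band>_<index>`` clusters.

    Extensions are first split by length band, then single-linkage
    clustered: two extensions join if their pairwise global-alignment
    identity is >= ``id_threshold`` (connected components of the
    thresholded identity graph). Labels are deterministic — bands in
    order, clusters within a band ordered by their smallest member id.
    Extensions longer than every band go to an overflow band.
    """
    if not extensions:
        raise ValueError("no extensions to cluster")
    bands = sorted(tuple(b) for b in length_bands)
    by_band: dict[tuple, list[CtExtension]] = {}
    for ext in extensions:
        band = next(
            (b for b in bands if b[0] <= len(ext) <= b[1]),
            None,
        )
        if band is None:
            band = ("overflow", "overflow")
        by_band.setdefault(band, []).append(ext)

    clusters: list[CtCluster] = []
    for band_index, band in enumerate(
        sorted(by_band, key=lambda b: (str(b[0]), str(b[1]))), start=1
    ):
        members = sorted(by_band[band], key=lambda e: e.seq_id)
        idents = pairwise_identity_matrix(members, scheme)
        components = _connected_components(
            [e.seq_id for e in members], idents, id_threshold
        )
        components.sort(key=lambda comp: min(comp))
        for comp_index, comp in enumerate(components, start=1):
            clusters.append(
                CtCluster(
                    label=f"Ct_{band_index}_{comp_index}",
                    members=sorted(comp),
                    band=band,
                )
            )
    return clusters


def _connected_components(
    ids: Sequence[str], idents: Mapping, threshold: float
) -> list[list]:
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if idents.get((a, b), 0.0) >= threshold:
                parent[find(a)] = find(b)
    comps: dict = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def subtype_type5(
    extension: CtExtension | None,
    big1_tag: Big1Tag | None,
    identified_modules: Sequence[str] = (),
) -> str:
    """Label a type-5 sequence's C-terminal arrangement.

    Default grammar: BIG1-bearing vs BIG1-free extensions, with a
    module-decorated variant when identified modules follow the DUF4982
    linker; no extension at all falls back to ``5-unassigned``.
    """
    modules = [m for m in identified_modules]
    if extension is None and not modules:
        return "5-unassigned"
    parts = []
    if big1_tag is not None and big1_tag.tagged:
        parts.append("BIG1")
    if modules:
        parts.append("+".join(modules))
    if extension is not None and (big1_tag is None or not big1_tag.tagged):
        parts.append("Cter")
    return "5-" + ("_".join(parts) if parts else "unassigned")


def write_cluster_report(
    extensions: Sequence[CtExtension],
    clusters: Sequence[CtCluster],
    tags: Mapping | None,
    path,
) -> None:
    label_of = {
        sid: cluster.label for cluster in clusters for sid in cluster.members
    }
    tags = tags or {}
    with open(path, "w") as fh:
        fh.write("seq_id\text_length\tcluster\tbig1\tidentity\tcoverage\n")
        for ext in sorted(extensions, key=lambda e: e.seq_id):
            tag = tags.get(ext.seq_id)
            fh.write(
                f"{ext.seq_id}\t{len(ext)}\t{label_of.get(ext.seq_id, '')}\t"
                f"{int(tag.tagged) if tag else ''}\t"
                f"{f'{tag.identity:.3f}' if tag else ''}\t"
                f"{f'{tag.coverage:.3f}' if tag else ''}\n"
            )
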