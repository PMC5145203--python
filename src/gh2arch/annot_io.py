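"""Readers and writers for sequences, domain annotations and trees.

All coordinates are 1-based inclusive, matching the Pfam envelope
convention. Conversion to other conventions (if ever needed) happens here
and nowhere else.

Supported formats:

* FASTA for protein sequences (validated: unique ids, canonical amino
  acids plus ``X``).
* Tab-separated domain tables (``seq_id  domain  env_start  env_end
  model_coverage``) and HMMER3 ``domtblout`` records for per-residue
  domain annotations.
* Newick for trees, with bootstrap supports carried as internal-node
  labels (the convention written by most tree builders).
* YAML for run configuration.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from skbio import TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class AnnotationError(ValueError):
    """Raised on malformed input files or invariant violations."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    ``residues`` is restricted to the 20 canonical amino acids plus the
    ambiguity letter ``X``; anything else is rejected at parse time so
    that downstream identity computations are well defined.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise AnnotationError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise AnnotationError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"sequence {self.id!r} contains non-amino-acid characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One annotated domain occurrence on a protein.

    ``env_start``/``env_end`` are the 1-based inclusive envelope
    coordinates; ``model_coverage`` is the fraction of the domain model
    matched by the hit.
    """

    seq_id: str
    domain: str
    env_start: int
    env_end: int
    model_coverage: float
    source: str = "table"

    def __post_init__(self) -> None:
        if self.env_start < 1:
            raise AnnotationError(
                f"hit {self.domain} on {self.seq_id}: env_start "
                f"{self.env_start} < 1 (coordinates are 1-based)"
            )
        if self.env_start > self.env_end:
            raise AnnotationError(
                f"hit {self.domain} on {self.seq_id}: env_start "
                f"{self.env_start} > env_end {self.env_end}"
            )
        if not 0.0 <= self.model_coverage <= 1.0:
            raise AnnotationError(
                f"hit {self.domain} on {self.seq_id}: model_coverage "
                f"{self.model_coverage} outside [0, 1]"
            )

    @property
    def span(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass
class AnnotationSet:
    """Sequences plus their domain hits, cross-validated on construction."""

    sequences: dict[str, SequenceRecord]
    hits: dict[str, list[DomainHit]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for seq_id, seq_hits in self.hits.items():
            if seq_id not in self.sequences:
                raise AnnotationError(
                    f"domain hits reference unknown sequence {seq_id!r}"
                )
            seq_len = len(self.sequences[seq_id])
            for hit in seq_hits:
                if hit.env_end > seq_len:
                    raise AnnotationError(
                        f"hit {hit.domain} on {seq_id}: env_end "
                        f"{hit.env_end} beyond sequence length {seq_len}"
                    )
            seq_hits.sort(key=lambda h: (h.env_start, h.env_end, h.domain))

    @classmethod
    def from_files(cls, fasta_path, table_path, dialect="tsv") -> "AnnotationSet":
        seqs = {r.id: r for r in read_fasta(fasta_path)}
        hits: dict[str, list[DomainHit]] = {}
        for hit in read_domain_table(table_path, dialect=dialect):
            hits.setdefault(hit.seq_id, []).append(hit)
        return cls(sequences=seqs, hits=hits)

    def hits_for(self, seq_id: str) -> list[DomainHit]:
        return self.hits.get(seq_id, [])


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into validated :class:`SequenceRecord` objects.

    Wrapped sequence lines are concatenated; record order is preserved.
    Duplicate ids and non-amino-acid characters are reported with the
    line number where they occur.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    current_desc = ""
    current_chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        residues = "".join(current_chunks)
        try:
            rec = SequenceRecord(current_id, residues, current_desc)
        except AnnotationError as exc:
            raise AnnotationError(f"{path}, record at line {header_line}: {exc}")
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                head = line[1:].split(None, 1)
                if not head:
                    raise AnnotationError(f"{path}, line {lineno}: empty FASTA header")
                current_id = head[0]
                current_desc = head[1] if len(head) > 1 else ""
                current_chunks = []
                header_line = lineno
                if current_id in seen:
                    raise AnnotationError(
                        f"{path}, line {lineno}: duplicate sequence id {current_id!r}"
                    )
                seen.add(current_id)
            else:
                if current_id is None:
                    raise AnnotationError(
                        f"{path}, line {lineno}: sequence data before first header"
                    )
                current_chunks.append(line.upper())
    flush()
    if not records:
        raise AnnotationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


_TSV_COLUMNS = ("seq_id", "domain", "env_start", "env_end", "model_coverage")

# domtblout whitespace-delimited field indices (HMMER3 --domtblout layout)
_DOMTBL_TARGET = 0
_DOMTBL_QUERY = 3
_DOMTBL_QLEN = 5
_DOMTBL_HMM_FROM = 15
_DOMTBL_HMM_TO = 16
_DOMTBL_ENV_FROM = 19
_DOMTBL_ENV_TO = 20


def read_domain_table(path, dialect: str = "tsv") -> list[DomainHit]:
    """Read per-sequence domain hits.

    ``tsv`` carries model_coverage as data; ``domtblout`` computes it as
    ``(hmm_to - hmm_from + 1) / model_length`` from the HMMER columns.
    """
    if dialect == "tsv":
        return _read_tsv_hits(path)
    if dialect == "domtblout":
        return _read_domtblout_hits(path)
    raise AnnotationError(f"unknown domain-table dialect {dialect!r}")


def _read_tsv_hits(path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "seq_id":
                continue  # header row
            if len(fields) < 5:
                raise AnnotationError(
                    f"{path}, line {lineno}: expected 5 tab-separated columns "
                    f"{_TSV_COLUMNS}, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    seq_id=fields[0].strip(),
                    domain=fields[1].strip(),
                    env_start=int(fields[2]),
                    env_end=int(fields[3]),
                    model_coverage=float(fields[4]),
                    source="tsv",
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}, line {lineno}: {exc}")
            hits.append(hit)
    return hits


def _read_domtblout_hits(path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.split()
            if len(fields) <= _DOMTBL_ENV_TO:
                raise AnnotationError(
                    f"{path}, line {lineno}: truncated domtblout record"
                )
            try:
                model_len = int(fields[_DOMTBL_QLEN])
                hmm_from = int(fields[_DOMTBL_HMM_FROM])
                hmm_to = int(fields[_DOMTBL_HMM_TO])
                hit = DomainHit(
                    seq_id=fields[_DOMTBL_TARGET],
                    domain=fields[_DOMTBL_QUERY],
                    env_start=int(fields[_DOMTBL_ENV_FROM]),
                    env_end=int(fields[_DOMTBL_ENV_TO]),
                    model_coverage=(hmm_to - hmm_from + 1) / model_len,
                    source="domtblout",
                )
            except (ValueError, ZeroDivisionError, AnnotationError) as exc:
                raise AnnotationError(f"{path}, line {lineno}: {exc}")
            hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for hit in hits:
            fh.write(
                f"{hit.seq_id}\t{hit.domain}\t{hit.env_start}\t{hit.env_end}"
                f"\t{hit.model_coverage:.4f}\n"
            )


def read_newick(source) -> TreeNode:
    """Read a Newick tree; numeric internal-node labels become supports.

    Supports are normalised to the [0, 1] scale (labels > 1 are treated
    as percentages and divided by 100).
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise AnnotationError(f"newick parse error: {exc}")
    tree.assign_supports()
    for node in tree.non_tips(include_self=True):
        if node.support is not None and node.support > 1.0:
            node.support /= 100.0  # percentage-style labels
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise AnnotationError("duplicate leaf labels in newick tree")
    return tree


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialise a tree; ``node.support`` values become internal-node
    labels (skbio's native convention)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_config(path) -> dict:
    """Load a YAML run-configuration file into a flat mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise AnnotationError(f"{path}: config must be a mapping")
    return dict(data)


def dump_config(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
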