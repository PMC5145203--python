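"""Pairwise and progressive protein alignment.

This is the pipeline's in-house replacement for an external multiple
aligner: a global affine-gap pairwise aligner (Needleman–Wunsch /
Gotoh), percent-identity computation with an explicit choice of
denominator, and a guide-tree progressive multiple aligner
(k-mer-distance UPGMA guide tree + profile–profile merging). Externally
computed alignments can be imported as aligned FASTA for users wanting
parity with a specific aligner.

Scoring defaults to BLOSUM62 with gap open −11 / extend −1, the common
default for global protein alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .annot_io import SequenceRecord, read_fasta

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GAP = "-"

NEG_INF = -1e30


def _blosum62_matrix() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=float)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = b62[a, b]
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both negative;
    opening a gap costs ``gap_open`` for the first gapped position and
    ``gap_extend`` for each further one)."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return self.matrix[_AA_INDEX[a], _AA_INDEX[b]]


@dataclass
class MSA:
    """A multiple alignment: equal-length rows over residues + ``-``."""

    ids: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")

    @classmethod
    def read_fasta(cls, path) -> "MSA":
        class _Aligned(str):
            pass

        ids, rows = [], []
        with open(path) as fh:
            current = None
            chunks: list[str] = []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if current is not None:
                        rows.append("".join(chunks))
                    current = line[1:].split()[0]
                    ids.append(current)
                    chunks = []
                else:
                    chunks.append(line.upper())
            if current is not None:
                rows.append("".join(chunks))
        return cls(ids, rows)

    def write_phylip(self, path) -> None:
        """Relaxed sequential PHYLIP, for external tree builders."""
        with open(path, "w") as fh:
            fh.write(f" {len(self.rows)} {self.n_columns}\n")
            for sid, row in zip(self.ids, self.rows):
                fh.write(f"{sid}  {row}\n")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-amino-acid character {exc} in sequence")


def nw_align(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[tuple[str, str], float]:
    """Global affine-gap alignment of two sequences (Gotoh's algorithm).

    Returns the aligned pair and the optimal score. Traceback ties are
    broken deterministically: substitution first, then a gap in ``a``
    (consuming ``b``), then a gap in ``b``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    ea, eb = _encode(a), _encode(b)
    sub = scheme.matrix[np.ix_(ea, eb)]  # (n, m) position scores
    profile_a = np.eye(len(ALPHABET))[ea]
    profile_b = np.eye(len(ALPHABET))[eb]
    (ra, rb), score = _affine_align_profiles(
        profile_a, profile_b, sub, scheme.gap_open, scheme.gap_extend
    )
    out_a = "".join(a[i] if i >= 0 else GAP for i in ra)
    out_b = "".join(b[j] if j >= 0 else GAP for j in rb)
    return (out_a, out_b), float(score)


def _affine_align_profiles(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    sub: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[tuple[list, list], float]:
    """Shared affine DP over precomputed column-pair scores ``sub``.

    Returns index traces (position index or −1 for a gap) and the score.
    M/E/F are the standard three states: M ends in a column pair, E in a
    gap in the first input (consuming the second), F in a gap in the
    second input.
    """
    n, m = sub.shape
    go, ge = gap_open, gap_extend
    tol = 1e-9
    M = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in A (consumes B, moves j)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in B (consumes A, moves i)
    # predecessor state per cell: 0 = M, 1 = E, 2 = F
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    E[0, 1:] = go + ge * np.arange(m)
    ptrE[0, 2:] = 1
    F[1:, 0] = go + ge * np.arange(n)
    ptrF[2:, 0] = 2
    for i in range(1, n + 1):
        # M comes from any state at the previous diagonal
        dM, dE, dF = M[i - 1, :-1], E[i - 1, :-1], F[i - 1, :-1]
        prev_best = np.maximum(np.maximum(dM, dE), dF)
        M[i, 1:] = prev_best + sub[i - 1]
        ptrM[i, 1:] = np.select(
            [dM >= prev_best - tol, dE >= prev_best - tol], [0, 1], 2
        )
        # F comes from the cell above (same column)
        fM = M[i - 1, 1:] + go
        fE = E[i - 1, 1:] + go
        fF = F[i - 1, 1:] + ge
        F[i, 1:] = np.maximum(np.maximum(fM, fE), fF)
        ptrF[i, 1:] = np.select(
            [fM >= F[i, 1:] - tol, fE >= F[i, 1:] - tol], [0, 1], 2
        )
        # E has an intra-row recurrence E[i,j] = max(M/F[i,j-1] + go,
        # E[i,j-1] + ge); a gap run opening after column k and ending at
        # j costs go + (j-1-k)·ge, so E[i,j] is a running maximum of
        # (best-non-E[i,k] + go − ge·k) shifted by ge·(j−1).
        openers = np.maximum(M[i, :-1], F[i, :-1]) + go
        base = openers - ge * np.arange(m)
        E[i, 1:] = np.maximum.accumulate(base) + ge * np.arange(m)
        eM = M[i, :-1] + go
        eF = F[i, :-1] + go
        eE = E[i, :-1] + ge
        ptrE[i, 1:] = np.select(
            [eM >= E[i, 1:] - tol, eE >= E[i, 1:] - tol], [0, 1], 2
        )
    finals = (M[n, m], E[n, m], F[n, m])
    score = max(finals)
    state = int(np.argmax([f >= score - tol for f in finals]))

    ra: list[int] = []
    rb: list[int] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            ra.append(i - 1)
            rb.append(j - 1)
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ra.append(-1)
            rb.append(j - 1)
            state = int(ptrE[i, j])
            j -= 1
        else:
            ra.append(i - 1)
            rb.append(-1)
            state = int(ptrF[i, j])
            i -= 1
    ra.reverse()
    rb.reverse()
    return (ra, rb), float(score)


def percent_identity(
    alignment: tuple[str, str], denominator: str = "aligned_columns"
) -> float:
    """Fraction of identical residues in a pairwise alignment.

    ``denominator`` choices: ``aligned_columns`` (columns with a residue
    in both rows), ``shorter_seq`` (length of the shorter input), or
    ``reference_positions`` (residues of the first row — the reference).
    Gap–gap columns never count anywhere.
    """
    a, b = alignment
    if len(a) != len(b):
        raise ValueError("aligned rows differ in length")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    if denominator == "aligned_columns":
        denom = sum(1 for x, y in zip(a, b) if x != GAP and y != GAP)
    elif denominator == "shorter_seq":
        denom = min(len(a.replace(GAP, "")), len(b.replace(GAP, "")))
    elif denominator == "reference_positions":
        denom = len(a.replace(GAP, ""))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length denominator")
    return matches / denom


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 − fractional k-mer overlap; the usual quick guide-tree metric."""
    if len(a) < k or len(b) < k:
        return 0.0 if a == b else 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def _upgma_order(dist: np.ndarray) -> list:
    """UPGMA merge schedule on a condensed distance matrix; returns a
    list of (left, right) cluster merges over indices 0..n-1 then n... ."""
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((i, j, next_id))
        ni, nj = len(active[i]), len(active[j])
        members = active[i] + active[j]
        del active[i], active[j]
        new_d = {}
        for k in active:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[(min(k, next_id), max(k, next_id))] = (
                ni * dik + nj * djk
            ) / (ni + nj)
        d = {
            key: val
            for key, val in d.items()
            if i not in key and j not in key
        }
        d.update(new_d)
        active[next_id] = members
        next_id += 1
    return merges


def _profile_from_rows(rows: list[str]) -> np.ndarray:
    """Residue-frequency profile (columns × alphabet); gaps contribute
    zero mass so a mostly-gap column scores near zero against anything."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, len(ALPHABET)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                prof[c, _AA_INDEX[ch]] += 1.0
    return prof / len(rows)


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> list[str]:
    pa = _profile_from_rows(rows_a)
    pb = _profile_from_rows(rows_b)
    sub = pa @ scheme.matrix @ pb.T
    (ra, rb), _ = _affine_align_profiles(
        pa, pb, sub, scheme.gap_open, scheme.gap_extend
    )
    merged = []
    for row in rows_a:
        merged_row = "".join(row[i] if i >= 0 else GAP for i in ra)
        merged.append(merged_row)
    out = merged
    for row in rows_b:
        merged_row = "".join(row[j] if j >= 0 else GAP for j in rb)
        out.append(merged_row)
    return out


def progressive_align(
    sequences: Sequence[SequenceRecord] | Sequence[tuple],
    scheme: ScoringScheme | None = None,
) -> MSA:
    """Guide-tree progressive multiple alignment.

    The guide tree is UPGMA on k-mer distances; profiles are merged
    leaf-to-root with the same affine profile–profile DP used for
    pairwise alignment. Row degapping always reproduces the inputs.
    """
    scheme = scheme or ScoringScheme()
    items = [
        (s.id, s.residues) if isinstance(s, SequenceRecord) else (s[0], s[1])
        for s in sequences
    ]
    if len(items) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(items[i][1], items[j][1])
    merges = _upgma_order(dist)
    clusters: dict[int, tuple[list, list]] = {
        i: ([items[i][0]], [items[i][1]]) for i in range(n)
    }
    for i, j, new_id in merges:
        ids_a, rows_a = clusters.pop(i)
        ids_b, rows_b = clusters.pop(j)
        merged_rows = _merge_profiles(rows_a, rows_b, scheme)
        clusters[new_id] = (ids_a + ids_b, merged_rows)
    final_ids, final_rows = next(iter(clusters.values()))
    order = {sid: k for k, sid in enumerate(ids)}
    paired = sorted(zip(final_ids, final_rows), key=lambda p: order[p[0]])
    msa = MSA([p[0] for p in paired], [p[1] for p in paired])
    for sid, (_, original) in zip(ids, items):
        if msa.degapped(sid) != original:
            raise AssertionError(
                f"degapping row {sid} does not reproduce the input sequence"
            )
    return msa
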