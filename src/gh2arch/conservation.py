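"""Active-site conservation profiling over an alignment.

Catalytic and acceptor-site residues are specified as anchors on a
reference sequence (1-based ungapped positions, e.g. the acid/base
glutamate of a β-galactosidase). Each anchor is mapped through the
alignment to its column, and the column's conservation is summarised as
a percentage and banded: strictly more than 50% identity is one band,
exactly 100% another, everything else below. Identity is measured
against the column's modal residue by default (the reference residue is
available as an alternative); gaps never count as matches but do count
in the denominator by default, so a sparsely populated column reads as
poorly conserved.

Shipped presets cover the documented β-galactosidase active-site
positions: the Bacillus circulans catalytic triad (Glu 447 acid/base,
Glu 532 nucleophile, Tyr 511) with acceptor-site residues Lys 409,
Tyr 449, Asp 481 and Trp 570, and the Thermotoga maritima acceptor
platform Trp 959.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .msa import GAP, MSA

logger = logging.getLogger(__name__)

# documented active-site positions, usable as anchor presets once the
# matching reference sequence is in the alignment
BCIRCULANS_ANCHOR_PRESET = (
    (409, "K", "acceptor site"),
    (447, "E", "acid/base"),
    (449, "Y", "acceptor site"),
    (481, "D", "acceptor site"),
    (511, "Y", "catalytic triad"),
    (532, "E", "nucleophile"),
    (570, "W", "acceptor site"),
)
TMARITIMA_ANCHOR_PRESET = ((959, "W", "acceptor platform"),)


@dataclass(frozen=True)
class ResidueAnchor:
    """A named residue on a reference sequence: 1-based ungapped
    position plus the residue expected there (an off-by-one guard)."""

    ref_id: str
    position: int
    expected_residue: str
    role: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("anchor positions are 1-based")
        if len(self.expected_residue) != 1:
            raise ValueError("expected_residue must be a single letter")


@dataclass(frozen=True)
class AnchorProfile:
    anchor: ResidueAnchor
    column: int
    percentage: float
    band: str
    frequencies: dict
    subset_percentage: float | None = None
    rest_percentage: float | None = None


@dataclass
class ConservationProfile:
    rows: list = field(default_factory=list)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "anchor\trole\tcolumn\tpercent\tband\tsubset_percent\trest_percent\n"
            )
            for r in self.rows:
                subset = "" if r.subset_percentage is None else f"{r.subset_percentage:.1f}"
                rest = "" if r.rest_percentage is None else f"{r.rest_percentage:.1f}"
                fh.write(
                    f"{r.anchor.ref_id}:{r.anchor.position}{r.anchor.expected_residue}"
                    f"\t{r.anchor.role}\t{r.column}\t{r.percentage:.1f}\t{r.band}"
                    f"\t{subset}\t{rest}\n"
                )


def anchor_to_column(msa: MSA, anchor: ResidueAnchor) -> int:
    """Map an anchor's ungapped reference position to its alignment
    column (0-based).

    Counts non-gap positions along the reference row. A mismatch between
    the residue found and the anchor's expected residue is a hard error:
    it almost always means an off-by-one or the wrong reference build.
    """
    row = msa.row(anchor.ref_id)
    count = 0
    for col, ch in enumerate(row):
        if ch == GAP:
            continue
        count += 1
        if count == anchor.position:
            if ch != anchor.expected_residue:
                raise ValueError(
                    f"anchor {anchor.ref_id}:{anchor.position} expects "
                    f"{anchor.expected_residue!r} but reference has {ch!r}"
                )
            return col
    raise ValueError(
        f"anchor position {anchor.position} beyond reference "
        f"{anchor.ref_id} length {count}"
    )


def band_of(percentage: float) -> str:
    """Band a conservation percentage: 100 exactly, strictly above 50,
    or below."""
    if not 0.0 <= percentage <= 100.0:
        raise ValueError(f"percentage {percentage} outside [0, 100]")
    if percentage == 100.0:
        return "100"
    if percentage > 50.0:
        return ">=50"
    return "<50"


def column_conservation(
    msa: MSA,
    column: int,
    mode: str = "modal",
    reference_id: str | None = None,
    row_subset: Sequence | None = None,
    count_gaps_in_denominator: bool = True,
) -> tuple[float, str, dict]:
    """Percentage of rows carrying the column's consensus residue.

    ``mode='modal'`` scores against the most frequent residue in the
    column (ties broken alphabetically); ``mode='to_reference'`` scores
    against the reference row's residue. Gapped rows never match; they
    stay in the denominator unless ``count_gaps_in_denominator=False``.
    """
    if not 0 <= column < msa.n_columns:
        raise ValueError(f"column {column} outside alignment")
    ids = list(row_subset) if row_subset is not None else list(msa.ids)
    residues = [msa.row(sid)[column] for sid in ids]
    non_gap = [r for r in residues if r != GAP]
    freqs = dict(Counter(residues))
    if mode == "modal":
        if not non_gap:
            return 0.0, band_of(0.0), freqs
        target = min(
            Counter(non_gap).items(), key=lambda kv: (-kv[1], kv[0])
        )[0]
    elif mode == "to_reference":
        if reference_id is None:
            raise ValueError("to_reference mode needs reference_id")
        target = msa.row(reference_id)[column]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    matches = sum(1 for r in residues if r == target and r != GAP)
    denom = len(residues) if count_gaps_in_denominator else len(non_gap)
    if denom == 0:
        return 0.0, band_of(0.0), freqs
    pct = 100.0 * matches / denom
    return pct, band_of(pct), freqs


def profile_anchors(
    msa: MSA,
    anchors: Sequence[ResidueAnchor],
    mode: str = "modal",
    subset: Sequence | None = None,
    count_gaps_in_denominator: bool = True,
) -> ConservationProfile:
    """Conservation profile over a set of anchors.

    When ``subset`` is given (e.g. the BIG1-tagged sequences), each
    anchor additionally reports conservation inside the subset and in
    the remaining rows. An empty subset just omits those statistics.
    """
    profile = ConservationProfile()
    seen_columns: dict = {}
    subset = [s for s in (subset or []) if s in msa.ids]
    rest = [sid for sid in msa.ids if sid not in set(subset)]
    for anchor in anchors:
        col = anchor_to_column(msa, anchor)
        if col in seen_columns:
            logger.warning(
                "anchors %s and %s map to the same column %d",
                seen_columns[col], anchor, col,
            )
        seen_columns[col] = anchor
        pct, band, freqs = column_conservation(
            msa, col, mode=mode, reference_id=anchor.ref_id,
            count_gaps_in_denominator=count_gaps_in_denominator,
        )
        sub_pct = rest_pct = None
        if subset:
            sub_pct, _, _ = column_conservation(
                msa, col, mode=mode, reference_id=anchor.ref_id,
                row_subset=subset,
                count_gaps_in_denominator=count_gaps_in_denominator,
            )
            if rest:
                rest_pct, _, _ = column_conservation(
                    msa, col, mode=mode, reference_id=anchor.ref_id,
                    row_subset=rest,
                    count_gaps_in_denominator=count_gaps_in_denominator,
                )
        profile.rows.append(
            AnchorProfile(
                anchor=anchor, column=col, percentage=pct, band=band,
                frequencies=freqs, subset_percentage=sub_pct,
                rest_percentage=rest_pct,
            )
        )
    return profile


def anchors_from_preset(
    ref_id: str, preset: Sequence[tuple], reference_residues: str
) -> list[ResidueAnchor]:
    """Instantiate a documented anchor preset against an actual reference
    sequence, verifying the expected residues."""
    anchors = []
    for position, residue, role in preset:
        if position > len(reference_residues):
            raise ValueError(
                f"preset position {position} beyond reference length "
                f"{len(reference_residues)}"
            )
        anchors.append(
            ResidueAnchor(ref_id=ref_id, position=position,
                          expected_residue=residue, role=role)
        )
    return anchors
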