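"""Selection filter and five-way domain-architecture (DA) classifier.

Family-2 glycoside hydrolases share a three-module core — two N-terminal
β-sandwiches (GH2N, GH2d) and the catalytic TIM barrel (GH2C) — and are
sorted into five DA types by what follows the catalytic module:

* type 1 — core only (mostly β-glucuronidases);
* type 2 — large subunit (LacL) of a bicistronic β-galactosidase, whose
  small subunit (LacM, a standalone Bgal_Small_N) is encoded by a
  separate locus; indistinguishable from type 1 by architecture alone;
* type 3 — canonical β-galactosidase: Bgal_Small_N at the C-terminus,
  usually linked through the β-sandwich DUF4981;
* type 4 — an unannotated C-terminal extension (60+ residues) with no
  identified domains;
* type 5 — DUF4982 immediately after GH2C followed by further C-terminal
  modules and/or extensions.

Sequences enter the classifier only if they carry exactly one GH2C hit
covering at least 70% of the Pfam model and no additional catalytic
(hybrid) module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .annot_io import DomainHit, SequenceRecord
from .da_encoding import Architecture, build_architecture

UNASSIGNED = "unassigned"
TYPE_1OR2 = "1or2"


@dataclass
class ClassifierConfig:
    """Thresholds and domain-name roles for filtering and classification.

    ``min_gh2c_coverage`` is the inclusive floor on the fraction of the
    GH2C model covered (default 0.70). ``min_ct_extension`` is the
    smallest unannotated C-terminal stretch that counts as an extension
    (default 60 residues, the smallest extension observed among type-4
    enzymes). ``gh2d_gap_window`` bounds, as fractions of the reference
    GH2d length, how long an unannotated GH2N–GH2C gap may be while
    still being read as a GH2d-like (unannotated equivalent) domain.
    """

    min_gh2c_coverage: float = 0.70
    min_ct_extension: int = 60
    gh2d_gap_window: tuple[float, float] = (0.7, 1.3)
    reference_gh2d_length: float = 300.0
    gh2c: str = "GH2C"
    gh2n: str = "GH2N"
    gh2d: str = "GH2d"
    small_subunit_domain: str = "Bgal_Small_N"
    type3_linker: str = "DUF4981"
    type5_linker: str = "DUF4982"
    catalytic_blacklist: frozenset = frozenset(
        {
            "Glyco_transf_2",
            "Lipase",
            "Polysacc_deac_1",
            "PKinase",
            "Hexosaminidase",
        }
    )
    decoration_domains: frozenset = frozenset(
        {"RicinB_lectin", "YSIRK_signal", "Laminin_G_3", "NPCBM", "F5_F8_type_C"}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.min_gh2c_coverage <= 1.0:
            raise ValueError("min_gh2c_coverage must lie in (0, 1]")
        if self.min_ct_extension < 0:
            raise ValueError("min_ct_extension must be >= 0")

    @property
    def core_domains(self) -> frozenset:
        return frozenset({self.gh2n, self.gh2d, self.gh2c})


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reason: str = ""


@dataclass
class DATypeCall:
    """Classifier verdict for one sequence: DA type, subtype and the
    ordered list of rules that fired."""

    seq_id: str
    da_type: str
    subtype: str = ""
    evidence: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def filter_gh2c(
    hits: Sequence[DomainHit], config: ClassifierConfig
) -> FilterDecision:
    """Admission filter: single GH2C, model coverage >= the configured
    floor (boundary inclusive), and no hybrid catalytic module."""
    gh2c_hits = [h for h in hits if h.domain == config.gh2c]
    if not gh2c_hits:
        return FilterDecision(False, "no_gh2c")
    if len(gh2c_hits) > 1:
        return FilterDecision(False, "multiple_gh2c")
    if gh2c_hits[0].model_coverage < config.min_gh2c_coverage:
        return FilterDecision(False, "low_coverage")
    hybrids = sorted(
        {h.domain for h in hits} & set(config.catalytic_blacklist)
    )
    if hybrids:
        return FilterDecision(False, f"hybrid_catalytic:{hybrids[0]}")
    return FilterDecision(True, "")


def detect_core(
    architecture: Architecture, seq_length: int, config: ClassifierConfig
) -> str:
    """Classify the N-terminal core layout.

    ``canonical``: GH2N, then GH2d, then GH2C in order. ``gh2d_like_gap``:
    GH2d absent but the unannotated stretch between GH2N and GH2C has a
    length within the configured window of the reference GH2d length
    (an unannotated equivalent domain). Anything else: ``incomplete``.
    """
    elements = architecture.elements
    spans = architecture.element_spans
    pos = {d: i for i, d in enumerate(elements)}
    if config.gh2n in pos and config.gh2d in pos and config.gh2c in pos:
        if pos[config.gh2n] < pos[config.gh2d] < pos[config.gh2c]:
            return "canonical"
    if config.gh2n in pos and config.gh2c in pos and config.gh2d not in pos:
        n_end = spans[pos[config.gh2n]][1]
        c_start = spans[pos[config.gh2c]][0]
        gap = c_start - n_end - 1
        lo = config.gh2d_gap_window[0] * config.reference_gh2d_length
        hi = config.gh2d_gap_window[1] * config.reference_gh2d_length
        if lo <= gap <= hi:
            return "gh2d_like_gap"
    return "incomplete"


def infer_reference_gh2d_length(
    architectures: Iterable[Architecture], config: ClassifierConfig
) -> float:
    """Median GH2d span across the dataset; falls back to the configured
    default when GH2d never occurs."""
    spans = [
        end - start + 1
        for arch in architectures
        for d, (start, end) in zip(arch.elements, arch.element_spans)
        if d == config.gh2d
    ]
    return float(median(spans)) if spans else config.reference_gh2d_length


def classify_da(
    architecture: Architecture,
    sequence: SequenceRecord,
    config: ClassifierConfig,
) -> DATypeCall:
    """Assign a DA type by the fixed C-terminal decision order.

    Bgal_Small_N downstream of GH2C wins (type 3, with canonical /
    replaced / appended subtypes); then DUF4982 directly after GH2C
    (type 5); then a bare unannotated extension (type 4); else the call
    is deferred as ``1or2`` for bicistronic resolution. N-terminal
    decoration domains are recorded as flags and never change the type.
    """
    call = DATypeCall(seq_id=architecture.seq_id or sequence.id, da_type=UNASSIGNED)
    elements = architecture.elements
    spans = architecture.element_spans
    seq_len = len(sequence)

    core = detect_core(architecture, seq_len, config)
    call.evidence.append(f"core:{core}")
    if core == "incomplete":
        call.da_type = UNASSIGNED
        call.evidence.append("rule:incomplete_core")
        return call

    gh2c_idx = elements.index(config.gh2c)
    gh2c_end = spans[gh2c_idx][1]
    downstream = [
        (d, spans[i]) for i, d in enumerate(elements) if i > gh2c_idx
    ]
    upstream_extras = [
        d
        for i, d in enumerate(elements)
        if i < gh2c_idx and d in config.decoration_domains
    ]
    for d in upstream_extras:
        call.flags.append(f"nterm_decoration:{d}")

    down_names = [d for d, _ in downstream]
    tail_len = seq_len - spans[-1][1] if spans else seq_len

    if config.small_subunit_domain in down_names:
        call.da_type = "3"
        call.evidence.append("rule:bgal_small_n_downstream")
        decorations = [d for d in down_names if d in config.decoration_domains]
        if decorations:
            call.subtype = "3-appended"
            call.evidence.append(f"subtype:decorations:{','.join(decorations)}")
        elif config.type3_linker in down_names and core == "canonical":
            call.subtype = "3-canonical"
            call.evidence.append("subtype:duf4981_linker")
        else:
            call.subtype = "3-replaced"
            missing = []
            if config.type3_linker not in down_names:
                missing.append(config.type3_linker)
            if core != "canonical":
                missing.append(config.gh2d)
            call.evidence.append(f"subtype:replaced:{','.join(missing)}")
        return call

    if down_names and down_names[0] == config.type5_linker:
        further_modules = down_names[1:]
        if further_modules or tail_len >= config.min_ct_extension:
            call.da_type = "5"
            call.evidence.append("rule:duf4982_plus_ct")
            if further_modules:
                call.evidence.append(f"modules:{','.join(further_modules)}")
            if tail_len >= config.min_ct_extension:
                call.evidence.append(f"ct_extension:{tail_len}")
            return call

    if not down_names and tail_len >= config.min_ct_extension:
        call.da_type = "4"
        call.evidence.append(f"rule:unannotated_ct_extension:{tail_len}")
        return call

    call.da_type = TYPE_1OR2
    call.evidence.append("rule:no_ct_signature")
    return call


def resolve_bicistronic(
    calls: Iterable[DATypeCall],
    companion_table: Mapping[str, str] | None = None,
    bicistronic_subclusters: Mapping[str, str] | None = None,
    known_ids: set | None = None,
) -> list[DATypeCall]:
    """Split the deferred 1or2 calls into types 1 and 2.

    A sequence becomes type 2 if a small-subunit (LacM) partner locus is
    recorded for it, or if its GH2C subcluster is tagged bicistronic;
    otherwise it defaults to type 1, mirroring the fact that the two
    types cannot be told apart from the architecture of the GH2C-bearing
    gene alone.
    """
    companion_table = companion_table or {}
    bicistronic_subclusters = bicistronic_subclusters or {}
    resolved = []
    for call in calls:
        if call.da_type != TYPE_1OR2:
            resolved.append(call)
            continue
        partner = companion_table.get(call.seq_id)
        if partner is not None:
            if known_ids is not None and partner not in known_ids:
                call.evidence.append(f"warning:partner_not_found:{partner}")
                call.da_type = "1"
                call.evidence.append("rule:default_type1")
            else:
                call.da_type = "2"
                call.evidence.append(f"rule:lacm_partner:{partner}")
        elif bicistronic_subclusters.get(call.seq_id) == "bicistronic":
            call.da_type = "2"
            call.evidence.append("rule:bicistronic_subcluster")
        else:
            call.da_type = "1"
            call.evidence.append("rule:default_type1")
        resolved.append(call)
    return resolved


def classify_dataset(
    sequences: Mapping[str, SequenceRecord],
    hits_by_seq: Mapping[str, Sequence[DomainHit]],
    config: ClassifierConfig | None = None,
    companion_table: Mapping[str, str] | None = None,
) -> tuple[list[DATypeCall], dict[str, str]]:
    """Run filter → core detection → classification → bicistronic
    resolution over a whole annotation set.

    Returns the resolved calls for admitted sequences and a mapping of
    rejected seq_id → reason.
    """
    config = config or ClassifierConfig()
    archs = {
        sid: build_architecture(list(hits_by_seq.get(sid, [])), len(seq))
        for sid, seq in sequences.items()
    }
    config.reference_gh2d_length = infer_reference_gh2d_length(
        archs.values(), config
    )
    calls: list[DATypeCall] = []
    rejected: dict[str, str] = {}
    for sid in sequences:
        decision = filter_gh2c(list(hits_by_seq.get(sid, [])), config)
        if not decision.passed:
            rejected[sid] = decision.reason
            continue
        calls.append(classify_da(archs[sid], sequences[sid], config))
    calls = resolve_bicistronic(
        calls, companion_table, known_ids=set(sequences)
    )
    return calls, rejected


def tally_da_types(calls: Iterable[DATypeCall]) -> dict[str, int]:
    """Deterministic per-DA-type counts, the summary a classification
    table reduces to."""
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.da_type] = counts.get(call.da_type, 0) + 1
    return dict(sorted(counts.items()))


def write_classification_report(calls: Iterable[DATypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tda_type\tsubtype\tevidence\tflags\n")
        for call in calls:
            fh.write(
                f"{call.seq_id}\t{call.da_type}\t{call.subtype}"
                f"\t{';'.join(call.evidence)}\t{';'.join(call.flags)}\n"
            )
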