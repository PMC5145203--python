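"""Synthetic GH2 dataset generator.

Emits a complete, download-free test bed with the statistical structure
the analysis pipeline assumes: a known phylogeny, a catalytic-module
sequence evolving along it, and domain-architecture types painted onto
clades following the evolutionary scenario the pipeline is meant to
recover — a core-only ancestor (type 1), one clade gaining the small
subunit module and its DUF4981 linker (type 3, with replaced and
decorated variants), a subclade of it split into two loci to mimic
bicistronic enzymes (type 2), one clade gaining a bare unannotated
C-terminal extension (type 4), and one clade gaining DUF4982 followed by
a BIG1-like module and a further extension (type 5, with a BIG1-free
variant).

Ground truth (tree, per-sequence type, partner map, planted conserved
columns, uncorrupted annotations) is recorded before any noise is
applied, so every corruption is auditable. Noise knobs: annotation
dropout, model-coverage jitter, hybrid-catalytic contaminants and
duplicated-GH2C records.

Sequences evolve by an independent-site substitution process with
uniform replacement among the 19 alternative residues; no indels are
simulated, so alignment difficulty is deliberately not part of the test
bed. Branch lengths carry a floor plus an exponential tail — the floor
keeps every internal edge long enough to be recoverable from
catalytic-module-length alignments at the default substitution rate,
which is what makes tree-recovery checks informative rather than coin
flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .annot_io import (
    AMINO_ACIDS,
    DomainHit,
    SequenceRecord,
    write_domain_table,
    write_fasta,
    write_newick,
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


@dataclass
class SynthConfig:
    """Generator settings. The defaults are the study conditions every
    recovery test runs under; scale ``n_taxa`` down for quick checks.

    Clade fractions allocate leaves to the four architecture clades;
    ``type2_fraction`` splits off the bicistronic subclade inside the
    type-3 clade. Branch lengths are ``branch_floor + Exp(branch_mean)``
    within clades and ``backbone_length`` on the edges separating the
    architecture clades. ``substitution_rate`` is in substitutions per
    site per unit branch length.
    """

    seed: int
    n_taxa: int = 60
    substitution_rate: float = 0.1
    branch_floor: float = 0.3
    branch_mean: float = 0.25
    backbone_length: float = 0.8
    # module lengths (residues)
    gh2n_len: int = 180
    gh2d_len: int = 300
    gh2c_len: int = 320
    duf4981_len: int = 100
    duf4982_len: int = 110
    small_subunit_len: int = 220
    big1_len: int = 90
    type5_tail_len: int = 250
    type4_ext_len: int = 200
    decoration_len: int = 150
    # scenario switches
    type1_fraction: float = 0.25
    type4_fraction: float = 0.20
    type5_fraction: float = 0.25
    type2_fraction: float = 0.30  # of the type-3 clade
    type3_replaced_fraction: float = 0.15
    type3_appended_fraction: float = 0.10
    type5_big1_free_fraction: float = 0.30
    planted_gh2c_positions: tuple = (40, 110, 200, 260)  # 1-based, in GH2C
    # noise knobs
    dropout_prob: float = 0.0
    coverage_jitter: float = 0.0
    n_hybrid_contaminants: int = 0
    n_duplicate_gh2c: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        for p in (self.dropout_prob, self.coverage_jitter):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_taxa < 8:
            raise ValueError("the default scenario needs at least 8 taxa")


@dataclass
class TruthSet:
    """Pre-noise ground truth for one emitted dataset."""

    tree: TreeNode
    da_type: dict
    subtype: dict
    partner_map: dict
    planted_gh2c_positions: tuple
    designated_clade: list  # leaves where planted columns are invariant
    clean_hits: dict

    def enzyme_ids(self) -> list:
        """Ids of GH2C-bearing records (small-subunit partner records
        excluded)."""
        return [sid for sid, t in self.da_type.items() if t != "2M"]


@dataclass
class SynthDataset:
    config: SynthConfig
    sequences: dict
    hits: dict
    truth: TruthSet
    big1_references: list

    def gh2c_region(self, seq_id: str, from_truth: bool = True) -> str:
        source = self.truth.clean_hits if from_truth else self.hits
        for hit in source[seq_id]:
            if hit.domain == "GH2C":
                return self.sequences[seq_id].residues[
                    hit.env_start - 1 : hit.env_end
                ]
        raise KeyError(f"no GH2C hit on {seq_id}")


# ---------------------------------------------------------------------------
# tree simulation


def sample_tree(n_taxa: int, seed: int, branch_mean: float = 0.3,
                branch_floor: float = 0.0) -> TreeNode:
    """Random bifurcating tree over ``n_taxa`` labelled leaves.

    Topology by uniform sequential joins; branch lengths are
    ``branch_floor`` plus an exponential draw. Deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i:03d}" for i in range(1, n_taxa + 1)]
    return _random_subtree(labels, rng, branch_mean, branch_floor)


def _random_subtree(labels: Sequence[str], rng, branch_mean: float,
                    branch_floor: float) -> TreeNode:
    nodes = []
    for name in labels:
        leaf = TreeNode(name=name)
        leaf.length = branch_floor + rng.exponential(branch_mean)
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.length = branch_floor + rng.exponential(branch_mean)
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# sequence evolution


def random_root_sequence(length: int, rng) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)].astype(str))


def evolve_sequences(
    tree: TreeNode,
    root_sequence: str,
    rate: float,
    rng=None,
    planted_positions: Sequence[int] = (),
    planted_clade_leaves: Sequence[str] = (),
) -> dict:
    """Evolve a sequence down a tree by independent-site substitution.

    Along a branch of length ``b`` each site substitutes with
    probability ``1 − exp(−rate·b)``, replaced uniformly by one of the
    19 other residues. ``planted_positions`` (1-based) are reset to the
    root residue in every leaf of ``planted_clade_leaves``, making those
    columns invariant within the designated clade. Rate 0 reproduces the
    root at every leaf.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    root = np.array(
        [AMINO_ACIDS.index(c) for c in root_sequence], dtype=np.int64
    )
    leaves: dict = {}

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            p = 1.0 - np.exp(-rate * b)
            child_state = state.copy()
            if p > 0:
                mask = rng.random(len(child_state)) < p
                if mask.any():
                    shift = rng.integers(1, 20, size=int(mask.sum()))
                    child_state[mask] = (child_state[mask] + shift) % 20
            if child.is_tip():
                leaves[child.name] = child_state
            else:
                descend(child, child_state)

    if tree.is_tip():
        leaves[tree.name] = root.copy()
    else:
        descend(tree, root)
    planted = [p - 1 for p in planted_positions]
    clade = set(planted_clade_leaves)
    out = {}
    for name, state in leaves.items():
        if planted and name in clade:
            state[planted] = root[planted]
        out[name] = "".join(_AA[state].astype(str))
    return out


# ---------------------------------------------------------------------------
# scenario painting


def _allocate_clades(config: SynthConfig) -> dict:
    n = config.n_taxa
    n1 = max(2, round(n * config.type1_fraction))
    n4 = max(2, round(n * config.type4_fraction))
    n5 = max(2, round(n * config.type5_fraction))
    n3 = n - n1 - n4 - n5
    if n3 < 4:
        raise ValueError("too few taxa for the type-3 clade")
    n2 = max(2, round(n3 * config.type2_fraction))
    return {"1": n1, "4": n4, "5": n5, "3": n3 - n2, "2": n2}


def build_scenario_tree(config: SynthConfig, rng) -> TreeNode:
    """The backbone topology of the evolutionary scenario.

    Rooted as ``(type1, (type4, (type5, type3)))``. The bicistronic
    subclade is grafted onto an internal branch *inside* the type-3
    clade, so the type-3 label is paraphyletic with respect to type 2 —
    bicistronic enzymes emerge from within the canonical
    β-galactosidases. Clade roots are named ``clade_type<k>`` so the
    painting step can find them.
    """
    sizes = _allocate_clades(config)
    counter = [0]

    def labels(k: int) -> list:
        out = [f"t{counter[0] + i:03d}" for i in range(1, k + 1)]
        counter[0] += k
        return out

    def clade(tag: str, k: int) -> TreeNode:
        sub = _random_subtree(
            labels(k), rng, config.branch_mean, config.branch_floor
        )
        sub.name = f"clade_type{tag}"
        sub.length = config.backbone_length
        return sub

    c1 = clade("1", sizes["1"])
    c4 = clade("4", sizes["4"])
    c5 = clade("5", sizes["5"])
    c3 = clade("3", sizes["3"])
    c2 = clade("2", sizes["2"])
    _graft_inside(c3, c2, rng)
    inner2 = TreeNode()
    inner2.length = config.backbone_length
    inner2.extend([c5, c3])
    inner1 = TreeNode()
    inner1.length = config.backbone_length
    inner1.extend([c4, inner2])
    root = TreeNode()
    root.extend([c1, inner1])
    return root


def _graft_inside(host: TreeNode, graft: TreeNode, rng) -> None:
    """Attach ``graft`` onto a branch inside ``host``: a non-root node of
    ``host`` is replaced by a new node whose children are that node and
    the graft. The split branch shares its length between the two new
    edges so path lengths below stay comparable."""
    candidates = [n for n in host.traverse() if n is not host]
    target = candidates[int(rng.integers(0, len(candidates)))]
    parent = target.parent
    half = (target.length or 0.0) / 2.0
    parent.remove(target)
    junction = TreeNode()
    junction.length = half
    target.length = half
    junction.extend([target, graft])
    parent.append(junction)


def paint_da_scenario(tree: TreeNode, config: SynthConfig, rng=None) -> dict:
    """Per-leaf DA type plus module plan from the named scenario clades.

    The root state is the bare core; each named clade gains its
    C-terminal modules. Within the type-3 clade the nested bicistronic
    subclade is planned as two loci (core-only large subunit plus a
    standalone small-subunit partner). Subtype variants (replaced /
    appended type 3, BIG1-free type 5) are drawn per leaf.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    plans: dict = {}
    found = set()
    for tag, da_type in (("clade_type1", "1"), ("clade_type4", "4"),
                         ("clade_type5", "5"), ("clade_type3", "3"),
                         ("clade_type2", "2")):
        nodes = [n for n in tree.traverse() if n.name == tag]
        if not nodes:
            raise ValueError(f"scenario clade {tag!r} missing from tree")
        found.add(tag)
        for leaf in sorted(nodes[0].tips(), key=lambda t: t.name):
            plans[leaf.name] = {"da_type": da_type, "modules": None}
    for name in sorted(plans):
        plan = plans[name]
        t = plan["da_type"]
        if t == "1":
            plan["modules"] = ["GH2N", "GH2d", "GH2C"]
            plan["subtype"] = "1"
        elif t == "2":
            plan["modules"] = ["GH2N", "GH2d", "GH2C"]
            plan["subtype"] = "2-bicistronic"
            plan["partner"] = f"{name}_M"
        elif t == "3":
            u = rng.random()
            if u < config.type3_replaced_fraction:
                plan["modules"] = ["GH2N", "gh2d_like", "GH2C", "DUF4981",
                                   "Bgal_Small_N"]
                plan["subtype"] = "3-replaced"
            elif u < config.type3_replaced_fraction + config.type3_appended_fraction:
                plan["modules"] = ["GH2N", "GH2d", "GH2C", "DUF4981",
                                   "Bgal_Small_N", "F5_F8_type_C"]
                plan["subtype"] = "3-appended"
            else:
                plan["modules"] = ["GH2N", "GH2d", "GH2C", "DUF4981",
                                   "Bgal_Small_N"]
                plan["subtype"] = "3-canonical"
        elif t == "4":
            plan["modules"] = ["GH2N", "GH2d", "GH2C", "ct_ext4"]
            plan["subtype"] = "4"
        elif t == "5":
            if rng.random() < config.type5_big1_free_fraction:
                plan["modules"] = ["GH2N", "GH2d", "GH2C", "DUF4982",
                                   "ct_tail5"]
                plan["subtype"] = "5-Cter"
            else:
                plan["modules"] = ["GH2N", "GH2d", "GH2C", "DUF4982",
                                   "big1_like", "ct_tail5"]
                plan["subtype"] = "5-BIG1_Cter"
    return plans


# modules annotated in the emitted domain table, with the coverage the
# annotation claims pre-jitter; unannotated stretches never appear there
_ANNOTATED = {
    "GH2N": 0.92,
    "GH2d": 0.90,
    "GH2C": 0.95,
    "DUF4981": 0.88,
    "DUF4982": 0.88,
    "Bgal_Small_N": 0.90,
    "F5_F8_type_C": 0.85,
}


def _module_length(module: str, config: SynthConfig) -> int:
    return {
        "GH2N": config.gh2n_len,
        "GH2d": config.gh2d_len,
        "gh2d_like": config.gh2d_len,
        "GH2C": config.gh2c_len,
        "DUF4981": config.duf4981_len,
        "DUF4982": config.duf4982_len,
        "Bgal_Small_N": config.small_subunit_len,
        "big1_like": config.big1_len,
        "ct_tail5": config.type5_tail_len,
        "ct_ext4": config.type4_ext_len,
        "F5_F8_type_C": config.decoration_len,
    }[module]


def generate(config: SynthConfig) -> SynthDataset:
    """Build the full in-memory dataset: tree, sequences, annotations,
    truth; then apply the configured noise."""
    rng = np.random.default_rng(config.seed)
    tree = build_scenario_tree(config, rng)
    plans = paint_da_scenario(tree, config, rng)
    leaf_names = sorted(plans)
    type5_leaves = [n for n in leaf_names if plans[n]["da_type"] == "5"]

    # one root sequence per module family, each evolved along the tree
    module_names = ["GH2N", "GH2d", "gh2d_like", "GH2C", "DUF4981",
                    "DUF4982", "Bgal_Small_N", "big1_like", "ct_tail5",
                    "ct_ext4", "F5_F8_type_C"]
    roots = {
        m: random_root_sequence(_module_length(m, config), rng)
        for m in module_names
    }
    evolved = {}
    for m in module_names:
        evolved[m] = evolve_sequences(
            tree,
            roots[m],
            config.substitution_rate,
            rng,
            planted_positions=(
                config.planted_gh2c_positions if m == "GH2C" else ()
            ),
            planted_clade_leaves=type5_leaves if m == "GH2C" else (),
        )

    sequences: dict = {}
    clean_hits: dict = {}
    da_type: dict = {}
    subtype: dict = {}
    partner_map: dict = {}
    for name in leaf_names:
        plan = plans[name]
        residues = ""
        hits = []
        pos = 1
        for module in plan["modules"]:
            part = evolved[module][name]
            end = pos + len(part) - 1
            if module in _ANNOTATED:
                hits.append(
                    DomainHit(name, module, pos, end, _ANNOTATED[module],
                              source="synthetic")
                )
            residues += part
            pos = end + 1
        sequences[name] = SequenceRecord(name, residues, f"synthetic DA type {plan['da_type']}")
        clean_hits[name] = hits
        da_type[name] = plan["da_type"]
        subtype[name] = plan["subtype"]
        if plan["da_type"] == "2":
            pid = plan["partner"]
            partner_map[name] = pid
            part = evolved["Bgal_Small_N"][name]
            sequences[pid] = SequenceRecord(
                pid, part, "synthetic small subunit (LacM)"
            )
            clean_hits[pid] = [
                DomainHit(pid, "Bgal_Small_N", 1, len(part),
                          _ANNOTATED["Bgal_Small_N"], source="synthetic")
            ]
            da_type[pid] = "2M"
            subtype[pid] = "2M"

    big1_refs = [SequenceRecord("BIG1_ref", roots["big1_like"],
                                "reference BIG1-like module")]
    truth = TruthSet(
        tree=tree,
        da_type=da_type,
        subtype=subtype,
        partner_map=partner_map,
        planted_gh2c_positions=tuple(config.planted_gh2c_positions),
        designated_clade=list(type5_leaves),
        clean_hits={k: list(v) for k, v in clean_hits.items()},
    )

    noisy = _apply_noise(sequences, clean_hits, config, rng, truth)
    return SynthDataset(
        config=config,
        sequences=noisy[0],
        hits=noisy[1],
        truth=truth,
        big1_references=big1_refs,
    )


def _apply_noise(sequences, clean_hits, config: SynthConfig, rng, truth):
    """Dropout, coverage jitter and contaminant records, applied after
    the truth snapshot."""
    sequences = dict(sequences)
    hits: dict = {}
    for sid in sorted(clean_hits):
        kept = []
        for hit in clean_hits[sid]:
            if config.dropout_prob > 0 and rng.random() < config.dropout_prob:
                continue
            cov = hit.model_coverage
            if config.coverage_jitter > 0:
                cov = float(
                    np.clip(
                        cov + rng.uniform(-config.coverage_jitter,
                                          config.coverage_jitter),
                        0.0, 1.0,
                    )
                )
            kept.append(replace(hit, model_coverage=cov))
        hits[sid] = kept

    core = ["GH2N", "GH2d", "GH2C"]
    for k in range(config.n_hybrid_contaminants):
        sid = f"contam_hybrid{k + 1:02d}"
        residues, rec_hits = _contaminant(core + ["Glyco_transf_2"], sid,
                                          config, rng)
        sequences[sid] = SequenceRecord(sid, residues, "synthetic hybrid contaminant")
        hits[sid] = rec_hits
        truth.da_type[sid] = "contaminant"
        truth.subtype[sid] = "hybrid"
        truth.clean_hits[sid] = list(rec_hits)
    for k in range(config.n_duplicate_gh2c):
        sid = f"contam_dupC{k + 1:02d}"
        residues, rec_hits = _contaminant(core + ["GH2C"], sid, config, rng)
        sequences[sid] = SequenceRecord(sid, residues, "synthetic duplicate-GH2C contaminant")
        hits[sid] = rec_hits
        truth.da_type[sid] = "contaminant"
        truth.subtype[sid] = "duplicate_gh2c"
        truth.clean_hits[sid] = list(rec_hits)
    return sequences, hits


def _contaminant(modules, sid, config: SynthConfig, rng):
    residues = ""
    hits = []
    pos = 1
    for module in modules:
        length = (
            _module_length(module, config) if module != "Glyco_transf_2" else 180
        )
        part = random_root_sequence(length, rng)
        end = pos + length - 1
        coverage = _ANNOTATED.get(module, 0.85)
        hits.append(DomainHit(sid, module, pos, end, coverage,
                              source="synthetic"))
        residues += part
        pos = end + 1
    return residues, hits


# ---------------------------------------------------------------------------
# file emission


def emit_dataset(config: SynthConfig, outdir) -> dict:
    """Write the dataset in the exact formats the readers consume.

    Byte-identical output for identical config + seed. Returns the path
    map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate(config)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "domains": outdir / "domains.tsv",
        "partners": outdir / "partners.tsv",
        "big1_refs": outdir / "big1_refs.fasta",
        "truth_types": outdir / "truth_types.tsv",
        "truth_tree": outdir / "truth_tree.nwk",
        "truth_domains": outdir / "truth_domains.tsv",
        "truth_planted": outdir / "truth_planted.tsv",
    }
    ordered_ids = sorted(ds.sequences)
    write_fasta([ds.sequences[s] for s in ordered_ids], paths["fasta"])
    write_domain_table(
        [h for s in ordered_ids for h in ds.hits.get(s, [])], paths["domains"]
    )
    with open(paths["partners"], "w") as fh:
        fh.write("seq_id\tpartner_id\n")
        for sid in sorted(ds.truth.partner_map):
            fh.write(f"{sid}\t{ds.truth.partner_map[sid]}\n")
    write_fasta(ds.big1_references, paths["big1_refs"])
    with open(paths["truth_types"], "w") as fh:
        fh.write("seq_id\tda_type\tsubtype\n")
        for sid in ordered_ids:
            fh.write(
                f"{sid}\t{ds.truth.da_type[sid]}\t{ds.truth.subtype[sid]}\n"
            )
    write_newick(ds.truth.tree, paths["truth_tree"])
    write_domain_table(
        [h for s in ordered_ids for h in ds.truth.clean_hits.get(s, [])],
        paths["truth_domains"],
    )
    with open(paths["truth_planted"], "w") as fh:
        fh.write("gh2c_position\n")
        for p in ds.truth.planted_gh2c_positions:
            fh.write(f"{p}\n")
        fh.write("# designated clade leaves\n")
        for sid in ds.truth.designated_clade:
            fh.write(f"# {sid}\n")
    return {k: str(v) for k, v in paths.items()}


def audit_classification(
    calls, rejected: Mapping, truth: TruthSet, noisy_hits: Mapping
) -> dict:
    """Compare classifier output with truth and explain every miss.

    Agreement is computed over enzyme records that passed the admission
    filter. Each disagreement is annotated with the domain hits that
    noise removed from that sequence (the usual cause); rejections of
    genuine enzymes (e.g. a dropped GH2C annotation) are listed
    separately.
    """
    calls_by_id = {c.seq_id: c for c in calls}
    comparable = [
        sid for sid in truth.enzyme_ids()
        if truth.da_type[sid] != "contaminant" and sid in calls_by_id
    ]
    misses = []
    agree = 0
    for sid in comparable:
        if calls_by_id[sid].da_type == truth.da_type[sid]:
            agree += 1
        else:
            misses.append(sid)
    explanations = {}
    for sid in misses:
        clean = {(h.domain, h.env_start) for h in truth.clean_hits[sid]}
        seen = {(h.domain, h.env_start) for h in noisy_hits.get(sid, [])}
        dropped = sorted(d for d, _ in clean - seen)
        explanations[sid] = {
            "truth": truth.da_type[sid],
            "called": calls_by_id[sid].da_type,
            "dropped_domains": dropped,
        }
    genuine_rejected = {
        sid: reason
        for sid, reason in rejected.items()
        if truth.da_type.get(sid) not in ("contaminant", "2M", None)
    }
    return {
        "n_comparable": len(comparable),
        "n_agree": agree,
        "agreement": agree / len(comparable) if comparable else float("nan"),
        "misses": explanations,
        "rejected_enzymes": genuine_rejected,
    }
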