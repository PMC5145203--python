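"""Stage glue shared by the command-line interface and scripts.

Each helper takes in-memory objects from one stage and produces the
inputs of the next, so the CLI subcommands stay thin wrappers over the
library.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .annot_io import DomainHit, SequenceRecord
from .arch_classify import ClassifierConfig, DATypeCall, classify_dataset
from .cterm import Big1Rule, CtExtension, extract_ct_extension, tag_big1
from .da_encoding import build_architecture
from .msa import MSA, progressive_align
from .phylo import bootstrap_support, condense


def gh2c_regions(
    sequences: Mapping[str, SequenceRecord],
    hits: Mapping[str, Sequence[DomainHit]],
    gh2c_name: str = "GH2C",
) -> list:
    """Cut the catalytic-module (GH2C) envelope out of each sequence that
    carries exactly one GH2C hit."""
    out = []
    for sid in sorted(sequences):
        gh2c = [h for h in hits.get(sid, []) if h.domain == gh2c_name]
        if len(gh2c) != 1:
            continue
        hit = gh2c[0]
        out.append((sid, sequences[sid].residues[hit.env_start - 1 : hit.env_end]))
    return out


def tree_stage(
    regions: Sequence[tuple],
    n_replicates: int = 100,
    seed: int = 0,
    method: str = "kimura",
    condense_threshold: float = 0.5,
):
    """Align catalytic modules, build the bootstrap NJ tree and condense
    weak edges; returns (msa, supported tree, condensed tree)."""
    msa = progressive_align(regions)
    tree = bootstrap_support(msa, n_replicates=n_replicates, seed=seed,
                             method=method)
    condensed = condense(tree, condense_threshold)
    return msa, tree, condensed


def classify_stage(
    sequences: Mapping[str, SequenceRecord],
    hits: Mapping[str, Sequence[DomainHit]],
    companion_table: Mapping[str, str] | None = None,
    config: ClassifierConfig | None = None,
):
    return classify_dataset(sequences, hits, config=config,
                            companion_table=companion_table)


def extension_stage(
    sequences: Mapping[str, SequenceRecord],
    hits: Mapping[str, Sequence[DomainHit]],
    calls: Sequence[DATypeCall],
    big1_references: Sequence[SequenceRecord] = (),
    min_length: int = 60,
) -> tuple:
    """Extract C-terminal extensions of type-4/5 sequences and tag the
    BIG1-like ones. Returns (extensions, tags by seq_id)."""
    call_type = {c.seq_id: c.da_type for c in calls}
    extensions: list[CtExtension] = []
    for sid in sorted(sequences):
        if call_type.get(sid) not in ("4", "5"):
            continue
        arch = build_architecture(list(hits.get(sid, [])), len(sequences[sid]))
        ext = extract_ct_extension(sequences[sid], arch, min_length)
        if ext is not None:
            extensions.append(ext)
    tags = {}
    if big1_references:
        rule = Big1Rule(references=list(big1_references))
        for ext in extensions:
            tags[ext.seq_id] = tag_big1(ext.residues, rule)
    return extensions, tags
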