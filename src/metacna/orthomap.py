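"""Projecting a target genome onto the reference enzyme orthology network.

Given an orthology/homology table relating reference genes to target genes,
a target genome's copy-number vector over the isoenzyme groups is built in
three assignment steps:

1. every target gene with an ortholog inside some group is counted in that
   group (a gene whose orthologs span several groups goes to the group
   holding the plurality of them; exact ties go to the lexicographically
   smallest group id, with a warning);
2. remaining "orphan" target genes that are *homologous* to members of
   exactly one group join it (homologs of two or more groups stay
   unassigned);
3. remaining gene families of at least ``min_family_size`` members whose
   annotated reference members all lie in a single group are assigned there.

An audit records which step placed each gene; genes absent from the table
are ignored (most of a genome is non-metabolic).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .isoenzyme import EnzymeOrthologyNetwork

__all__ = ["OrthologyTable", "read_orthology_table", "map_genome_to_network"]

_RELATIONS = {"ortholog", "homolog"}
_COLUMNS = ["reference_gene", "target_gene", "relation", "family"]


@dataclass
class OrthologyTable:
    """Rows of (reference_gene, target_gene, relation, family)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"orthology table missing columns: {sorted(missing)}")
        bad = set(self.rows["relation"].unique()) - _RELATIONS
        if bad:
            raise ValueError(f"unknown relation values: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str) -> "OrthologyTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str) -> None:
        self.rows[_COLUMNS].to_csv(path, sep="\t", index=False)


def read_orthology_table(path: str) -> OrthologyTable:
    return OrthologyTable.from_tsv(path)


@dataclass
class MappingAudit:
    by_step: dict[int, dict[str, str]] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)

    def step_of(self, gene: str) -> int | None:
        for step, placed in self.by_step.items():
            if gene in placed:
                return step
        return None


def map_genome_to_network(
    net: EnzymeOrthologyNetwork,
    orth: OrthologyTable,
    target_genes: set[str] | None = None,
    species: str = "target",
    min_family_size: int = 2,
) -> tuple[pd.Series, MappingAudit]:
    """Copy-number vector of a target genome over the network's groups.

    ``target_genes`` restricts the table to a gene universe; by default all
    target genes in the table are considered.  Returns a group-indexed
    integer Series (named after the species) and the assignment audit.
    """
    rows = orth.rows
    if target_genes is not None:
        rows = rows[rows["target_gene"].isin(target_genes)]

    group_of_ref = {
        g: grp.id for grp in net.groups for g in grp.genes
    }
    counts = {grp.id: 0 for grp in net.groups}
    audit = MappingAudit(by_step={1: {}, 2: {}, 3: {}})

    # step 1: orthologs
    ortho = rows[rows["relation"] == "ortholog"]
    for tg, sub in ortho.groupby("target_gene"):
        groups = Counter(
            group_of_ref[rg]
            for rg in sub["reference_gene"]
            if rg in group_of_ref
        )
        if not groups:
            continue
        top = max(groups.values())
        best = sorted(g for g, c in groups.items() if c == top)
        if len(best) > 1:
            warnings.warn(
                f"target gene {tg!r} has orthologs tied across groups "
                f"{best}; assigned to {best[0]!r}"
            )
        counts[best[0]] += 1
        audit.by_step[1][tg] = best[0]

    assigned = set(audit.by_step[1])

    # step 2: orphans homologous to exactly one group
    homol = rows[rows["relation"] == "homolog"]
    for tg, sub in homol.groupby("target_gene"):
        if tg in assigned:
            continue
        groups = {
            group_of_ref[rg]
            for rg in sub["reference_gene"]
            if rg in group_of_ref
        }
        if len(groups) == 1:
            gid = next(iter(groups))
            counts[gid] += 1
            audit.by_step[2][tg] = gid
            assigned.add(tg)

    # step 3: families whose annotated reference members fall in one group
    for fam, sub in rows.groupby("family"):
        tg_in_family = set(sub["target_gene"]) - assigned
        if not tg_in_family:
            continue
        if len(set(sub["target_gene"])) < min_family_size:
            continue
        ref_groups = {
            group_of_ref[rg]
            for rg in sub["reference_gene"]
            if rg in group_of_ref
        }
        if len(ref_groups) == 1:
            gid = next(iter(ref_groups))
            for tg in sorted(tg_in_family):
                counts[gid] += 1
                audit.by_step[3][tg] = gid
                assigned.add(tg)

    all_targets = set(rows["target_gene"])
    audit.unassigned = all_targets - assigned
    vec = pd.Series(counts, name=species, dtype=int)
    return vec.sort_index(), audit
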