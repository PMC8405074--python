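"""Second analysis cycle: consensus biomarker discovery.

Intersects tumor-compartment DEGs with PBMC-compartment DEGs (optionally
requiring direction agreement), then with the topologically central gene
set, keeping a full provenance record of why each gene survived — the
cross-compartment logic behind a single consensus biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .topology import CentralGeneSet

__all__ = ["ConsensusResult", "shared_degs", "consensus_with_central"]


@dataclass
class ConsensusResult:
    shared_degs: set[str]
    consensus: set[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.provenance):
            rec = {"gene": gene, **self.provenance[gene]}
            rows.append(rec)
        return pd.DataFrame(rows)


def _significant_directions(tables: list[pd.DataFrame], combine: str) -> dict[str, set[str]]:
    """Per-gene set of directions among tables where the gene is significant;
    a gene qualifies in the compartment if significant in all (or any)
    tables per ``combine``."""
    per_table = []
    for t in tables:
        sig = t[t["significant"]]
        per_table.append(dict(zip(sig["gene"], sig["direction"])))
    if combine == "all":
        genes = set.intersection(*(set(d) for d in per_table)) if per_table else set()
    elif combine == "any":
        genes = set().union(*(set(d) for d in per_table))
    else:
        raise ValueError(f"combine must be 'all' or 'any', got {combine!r}")
    return {g: {d[g] for d in per_table if g in d} for g in genes}


def shared_degs(
    tumor,
    pbmc,
    require_same_direction: bool = True,
    combine: str = "all",
) -> tuple[set[str], dict[str, dict]]:
    """Genes significant in both compartments (each given as one DEG table
    or a list of tables combined by significance-in-``combine``).

    With ``require_same_direction`` a gene must move the same way in every
    table it is counted from — the situation of a biomarker overexpressed
    in both the tumor and the circulating immune cells.
    Returns (gene set, per-gene provenance).
    """
    tumor_tables = tumor if isinstance(tumor, list) else [tumor]
    pbmc_tables = pbmc if isinstance(pbmc, list) else [pbmc]
    for t in tumor_tables + pbmc_tables:
        if len(t) == 0:
            raise ValueError("empty DEG table")
    t_dir = _significant_directions(tumor_tables, combine)
    p_dir = _significant_directions(pbmc_tables, combine)

    shared: set[str] = set()
    provenance: dict[str, dict] = {}
    for gene in sorted(set(t_dir) & set(p_dir)):
        dirs = t_dir[gene] | p_dir[gene]
        agree = len(dirs) == 1
        if require_same_direction and not agree:
            continue
        shared.add(gene)
        provenance[gene] = {
            "significant_tumor": True,
            "significant_pbmc": True,
            "direction_tumor": "/".join(sorted(t_dir[gene])),
            "direction_pbmc": "/".join(sorted(p_dir[gene])),
            "direction_agrees": agree,
        }
    return shared, provenance


def consensus_with_central(
    shared: set[str],
    central: CentralGeneSet,
    provenance: dict[str, dict] | None = None,
) -> ConsensusResult:
    """Intersect the shared-DEG set with the central gene set.

    An empty intersection is a valid outcome; the provenance trail records,
    per shared gene, whether it was a hub, in the high-betweenness tier,
    and hence central.
    """
    if not central.central:
        raise ValueError("central gene set is empty")
    prov = {g: dict(rec) for g, rec in (provenance or {}).items()}
    consensus = set()
    for gene in sorted(shared):
        rec = prov.setdefault(gene, {})
        rec["is_hub"] = gene in central.hubs
        rec["is_high_betweenness"] = gene in central.high_betweenness
        rec["is_central"] = gene in central.central
        rec["is_consensus"] = gene in central.central
        if rec["is_consensus"]:
            consensus.add(gene)
    return ConsensusResult(shared_degs=set(shared), consensus=consensus, provenance=prov)
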