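"""Per-gene TF binding sets and shared-site Venn partitions across promoters."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .promoter_scan import MotifHit


@dataclass(frozen=True)
class TFBindingSet:
    """TF names with at least one surviving hit in one gene's promoter."""

    gene_id: str
    tfs: frozenset[str]
    best_hits: Mapping[str, MotifHit]  # per TF: highest relative_score, then smallest offset

    def __post_init__(self) -> None:
        object.__setattr__(self, "tfs", frozenset(self.tfs))
        if set(self.best_hits) != self.tfs:
            raise ValueError("best_hits keys must equal the TF set")


@dataclass(frozen=True)
class VennPartition:
    """Disjoint exclusive regions keyed by frozenset of gene ids."""

    gene_ids: tuple[str, ...]
    regions: Mapping[frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        members = [tfs for tfs in self.regions.values()]
        union: set[str] = set()
        total = 0
        for tfs in members:
            union |= tfs
            total += len(tfs)
        if total != len(union):
            raise AssertionError("Venn regions are not pairwise disjoint")

    def region(self, *gene_ids: str) -> frozenset[str]:
        return self.regions.get(frozenset(gene_ids), frozenset())

    def counts(self) -> dict[str, int]:
        return {
            "&".join(sorted(k)): len(v) for k, v in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        }

    def to_json_obj(self) -> dict[str, list[str]]:
        return {
            "&".join(sorted(k)): sorted(v) for k, v in sorted(
                self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        }


def tf_set(hits: Iterable[MotifHit]) -> TFBindingSet:
    """Reduce one gene's surviving hits to TF presence plus best-hit metadata."""
    hits = list(hits)
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise ValueError(f"hits span several genes: {sorted(genes)}")
    best: dict[str, MotifHit] = {}
    for h in hits:
        cur = best.get(h.tf_name)
        if cur is None or (-h.relative_score, h.local_offset) < (
            -cur.relative_score, cur.local_offset
        ):
            best[h.tf_name] = h
    gene_id = genes.pop() if genes else ""
    return TFBindingSet(gene_id=gene_id, tfs=frozenset(best), best_hits=best)


def venn_partition(sets: Sequence[TFBindingSet]) -> VennPartition:
    """Partition the union of 2-3 TF sets into subset-exclusive regions.

    Region ``{g1, g2}`` holds the TFs present in exactly ``g1`` and ``g2``
    and no other input gene; regions are disjoint and cover the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition takes 2 or 3 TF sets")
    ids = [s.gene_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate gene ids: {ids}")
    by_gene = {s.gene_id: s.tfs for s in sets}
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            inside = set.intersection(*(set(by_gene[g]) for g in combo))
            outside = set().union(*(by_gene[g] for g in ids if g not in combo))
            regions[frozenset(combo)] = frozenset(inside - outside)
    part = VennPartition(gene_ids=tuple(ids), regions=regions)
    union = set().union(*by_gene.values())
    covered = set().union(*part.regions.values()) if part.regions else set()
    assert covered == union, "Venn regions do not cover the union"
    return part


def genes_with_tf(sets: Iterable[TFBindingSet], tf: str) -> list[str]:
    """Sorted gene ids whose surviving TF set contains ``tf`` (case-insensitive)."""
    needle = tf.lower()
    return sorted(s.gene_id for s in sets if any(t.lower() == needle for t in s.tfs))
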