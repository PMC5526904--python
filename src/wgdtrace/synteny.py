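"""Outgroup-anchored paralog families and sliding-window synteny detection.

After a whole-genome duplication, surviving duplicate ("ohnolog") pairs tend
to sit in two genomic regions that preserve an ordered run of paralogous
gene pairs — a paralogon. Detection here follows the classic recipe:

1. *Anchoring*: each paralog family is validated against an unduplicated
   outgroup proteome. Members with no outgroup hit below the E-value cutoff
   are dropped; families whose members hit different outgroup proteins are
   split into subgroups, each anchored to its shared top hit; subgroups with
   fewer than two members are discarded.
2. *Detection*: anchored pairs between the two regions are chained into
   maximal runs whose region-B ranks are monotone — increasing (direct) or
   decreasing (inverted) — with the sliding window enforced as a locality
   constraint: successive pairs of a run must lie within the window width
   on *both* regions. The longest such chain is extracted repeatedly until
   fewer than ``min_pairs`` pairs remain; ties are broken by a canonical
   region-order-independent key so the decomposition is symmetric in the
   two regions.

Gene order is by rank along the chromosome (order_index), not base pairs;
strand is recorded but orientation is defined purely by rank monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .homology import HitRecord, _hit_sort_key

__all__ = [
    "GeneLocus",
    "ParalogFamily",
    "SyntenyBlock",
    "loci_from_table",
    "anchor_paralog_families",
    "detect_syntenic_blocks",
]


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    order_index: int
    strand: str = "+"
    family_id: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ParalogFamily:
    family_id: str
    member_ids: tuple[str, ...]
    anchor_id: str | None = None


@dataclass(frozen=True)
class SyntenyBlock:
    """An ordered run of anchored gene pairs between two regions."""

    pairs: tuple[tuple[GeneLocus, GeneLocus], ...]
    orientation: str  # {"direct", "inverted"}

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.order_index for a, _ in self.pairs]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [b.order_index for _, b in self.pairs]
        return min(ranks), max(ranks)

    @property
    def pair_ids(self) -> frozenset[tuple[str, str]]:
        return frozenset((a.gene_id, b.gene_id) for a, b in self.pairs)


def loci_from_table(rows: Sequence[tuple], family_of: Mapping[str, str] | None = None
                    ) -> list[GeneLocus]:
    """Build rank-ordered loci from (gene_id, chrom, start, strand) rows
    (the output of :func:`wgdtrace.core_io.read_gene_loci`); order_index is
    the 0-based rank of the gene along its chromosome by start coordinate."""
    loci = []
    by_chrom: dict[str, list[tuple]] = {}
    for r in rows:
        by_chrom.setdefault(r[1], []).append(r)
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r[2])
        for rank, (gene_id, _c, _s, strand) in enumerate(rs):
            fam = family_of.get(gene_id) if family_of else None
            loci.append(GeneLocus(gene_id, chrom, rank, strand, fam))
    return loci


# ---------------------------------------------------------------------------
# Outgroup anchoring
# ---------------------------------------------------------------------------


def anchor_paralog_families(
    families: Iterable[ParalogFamily],
    outgroup_hits: Mapping[str, Sequence[HitRecord]] | Sequence[HitRecord],
    e_max: float = 1e-10,
) -> list[ParalogFamily]:
    """Validate and split paralog families by outgroup anchoring.

    ``outgroup_hits`` maps member gene_id -> its hits against the outgroup
    proteome (or is a flat hit list keyed by ``query_id``). Members with no
    hit at E < ``e_max`` are discarded; each family is partitioned by its
    members' top outgroup hit (module tie rule); only subgroups with >= 2
    members survive, anchored to the shared top hit. Subgroup family ids are
    suffixed ``:ANCHOR`` when a family splits.
    """
    if not isinstance(outgroup_hits, Mapping):
        table: dict[str, list[HitRecord]] = {}
        for h in outgroup_hits:
            table.setdefault(h.query_id, []).append(h)
        outgroup_hits = table

    out: list[ParalogFamily] = []
    for fam in families:
        by_anchor: dict[str, list[str]] = {}
        for member in fam.member_ids:
            hits = [h for h in outgroup_hits.get(member, []) if h.evalue < e_max]
            if not hits:
                continue  # no outgroup hit: member discarded
            top = min(hits, key=_hit_sort_key)
            by_anchor.setdefault(top.subject_id, []).append(member)
        survivors = {a: m for a, m in by_anchor.items() if len(m) >= 2}
        split = len(survivors) > 1
        for anchor in sorted(survivors):
            fid = f"{fam.family_id}:{anchor}" if split else fam.family_id
            out.append(
                ParalogFamily(
                    family_id=fid,
                    member_ids=tuple(survivors[anchor]),
                    anchor_id=anchor,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Block detection
# ---------------------------------------------------------------------------


def _chain_key(chain: list[int], pair_ids: list[tuple[str, ...]]):
    """Canonical, region-order-independent identity of a chain (the sorted
    tuple of its unordered gene-id pairs) — used only to break ties so the
    decomposition is symmetric under swapping regions A and B."""
    return tuple(sorted(pair_ids[i] for i in chain))


def _best_monotone_chain(
    coords: list[tuple[int, int]],
    pair_ids: list[tuple[str, ...]],
    indices: list[int],
    sign: int,
    max_gap: int,
) -> list[int]:
    """Longest strictly monotone chain (O(n^2) DP) over the ``indices``
    subset of pairs; successive chain members must be within ``max_gap``
    ranks on both regions. Ties resolved by the canonical chain key."""
    order = sorted(indices, key=lambda i: (coords[i][0], coords[i][1]))
    chains: dict[int, list[int]] = {}
    for i in order:
        best_prev: list[int] = []
        for j in order:
            if j == i:
                break
            aj, bj = coords[j]
            ai, bi = coords[i]
            if not (aj < ai and sign * (bi - bj) > 0):
                continue
            if ai - aj > max_gap or abs(bi - bj) > max_gap:
                continue
            cand = chains[j]
            if len(cand) > len(best_prev) or (
                len(cand) == len(best_prev) and best_prev
                and _chain_key(cand, pair_ids) < _chain_key(best_prev, pair_ids)
            ):
                best_prev = cand
        chains[i] = best_prev + [i]
    if not chains:
        return []
    return min(
        chains.values(),
        key=lambda c: (-len(c), _chain_key(c, pair_ids)),
    )


def _anchored_pairs(
    region_a: Sequence[GeneLocus],
    region_b: Sequence[GeneLocus],
    families: Iterable[ParalogFamily] | None,
    same_region: bool,
) -> list[tuple[GeneLocus, GeneLocus]]:
    if families is not None:
        fam_of: dict[str, str] = {}
        for fam in families:
            for m in fam.member_ids:
                fam_of[m] = fam.family_id
        a_loc = [replace(l, family_id=fam_of.get(l.gene_id)) for l in region_a]
        b_loc = [replace(l, family_id=fam_of.get(l.gene_id)) for l in region_b]
    else:
        a_loc, b_loc = list(region_a), list(region_b)
    by_fam_b: dict[str, list[GeneLocus]] = {}
    for l in b_loc:
        if l.family_id is not None:
            by_fam_b.setdefault(l.family_id, []).append(l)
    pairs = []
    for a in a_loc:
        if a.family_id is None:
            continue
        for b in by_fam_b.get(a.family_id, []):
            if same_region and a.gene_id == b.gene_id:
                continue  # trivial self-pair
            pairs.append((a, b))
    return pairs


def detect_syntenic_blocks(
    region_a: Sequence[GeneLocus],
    region_b: Sequence[GeneLocus],
    anchored_families: Iterable[ParalogFamily] | None = None,
    window_size: int = 100,
    min_pairs: int = 3,
) -> list[SyntenyBlock]:
    """Sliding-window detection of direct and inverted syntenic blocks.

    Anchored pairs are genes of the two regions sharing an (anchored)
    family; if ``anchored_families`` is None, the loci's own ``family_id``
    fields are used. The window constrains locality symmetrically:
    successive pairs of a block must lie within ``window_size`` gene ranks
    of each other on *both* regions. Blocks are extracted by repeatedly
    removing the longest strictly monotone chain (direct = increasing,
    inverted = decreasing in region-B rank) until none of at least
    ``min_pairs`` pairs remains; ties are broken by a canonical
    region-order-independent key, so swapping the two regions yields
    identical blocks.

    When the two regions are the same chromosome self-comparison rules
    apply: self-pairs are excluded and a block's A-span and B-span must not
    overlap.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    same_region = {l.gene_id for l in region_a} & {l.gene_id for l in region_b}
    pairs = _anchored_pairs(region_a, region_b, anchored_families,
                            bool(same_region))
    if not pairs:
        return []
    pairs.sort(key=lambda p: (p[0].order_index, p[1].order_index))
    coords = [(a.order_index, b.order_index) for a, b in pairs]
    pair_ids = [tuple(sorted((a.gene_id, b.gene_id))) for a, b in pairs]

    remaining = list(range(len(pairs)))
    found: list[tuple[str, list[int]]] = []
    while len(remaining) >= min_pairs:
        inc = _best_monotone_chain(coords, pair_ids, remaining, +1,
                                   window_size)
        dec = _best_monotone_chain(coords, pair_ids, remaining, -1,
                                   window_size)
        cands = [(c, o) for c, o in ((inc, "direct"), (dec, "inverted")) if c]
        if not cands:
            break
        chosen, orient = min(
            cands, key=lambda co: (-len(co[0]), _chain_key(co[0], pair_ids))
        )
        if len(chosen) < min_pairs:
            break
        found.append((orient, chosen))
        chosen_set = set(chosen)
        remaining = [i for i in remaining if i not in chosen_set]

    blocks = []
    for orient, idx in found:
        blk_pairs = tuple(
            sorted((pairs[i] for i in idx),
                   key=lambda p: (p[0].order_index, p[1].order_index))
        )
        blk = SyntenyBlock(pairs=blk_pairs, orientation=orient)
        if same_region:
            (a0, a1), (b0, b1) = blk.span_a, blk.span_b
            if not (a1 < b0 or b1 < a0):
                continue  # overlapping self-comparison spans
        blocks.append(blk)
    blocks.sort(key=lambda b: (b.span_a, b.span_b, b.orientation))
    return blocks


def shared_pair_count(blocks: Iterable[SyntenyBlock]) -> int:
    """Total number of distinct gene pairs across all blocks."""
    seen: set[tuple[str, str]] = set()
    for b in blocks:
        seen |= b.pair_ids
    return len(seen)
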