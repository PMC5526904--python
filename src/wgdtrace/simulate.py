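"""Synthetic-data generators with machine-readable ground truth.

Each generator is a pure function of (parameters, seed): codon alignments
evolved under branch-/site-class-specific omega on a known tree; duplicated
gene orders produced by a WGD with per-copy loss, inversions and
translocations; rate-divergent protein alignments for two paralog clusters;
and forward/reverse similarity-hit tables with planted reciprocal-best
structure. A :class:`SimulationTruth` records every true parameter so any
downstream stage can be scored without re-deriving the answer.

One global seed fans out to per-generator independent streams (the stream
key is the generator's name), so adding a generator never perturbs the
output of an existing one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._codons import get_code
from .codonml import CodonModelSpec, _class_matrices, _eigen, _p_matrix
from .core_io import CodonAlignment, GeneTree, SequenceRecord, Alignment
from .homology import HitRecord
from .synteny import GeneLocus, ParalogFamily, SyntenyBlock

__all__ = [
    "SimulationTruth",
    "simulate_codon_alignment",
    "simulate_wgd_gene_orders",
    "simulate_divergent_clusters",
    "simulate_hit_table",
]

_STREAM_KEYS = {
    "codon": 1, "wgd": 2, "diverge": 3, "hits": 4,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationTruth:
    """Ground truth shipped with every simulated dataset."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    return str(obj)


def _rng(generator: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(_STREAM_KEYS[generator],))
    )


# ---------------------------------------------------------------------------
# Codon alignments under GY94
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: GeneTree,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along ``tree`` under a GY94 model.

    Root codons are drawn from the model's equilibrium frequencies; each
    site is assigned a site class from the mixture proportions; along every
    branch the child state is sampled from exp(Q_{class} t). Only sense
    codons are ever emitted.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    code = get_code(spec.genetic_code)
    rng = _rng("codon", seed)
    pi = spec.frequencies.pi
    mats = _class_matrices(spec)
    props = np.array([sc.proportion for sc in spec.site_classes])
    site_class = rng.choice(len(props), size=n_codons, p=props / props.sum())
    root_state = rng.choice(code.n, size=n_codons, p=pi / pi.sum())

    # transition matrices per (branch class, site class, branch length)
    eigs = {
        bc: [_eigen(m, pi) for m in mats[bc]] for bc in mats
    }

    states: dict[int, np.ndarray] = {}
    nodes = tree.postorder()
    node_index = {id(n): i for i, n in enumerate(nodes)}
    root_i = len(nodes) - 1
    states[root_i] = root_state
    leaf_seqs: dict[str, np.ndarray] = {}
    # preorder: parents before children
    for i in range(root_i, -1, -1):
        node = nodes[i]
        if i != root_i:
            parent_i = node_index[id(node.parent)]
            t = node.length if node.length is not None else 0.0
            bc = node.branch_class if node.branch_class in eigs else 0
            parent_state = states[parent_i]
            child = np.empty(n_codons, dtype=int)
            for k in range(len(props)):
                mask = site_class == k
                if not mask.any():
                    continue
                P = _p_matrix(eigs[bc][k], t)
                P = P / P.sum(axis=1, keepdims=True)
                sub = parent_state[mask]
                u = rng.random(sub.size)
                cum = np.cumsum(P, axis=1)
                child[mask] = (cum[sub] < u[:, None]).sum(axis=1)
            states[i] = np.minimum(child, code.n - 1)
        if node.is_leaf:
            leaf_seqs[node.name] = states[i]

    records = [
        SequenceRecord(
            name, "".join(code.codons[s] for s in leaf_seqs[name]), "dna"
        )
        for name in tree.leaf_names
    ]
    aln = CodonAlignment(records, genetic_code=spec.genetic_code)
    truth = SimulationTruth(
        generator="codon", seed=seed,
        parameters={
            "family": spec.family,
            "kappa": spec.kappa,
            "site_classes": [
                {"proportion": sc.proportion, "omega": dict(sc.omega)}
                for sc in spec.site_classes
            ],
            "n_codons": n_codons,
            "site_class_assignment": site_class,
            "tree_leaves": tree.leaf_names,
        },
    )
    return aln, truth


# ---------------------------------------------------------------------------
# WGD gene orders
# ---------------------------------------------------------------------------


def simulate_wgd_gene_orders(
    n_genes: int,
    retention: float,
    n_inversions: int = 0,
    n_translocations: int = 0,
    seed: int = 0,
) -> tuple[list[GeneLocus], list[GeneLocus], list[ParalogFamily],
           SimulationTruth]:
    """Duplicate an ancestral gene order and degrade the two copies.

    Each copy of each ancestral gene survives independently with probability
    ``retention``; region B then suffers ``n_inversions`` random segment
    reversals and ``n_translocations`` random segment moves. Every ancestral
    gene founds a two-member paralog family anchored to its own outgroup
    protein, so all surviving A/B copy pairs are anchored pairs by
    construction. The truth records the surviving pair list and the
    rearrangement breakpoints.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not (0.0 <= retention <= 1.0):
        raise ValueError("retention must be in [0, 1]")
    rng = _rng("wgd", seed)
    keep_a = rng.random(n_genes) < retention
    keep_b = rng.random(n_genes) < retention

    order_a = [g for g in range(n_genes) if keep_a[g]]
    order_b = [g for g in range(n_genes) if keep_b[g]]
    orient_b = {g: "+" for g in order_b}

    inversions = []
    for _ in range(n_inversions):
        if len(order_b) < 2:
            break
        i, j = sorted(rng.integers(0, len(order_b), size=2))
        j = min(j + 1, len(order_b))
        if j - i < 2:
            j = min(i + 2, len(order_b))
        seg = order_b[i:j][::-1]
        order_b[i:j] = seg
        for g in seg:
            orient_b[g] = "-" if orient_b[g] == "+" else "+"
        inversions.append((i, j))
    translocations = []
    for _ in range(n_translocations):
        if len(order_b) < 3:
            break
        i, j = sorted(rng.integers(0, len(order_b), size=2))
        j = min(j + 1, len(order_b))
        seg = order_b[i:j]
        rest = order_b[:i] + order_b[j:]
        k = int(rng.integers(0, len(rest) + 1))
        order_b = rest[:k] + seg + rest[k:]
        translocations.append((i, j, k))

    region_a = [
        GeneLocus(f"A_g{g}", "regionA", rank, "+", family_id=f"fam{g}")
        for rank, g in enumerate(order_a)
    ]
    region_b = [
        GeneLocus(f"B_g{g}", "regionB", rank, orient_b[g], family_id=f"fam{g}")
        for rank, g in enumerate(order_b)
    ]
    families = [
        ParalogFamily(
            family_id=f"fam{g}",
            member_ids=(f"A_g{g}", f"B_g{g}"),
            anchor_id=f"OUT_g{g}",
        )
        for g in range(n_genes)
        if keep_a[g] and keep_b[g]
    ]
    true_pairs = sorted(
        (f"A_g{g}", f"B_g{g}") for g in range(n_genes)
        if keep_a[g] and keep_b[g]
    )
    truth = SimulationTruth(
        generator="wgd", seed=seed,
        parameters={
            "n_genes": n_genes,
            "retention": retention,
            "n_inversions": n_inversions,
            "n_translocations": n_translocations,
            "true_pairs": true_pairs,
            "inversion_breakpoints": inversions,
            "translocation_breakpoints": translocations,
        },
    )
    return region_a, region_b, families, truth


# ---------------------------------------------------------------------------
# Rate-divergent protein clusters
# ---------------------------------------------------------------------------


def _evolve_protein(tree: GeneTree, rates: np.ndarray, root: np.ndarray,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve residues along a tree with per-column rates under a uniform
    20-state exchange model (every substitution picks a uniformly random
    different residue)."""
    n = rates.size
    nodes = tree.postorder()
    node_index = {id(nd): i for i, nd in enumerate(nodes)}
    states = {len(nodes) - 1: root}
    out = {}
    for i in range(len(nodes) - 1, -1, -1):
        node = nodes[i]
        if i != len(nodes) - 1:
            t = node.length if node.length is not None else 0.0
            parent = states[node_index[id(node.parent)]]
            n_sub = rng.poisson(rates * t)
            cur = parent.copy()
            for col in np.nonzero(n_sub)[0]:
                for _ in range(n_sub[col]):
                    new = rng.integers(0, 19)
                    cur[col] = new if new < cur[col] else new + 1
            states[i] = cur
        if node.is_leaf:
            out[node.name] = states[i]
    return out


def simulate_divergent_clusters(
    tree_a: GeneTree,
    tree_b: GeneTree,
    n_columns: int,
    theta: float,
    shape: float = 1.0,
    seed: int = 0,
) -> tuple[Alignment, SimulationTruth]:
    """Protein alignment of two clusters with a fraction ``theta`` of
    rate-divergent columns.

    Per column, with probability ``theta`` the two clusters draw independent
    gamma(shape) rates (type-I divergence); otherwise they share one rate.
    Residues evolve independently along each cluster's tree under a uniform
    exchangeability model from a common root residue.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must be in [0, 1]")
    rng = _rng("diverge", seed)
    divergent = rng.random(n_columns) < theta
    shared = rng.gamma(shape, 1.0 / shape, size=n_columns)
    rate_a = shared.copy()
    rate_b = shared.copy()
    n_div = int(divergent.sum())
    rate_a[divergent] = rng.gamma(shape, 1.0 / shape, size=n_div)
    rate_b[divergent] = rng.gamma(shape, 1.0 / shape, size=n_div)
    root = rng.integers(0, 20, size=n_columns)
    seqs_a = _evolve_protein(tree_a, rate_a, root, rng)
    seqs_b = _evolve_protein(tree_b, rate_b, root, rng)
    records = [
        SequenceRecord(name, "".join(AMINO_ACIDS[s] for s in states), "protein")
        for name, states in list(seqs_a.items()) + list(seqs_b.items())
    ]
    truth = SimulationTruth(
        generator="diverge", seed=seed,
        parameters={
            "theta": theta, "shape": shape, "n_columns": n_columns,
            "divergent_columns": np.nonzero(divergent)[0],
            "cluster_a": tree_a.leaf_names, "cluster_b": tree_b.leaf_names,
        },
    )
    return Alignment(records), truth


# ---------------------------------------------------------------------------
# Hit tables with planted orthologs
# ---------------------------------------------------------------------------


def simulate_hit_table(
    n_queries: int,
    n_subjects: int,
    planted_ortholog_map: Mapping[str, str] | None = None,
    noise_hits: int = 0,
    n_forward_decoys: int = 0,
    seed: int = 0,
) -> tuple[list[HitRecord], dict[str, list[HitRecord]], SimulationTruth]:
    """Forward and reverse hit tables with a planted ortholog structure.

    Planted pairs (query -> subject) receive strong forward hits whose
    *reverse* best hit is the query. ``noise_hits`` adds weaker random
    forward hits whose reverse best hit points elsewhere. Each of
    ``n_forward_decoys`` plants, for one query with an ortholog, a decoy
    subject that outranks the true ortholog in the forward table (so the
    planted ortholog sits at forward rank 2) while the decoy's reverse best
    hit is not the query — exercising the reverse-best (not
    bidirectional-best) rule.
    """
    rng = _rng("hits", seed)
    queries = [f"Q{i}" for i in range(n_queries)]
    subjects = [f"S{j}" for j in range(n_subjects)]
    if planted_ortholog_map is None:
        k = min(n_queries, n_subjects)
        planted_ortholog_map = {queries[i]: subjects[i] for i in range(k)}
    else:
        values = list(planted_ortholog_map.values())
        if len(values) != len(set(values)):
            raise ValueError("planted map must be injective")

    forward: list[HitRecord] = []
    reverse: dict[str, list[HitRecord]] = {s: [] for s in subjects}

    for q, s in planted_ortholog_map.items():
        e = 10.0 ** (-50 + rng.uniform(-2, 2))
        forward.append(HitRecord(q, s, e, bitscore=500 + rng.uniform(0, 50)))
        reverse[s].append(HitRecord(s, q, e, bitscore=500 + rng.uniform(0, 50)))
        # weaker reverse self-noise
        other = rng.choice([x for x in queries if x != q]) if n_queries > 1 else None
        if other is not None:
            reverse[s].append(
                HitRecord(s, str(other), 1e-8, bitscore=100 + rng.uniform(0, 10))
            )

    with_orth = sorted(planted_ortholog_map)
    decoys = []
    for d in range(min(n_forward_decoys, len(with_orth))):
        q = with_orth[d]
        decoy = f"D{d}"
        subjects.append(decoy)
        forward.append(
            HitRecord(q, decoy, 1e-80, bitscore=900 + rng.uniform(0, 10))
        )
        other_q = queries[(queries.index(q) + 1) % n_queries]
        reverse[decoy] = [
            HitRecord(decoy, other_q, 1e-90, bitscore=950.0),
            HitRecord(decoy, q, 1e-60, bitscore=700.0),
        ]
        decoys.append(decoy)

    for _ in range(noise_hits):
        q = queries[int(rng.integers(0, n_queries))]
        s = subjects[int(rng.integers(0, n_subjects))]
        if planted_ortholog_map.get(q) == s:
            continue
        e = 10.0 ** rng.uniform(-8, -1)
        forward.append(HitRecord(q, s, e, bitscore=40 + rng.uniform(0, 20)))
        best_other = [x for x in queries if x != q]
        if best_other:
            reverse.setdefault(s, []).append(
                HitRecord(s, str(rng.choice(best_other)), e / 10,
                          bitscore=80 + rng.uniform(0, 20))
            )

    truth = SimulationTruth(
        generator="hits", seed=seed,
        parameters={
            "n_queries": n_queries, "n_subjects": n_subjects,
            "planted_ortholog_map": dict(planted_ortholog_map),
            "noise_hits": noise_hits, "forward_decoys": decoys,
        },
    )
    return forward, reverse, truth
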