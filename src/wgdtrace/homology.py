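"""Homolog screening over externally produced similarity-search tables.

Three operations mirror the screening stages of a domain-centric homolog
survey: (1) filtering profile-HMM domain hits on sequence/domain E-values
and fractional coverage of the HMM; (2) greedy incremental redundancy
clustering of near-identical sequences (CD-HIT-like: longest-first, join the
best-matching representative above identity and short-sequence-coverage
thresholds); (3) reverse-best-hit orthology: a forward hit is accepted as a
putative ortholog when the *reverse* search's best hit is the query — the
forward hit itself is deliberately not required to rank first.

Ties everywhere are broken by bitscore (descending), then E-value
(ascending), then subject id (lexicographic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .core_io import SequenceRecord

__all__ = [
    "DomainHit",
    "HitRecord",
    "SequenceCluster",
    "read_domtblout",
    "write_domtblout",
    "read_blast_tab",
    "write_blast_tab",
    "rank_hits",
    "filter_domain_hits",
    "cluster_redundant_sequences",
    "assign_orthologs",
]


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM domain hit (one domtblout row)."""

    target_id: str
    query_domain: str
    seq_evalue: float
    dom_evalue: float
    env_from: int
    env_to: int
    hmm_from: int
    hmm_to: int
    hmm_length: int

    def __post_init__(self):
        if self.hmm_length <= 0:
            raise ValueError(f"{self.target_id!r}: non-positive hmm_length")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"{self.target_id!r}: malformed HMM coords "
                f"{self.hmm_from}-{self.hmm_to} (length {self.hmm_length})"
            )
        if self.env_from > self.env_to or self.env_from < 1:
            raise ValueError(f"{self.target_id!r}: malformed envelope coords")
        if self.seq_evalue < 0 or self.dom_evalue < 0:
            raise ValueError(f"{self.target_id!r}: negative E-value")

    @property
    def hmm_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_length


@dataclass(frozen=True)
class HitRecord:
    """One pairwise search hit (one BLAST outfmt-6 row), optionally ranked
    within its query."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    rank: int | None = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class SequenceCluster:
    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def _hit_sort_key(h: HitRecord):
    # bitscore desc, e-value asc, subject id lexicographic — the module-wide
    # tie rule
    return (-h.bitscore, h.evalue, h.subject_id)


def rank_hits(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Assign within-query ranks (1 = best) under the module tie rule."""
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = []
    for q in by_query:
        for i, h in enumerate(sorted(by_query[q], key=_hit_sort_key), start=1):
            out.append(replace(h, rank=i))
    return out


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------


def read_domtblout(path: str | Path, dom_evalue: str = "conditional"
                   ) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` (whitespace-delimited, '#' comments).

    ``dom_evalue`` selects which per-domain E-value populates
    :attr:`DomainHit.dom_evalue`: 'conditional' (c-Evalue, column 12) or
    'independent' (i-Evalue, column 13).
    """
    if dom_evalue not in ("conditional", "independent"):
        raise ValueError(f"unknown dom_evalue dialect {dom_evalue!r}")
    col = 11 if dom_evalue == "conditional" else 12
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        hits.append(
            DomainHit(
                target_id=f[0],
                query_domain=f[3],
                seq_evalue=float(f[6]),
                dom_evalue=float(f[col]),
                env_from=int(f[19]),
                env_to=int(f[20]),
                hmm_from=int(f[15]),
                hmm_to=int(f[16]),
                hmm_length=int(f[5]),
            )
        )
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in HMMER3 domtblout column layout (both per-domain E-value
    columns carry :attr:`DomainHit.dom_evalue`)."""
    with open(path, "w") as fh:
        fh.write("# target_name acc tlen query_name acc qlen E-value score "
                 "bias # of c-Evalue i-Evalue score bias hmm_from hmm_to "
                 "ali_from ali_to env_from env_to acc description\n")
        for h in hits:
            fh.write(
                f"{h.target_id} - {h.env_to} {h.query_domain} - "
                f"{h.hmm_length} {h.seq_evalue:.2g} 100.0 0.0 1 1 "
                f"{h.dom_evalue:.2g} {h.dom_evalue:.2g} 100.0 0.0 "
                f"{h.hmm_from} {h.hmm_to} {h.env_from} {h.env_to} "
                f"{h.env_from} {h.env_to} 0.90 -\n"
            )


def read_blast_tab(path: str | Path) -> list[HitRecord]:
    """Parse BLAST tabular outfmt 6 (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        hits.append(
            HitRecord(
                query_id=f[0], subject_id=f[1],
                evalue=float(f[10]), bitscore=float(f[11]),
            )
        )
    return hits


def write_blast_tab(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as BLAST tabular outfmt 6 (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t90.0\t100\t10\t0\t1\t100\t"
                f"1\t100\t{h.evalue:.6g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_domain_hits(
    hits: Sequence[DomainHit],
    seq_e_max: float = 1e-2,
    dom_e_max: float = 1e-2,
    min_coverage: float = 0.5,
    merge_domains: bool = False,
) -> list[DomainHit]:
    """Keep hits with seq E <= ``seq_e_max``, domain E <= ``dom_e_max`` and
    HMM coverage >= ``min_coverage`` (all thresholds inclusive); input order
    is preserved.

    With ``merge_domains=True`` the coverage test instead uses, per target
    protein, the union of that protein's E-value-passing HMM spans (summed
    envelope); the E-value tests stay per hit.
    """
    passing = [
        h for h in hits
        if h.seq_evalue <= seq_e_max and h.dom_evalue <= dom_e_max
    ]
    if not merge_domains:
        return [h for h in passing if h.hmm_coverage >= min_coverage]
    # summed-envelope coverage per (target, HMM)
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in passing:
        spans.setdefault((h.target_id, h.query_domain), []).append(
            (h.hmm_from, h.hmm_to)
        )
    covered: dict[tuple[str, str], int] = {}
    for key, ivs in spans.items():
        ivs.sort()
        total, cur_a, cur_b = 0, *ivs[0]
        for a, b in ivs[1:]:
            if a > cur_b + 1:
                total += cur_b - cur_a + 1
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        total += cur_b - cur_a + 1
        covered[key] = total
    return [
        h for h in passing
        if covered[(h.target_id, h.query_domain)] / h.hmm_length >= min_coverage
    ]


def _local_identity_coverage(short: str, long: str) -> tuple[float, float]:
    """Best local alignment of the shorter sequence against the longer one:
    (identity over alignment columns, aligned fraction of the shorter)."""
    aligner = Align.PairwiseAligner(
        mode="local", match_score=2, mismatch_score=-3,
        open_gap_score=-6, extend_gap_score=-1,
    )
    try:
        aln = aligner.align(long, short)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    cols = 0
    matches = 0
    short_aligned = 0
    a, b = aln[0], aln[1]
    for x, y in zip(a, b):
        cols += 1
        if y != "-":
            short_aligned += 1
        if x == y and x != "-":
            matches += 1
    if cols == 0:
        return 0.0, 0.0
    return matches / cols, short_aligned / len(short)


def cluster_redundant_sequences(
    seqs: Sequence[SequenceRecord],
    identity_min: float = 0.95,
    short_coverage_min: float = 0.6,
) -> list[SequenceCluster]:
    """Greedy incremental redundancy clustering.

    Sequences are processed longest first (ties by id). Each sequence joins
    the *best-matching* existing representative (highest local-alignment
    identity, ties by earlier-founded cluster) whose identity >=
    ``identity_min`` and whose aligned coverage of the shorter sequence >=
    ``short_coverage_min``; otherwise it founds a new cluster. The
    representative is the (first-seen, hence longest) founding member.
    Clusters partition the input.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda r: (-len(r.ungapped), r.id))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        best_i = None
        best_ident = -1.0
        for i, rep in enumerate(reps):
            s, l = (rec.ungapped, rep.ungapped)
            if len(s) > len(l):
                s, l = l, s
            ident, cov = _local_identity_coverage(s, l)
            if ident >= identity_min and cov >= short_coverage_min:
                if ident > best_ident:
                    best_ident = ident
                    best_i = i
        if best_i is None:
            reps.append(rec)
            members.append([rec.id])
        else:
            members[best_i].append(rec.id)
    return [
        SequenceCluster(representative_id=rep.id, member_ids=tuple(mem))
        for rep, mem in zip(reps, members)
    ]


def assign_orthologs(
    query_id: str,
    forward_hits: Sequence[HitRecord],
    reverse_hits: Mapping[str, Sequence[HitRecord]],
    e_max: float = 1e-3,
) -> set[str]:
    """Reverse-best-hit orthology.

    Returns every forward subject with forward E-value <= ``e_max`` whose
    reverse search's best hit (rank 1 under the tie rule, E <= ``e_max``)
    is ``query_id``. Forward rank is deliberately not required to be 1.
    Raises KeyError if a candidate has no reverse table.
    """
    candidates = [
        h for h in forward_hits if h.query_id == query_id and h.evalue <= e_max
    ]
    orthologs: set[str] = set()
    for h in candidates:
        if h.subject_id not in reverse_hits:
            raise KeyError(
                f"no reverse hit table for candidate {h.subject_id!r}"
            )
        rev = list(reverse_hits[h.subject_id])
        if not rev:
            continue
        best = min(rev, key=_hit_sort_key)
        if best.subject_id == query_id and best.evalue <= e_max:
            orthologs.add(h.subject_id)
    return orthologs
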