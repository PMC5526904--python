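"""Nei–Gojobori (1986) pairwise dN/dS and clade/domain substitution summaries.

The NG86 method counts, for each codon, the expected number of synonymous
(S) and nonsynonymous (N) *sites* — the per-position fraction of single-
nucleotide changes that preserve the amino acid — and, for each codon pair,
the observed synonymous (Sd) and nonsynonymous (Nd) *differences*, averaging
equally over all shortest mutational pathways between the two codons.
Pathways passing through stop codons are excluded and the remaining pathways
re-weighted equally; likewise, changes to stop codons are excluded from site
counting with per-position renormalization. Proportions pS = Sd/S̄ and
pN = Nd/N̄ are Jukes–Cantor corrected: d = −(3/4)·ln(1 − (4/3)·p), which is
undefined for p ≥ 3/4 (flagged, never clamped).

Clade summaries average the pairwise values over all within-clade pairs,
optionally restricted to named domain partitions of a reference sequence;
ω is reported as mean(dN)/mean(dS) by default, with a mean-of-ratios
alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Iterable, Mapping, Sequence

from ._codons import get_code
from .core_io import CodonAlignment, DomainPartition, map_residue_ranges

NT = "TCAG"

__all__ = [
    "SiteCounts",
    "PairwiseDnDs",
    "CladeRateSummary",
    "ng86_codon_sites",
    "ng86_pairwise",
    "clade_rate_summary",
]


@dataclass(frozen=True)
class SiteCounts:
    """Synonymous (S) and nonsynonymous (N) site counts, in codon units."""

    S: float
    N: float


@dataclass(frozen=True)
class PairwiseDnDs:
    """Full NG86 pairwise result; ``dS``/``dN``/``omega`` are None when the
    Jukes–Cantor correction is undefined (p ≥ 3/4) or, for omega, dS = 0."""

    Sd: float
    Nd: float
    S_bar: float
    N_bar: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int  # codons compared after pairwise deletion


@dataclass(frozen=True)
class CladeRateSummary:
    clade: str
    partition: str | None
    mean_dN: float | None
    mean_dS: float | None
    omega: float | None
    n_pairs: int
    n_undefined: int  # pairs excluded from at least one average


def _is_unambiguous(codon: str) -> bool:
    return all(c in NT for c in codon)


@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str, genetic_code: int = 1) -> SiteCounts:
    """NG86 site decomposition of one sense codon.

    Per position, the synonymous fraction is computed over the non-stop
    single-nucleotide changes at that position (renormalized when a stop
    neighbor is excluded); a position whose three alternatives are all stops
    contributes no sites.
    """
    code = get_code(genetic_code)
    codon = codon.upper().replace("U", "T")
    if not code.is_sense(codon):
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = code.translate(codon)
    S = 0.0
    N = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for alt in NT:
            if alt == codon[pos]:
                continue
            neighbor = codon[:pos] + alt + codon[pos + 1 :]
            if code.is_stop(neighbor):
                continue
            nonstop += 1
            if code.translate(neighbor) == aa:
                syn += 1
        if nonstop:
            S += syn / nonstop
            N += (nonstop - syn) / nonstop
    return SiteCounts(S=S, N=N)


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str, genetic_code: int) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons: equal weighting over all shortest
    stop-free mutational pathways; if every pathway crosses a stop codon,
    all pathways are used with stop-involving steps counted nonsynonymous."""
    code = get_code(genetic_code)
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool):
        syn = nonsyn = 0
        cur = c1
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if code.is_stop(nxt) and not allow_stops:
                return None
            a1 = code.translate(cur) if not code.is_stop(cur) else "*"
            a2 = code.translate(nxt) if not code.is_stop(nxt) else "*"
            if a1 == a2 and a1 != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    results = [r for r in (walk(o, False) for o in permutations(diffs)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(diffs)]
    Sd = sum(r[0] for r in results) / len(results)
    Nd = sum(r[1] for r in results) / len(results)
    return Sd, Nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pairwise(
    codons_a: Sequence[str] | str,
    codons_b: Sequence[str] | str,
    genetic_code: int = 1,
) -> PairwiseDnDs:
    """NG86 dN/dS between two equal-length in-frame codon sequences.

    Codons containing a gap or ambiguity in *either* sequence are deleted
    pairwise before counting. Accepts codon lists or plain nucleotide
    strings (length divisible by 3).
    """
    if isinstance(codons_a, str):
        codons_a = [codons_a[k : k + 3] for k in range(0, len(codons_a), 3)]
    if isinstance(codons_b, str):
        codons_b = [codons_b[k : k + 3] for k in range(0, len(codons_b), 3)]
    if len(codons_a) != len(codons_b):
        raise ValueError(
            f"length mismatch: {len(codons_a)} vs {len(codons_b)} codons"
        )
    code = get_code(genetic_code)
    S_a = S_b = N_a = N_b = 0.0
    Sd = Nd = 0.0
    n_used = 0
    for ca, cb in zip(codons_a, codons_b):
        ca = ca.upper().replace("U", "T")
        cb = cb.upper().replace("U", "T")
        if not (_is_unambiguous(ca) and _is_unambiguous(cb)):
            continue  # pairwise deletion of gapped/ambiguous codons
        if code.is_stop(ca) or code.is_stop(cb):
            raise ValueError(f"stop codon in input pair ({ca}, {cb})")
        n_used += 1
        sa = ng86_codon_sites(ca, genetic_code)
        sb = ng86_codon_sites(cb, genetic_code)
        S_a += sa.S
        N_a += sa.N
        S_b += sb.S
        N_b += sb.N
        ds, dn = _pair_differences(ca, cb, genetic_code)
        Sd += ds
        Nd += dn
    if n_used == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    S_bar = (S_a + S_b) / 2.0
    N_bar = (N_a + N_b) / 2.0
    pS = Sd / S_bar if S_bar > 0 else 0.0
    pN = Nd / N_bar if N_bar > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return PairwiseDnDs(
        Sd=Sd, Nd=Nd, S_bar=S_bar, N_bar=N_bar, pS=pS, pN=pN,
        dS=dS, dN=dN, omega=omega, n_codons=n_used,
    )


def clade_rate_summary(
    codon_aln: CodonAlignment,
    clades: Mapping[str, Iterable[str]],
    partitions: Sequence[DomainPartition] | None = None,
    reference_id: str | None = None,
    omega_mode: str = "ratio_of_means",
) -> list[CladeRateSummary]:
    """Average pairwise dN/dS within each clade, full-length and optionally
    per domain partition.

    Parameters
    ----------
    clades : mapping clade name -> member sequence ids (must be in the
        alignment; each clade needs >= 2 usable members).
    partitions : optional domain partitions, mapped through the alignment on
        ``reference_id``'s ungapped residue coordinates.
    omega_mode : 'ratio_of_means' (mean dN / mean dS; default) or
        'mean_of_ratios' (average of per-pair dN/dS over defined pairs).

    Pairs whose Jukes–Cantor correction is undefined are excluded from the
    affected average and tallied in ``n_undefined``.
    """
    if omega_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown omega_mode {omega_mode!r}")
    views: list[tuple[str | None, CodonAlignment]] = [(None, codon_aln)]
    if partitions:
        if reference_id is None:
            raise ValueError("partitions require a reference_id")
        for part in partitions:
            views.append((part.name, map_residue_ranges(codon_aln, part, reference_id)))

    out: list[CladeRateSummary] = []
    for part_name, view in views:
        for clade, members in clades.items():
            members = [m for m in members if m in view]
            if len(members) < 2:
                raise ValueError(
                    f"clade {clade!r} has fewer than 2 members in the alignment"
                )
            dns, dss, ratios = [], [], []
            n_undef = 0
            n_pairs = 0
            for a, b in combinations(members, 2):
                n_pairs += 1
                try:
                    pw = ng86_pairwise(
                        view.codons_of(a), view.codons_of(b),
                        genetic_code=view.genetic_code,
                    )
                except ValueError:
                    n_undef += 1
                    continue
                if pw.dN is None or pw.dS is None:
                    n_undef += 1
                if pw.dN is not None:
                    dns.append(pw.dN)
                if pw.dS is not None:
                    dss.append(pw.dS)
                if pw.omega is not None:
                    ratios.append(pw.omega)
            mean_dN = sum(dns) / len(dns) if dns else None
            mean_dS = sum(dss) / len(dss) if dss else None
            if omega_mode == "ratio_of_means":
                omega = (
                    mean_dN / mean_dS
                    if mean_dN is not None and mean_dS not in (None, 0.0)
                    else None
                )
            else:
                omega = sum(ratios) / len(ratios) if ratios else None
            out.append(
                CladeRateSummary(
                    clade=clade, partition=part_name, mean_dN=mean_dN,
                    mean_dS=mean_dS, omega=omega, n_pairs=n_pairs,
                    n_undefined=n_undef,
                )
            )
    return out
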