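"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions alone (enumeration over
neighbors, pathways, internal states or subsequences) and never calls the
implementation paths it is used to check.
"""

from itertools import combinations, permutations, product

import numpy as np

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
NT = "TCAG"


def translate(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """(S, N) by direct neighbor enumeration with per-position stop
    exclusion and renormalization."""
    aa = translate(codon)
    S = N = 0.0
    for pos in range(3):
        fates = []
        for alt in NT:
            if alt == codon[pos]:
                continue
            nb = codon[:pos] + alt + codon[pos + 1 :]
            if nb in _STOPS:
                continue
            fates.append(translate(nb) == aa)
        if fates:
            S += sum(fates) / len(fates)
            N += (len(fates) - sum(fates)) / len(fates)
    return S, N


def ng86_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) by enumerating all shortest mutational pathways, dropping
    those through stops and averaging equally over the survivors."""
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            steps.append(translate(cur) == translate(nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # all pathways stop-blocked: count steps, stops nonsyn
        for order in permutations(diffs):
            cur = c1
            steps = []
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                syn = (cur not in _STOPS and nxt not in _STOPS
                       and translate(cur) == translate(nxt))
                steps.append(syn)
                cur = nxt
            paths.append(steps)
    sd = np.mean([sum(steps) for steps in paths])
    nd = np.mean([len(steps) - sum(steps) for steps in paths])
    return float(sd), float(nd)


def ng86_pairwise_oracle(codons_a, codons_b):
    """Full pairwise NG86 from the definitions; returns a dict of fields."""
    import math

    Sd = Nd = Sa = Na = Sb = Nb = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if any(c not in NT for c in ca + cb):
            continue
        s, n = ng86_sites_oracle(ca)
        Sa += s
        Na += n
        s, n = ng86_sites_oracle(cb)
        Sb += s
        Nb += n
        sd, nd = ng86_diffs_oracle(ca, cb)
        Sd += sd
        Nd += nd
    S_bar = (Sa + Sb) / 2
    N_bar = (Na + Nb) / 2
    pS = Sd / S_bar if S_bar else 0.0
    pN = Nd / N_bar if N_bar else 0.0

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    dS, dN = jc(pS), jc(pN)
    omega = dN / dS if (dS not in (None, 0.0) and dN is not None) else None
    return {"Sd": Sd, "Nd": Nd, "S_bar": S_bar, "N_bar": N_bar,
            "pS": pS, "pN": pN, "dS": dS, "dN": dN, "omega": omega}


def random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    sense = [a + b + c for a, b, c in product(NT, repeat=3)
             if a + b + c not in _STOPS]
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


def exhaustive_4taxon_loglik(codons_by_leaf, topology, P, pi) -> float:
    """lnL of an unrooted 4-taxon tree ((A,B),(C,D)) by summing over all
    61 x 61 internal-state assignments.

    ``topology``: dict with leaf name -> P-matrix for its edge; 'internal':
    P-matrix for the internal edge. ``codons_by_leaf``: leaf -> codon index
    list. The root sits at the A/B junction.
    """
    n_sites = len(next(iter(codons_by_leaf.values())))
    lnL = 0.0
    n = pi.size
    for s in range(n_sites):
        a = codons_by_leaf["A"][s]
        b = codons_by_leaf["B"][s]
        c = codons_by_leaf["C"][s]
        d = codons_by_leaf["D"][s]
        total = 0.0
        for x in range(n):  # state at the A/B junction (root)
            for y in range(n):  # state at the C/D junction
                total += (
                    pi[x]
                    * P["A"][x, a]
                    * P["B"][x, b]
                    * P["internal"][x, y]
                    * P["C"][y, c]
                    * P["D"][y, d]
                )
        lnL += np.log(total)
    return float(lnL)


def longest_monotone_subsequence_oracle(pairs, sign):
    """Longest strictly monotone-in-b subsequence (strictly increasing in a)
    by exhaustive subset enumeration; pairs are (a_rank, b_rank) tuples.
    Returns the best pair subset (ties: lexicographically smallest)."""
    best: tuple = ()
    n = len(pairs)
    for size in range(n, 0, -1):
        candidates = []
        for combo in combinations(sorted(pairs), size):
            ok = all(
                combo[i][0] < combo[i + 1][0]
                and sign * (combo[i + 1][1] - combo[i][1]) > 0
                for i in range(len(combo) - 1)
            )
            if ok:
                candidates.append(combo)
        if candidates:
            best = min(candidates)
            break
    return best


def bh_oracle(pvals):
    """Benjamini–Hochberg step-up by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        k = m - rank_from_end  # 1-based rank
        val = min(pvals[idx] * m / k, prev)
        adj[idx] = val
        prev = val
    return adj
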