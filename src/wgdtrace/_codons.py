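"""Genetic-code tables and codon-pair classification.

Every codon-level computation in the package (NG86 site counting, the GY94
rate matrix, codon simulation) works on the list of *sense* codons of a
genetic code — stop codons are excluded from the state space. This module
builds, per NCBI translation-table id, the sense-codon index together with
precomputed single-nucleotide-neighbor classifications (which position
differs, transition vs transversion, synonymous vs nonsynonymous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: IUPAC nucleotide ambiguity codes -> set of unambiguous bases
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code restricted to its sense codons.

    Attributes
    ----------
    table_id : NCBI translation table id (1 = standard).
    codons : tuple of sense codons in fixed (T,C,A,G) lexicographic order.
    stops : frozenset of stop codons.
    aa : amino acid (one-letter) per sense codon, parallel to ``codons``.
    """

    table_id: int
    codons: tuple[str, ...]
    stops: frozenset[str]
    aa: tuple[str, ...]
    index: dict[str, int] = field(repr=False, hash=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.codons)

    def translate(self, codon: str) -> str:
        """Translate a sense codon; '*' for stops, 'X' for ambiguous."""
        codon = codon.upper().replace("U", "T")
        if codon in self.index:
            return self.aa[self.index[codon]]
        if codon in self.stops:
            return "*"
        return "X"

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stops

    def is_sense(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.index

    # -- single-nucleotide neighbor structure (built lazily, cached) --------

    @property
    def neighbor_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (i, j, ts, syn) over ordered sense-codon pairs differing at
        exactly one position: indices, transition flag, synonymous flag."""
        return _neighbor_pairs(self)


@lru_cache(maxsize=None)
def _neighbor_pairs(code: GeneticCode):
    ii, jj, ts, syn = [], [], [], []
    for i, ci in enumerate(code.codons):
        for j, cj in enumerate(code.codons):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[p], cj[p]))
            syn.append(code.aa[i] == code.aa[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    """Build a :class:`GeneticCode` from an NCBI translation-table id."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in stops
    )
    aa = tuple(table.forward_table["".join(c)] for c in (codons))
    index = {c: k for k, c in enumerate(codons)}
    return GeneticCode(table_id=table_id, codons=codons, stops=stops, aa=aa, index=index)


def codon_compatibility(codon: str, code: GeneticCode) -> np.ndarray:
    """Binary vector over sense codons compatible with a possibly ambiguous codon.

    A gap codon ('---') or fully unresolvable codon is compatible with every
    sense codon (treated as missing data). Raises ValueError if the codon
    resolves only to stop codons.
    """
    codon = codon.upper().replace("U", "T")
    if codon == "---" or any(c == "-" for c in codon):
        return np.ones(code.n)
    sets = []
    for c in codon:
        if c not in AMBIGUITY:
            raise ValueError(f"invalid nucleotide {c!r} in codon {codon!r}")
        sets.append(AMBIGUITY[c])
    mask = np.zeros(code.n)
    for combo in product(*sets):
        cd = "".join(combo)
        if cd in code.index:
            mask[code.index[cd]] = 1.0
    if not mask.any():
        raise ValueError(f"codon {codon!r} resolves only to stop codons")
    return mask
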