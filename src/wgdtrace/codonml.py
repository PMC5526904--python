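"""Goldman–Yang codon-model likelihoods, model fitting and LRTs.

The GY94 substitution process acts on the 61 sense codons. Instantaneous
rates are zero for multi-nucleotide changes; a single-nucleotide change
i -> j has rate proportional to the target codon's equilibrium frequency
pi_j, multiplied by kappa for transitions and by omega for nonsynonymous
changes. The model zoo:

========== ================================================================
family     parameterization
========== ================================================================
M0         one omega for all sites and branches
branch2    two-ratio branch model: omega_bg (class 0), omega_fg (class 1)
M1a        "nearly neutral": p0 with omega0 in (0,1), p1 with omega1 = 1
M2a_rel    M1a plus a third class with free shared omega2 > 0
CmC        clade model C: the third class's omega2 differs per clade
           (branch-class) partition; M2a_rel is its null
branchsiteA M1a background plus classes 2a/2b where the foreground takes
           omega2 >= 1; M1a is the null of branch-site test 1
========== ================================================================

Likelihoods are computed by Felsenstein pruning with transition matrices
exp(Q t) obtained from the eigendecomposition of the reversible generator
symmetrized by pi^{1/2}. Each branch class's matrices are scaled so one unit
of branch length is one expected substitution per codon under the model's
site-class mixture. Gap and ambiguous codons integrate over all compatible
sense codons. Branch lengths are, by default, estimated under M0 (by
per-edge Brent optimization on up/down partial likelihoods, alternated with
the rate parameters) and held fixed for the richer families; pass
``estimate_branch_lengths=True`` to co-estimate them anywhere.

Every fit can be launched from a grid of omega starting values; the
per-start results are retained in the returned :class:`FitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from ._codons import codon_compatibility, get_code
from .core_io import CodonAlignment, GeneTree, TreeNode

__all__ = [
    "CodonFrequencies",
    "SiteClass",
    "CodonModelSpec",
    "FitResult",
    "LRTResult",
    "build_gy94_matrix",
    "compute_tree_loglik",
    "fit_codon_model",
    "likelihood_ratio_test",
    "bh_adjust",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("M0", "branch2", "M1a", "M2a_rel", "CmC", "branchsiteA")

#: multi-start omega grids; the clade-model and branch-site grids follow the
#: common practice of spanning purifying through positive-selection starts
DEFAULT_OMEGA_STARTS: dict[str, tuple[float, ...]] = {
    "M0": (0.1, 1.0),
    "branch2": (0.1, 1.0),
    "M1a": (0.1, 0.5),
    "M2a_rel": (0.1, 1.0),
    "CmC": (0.001, 0.01, 0.1, 0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0, 10.0),
    "branchsiteA": (1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 10.0),
}

_MIN_PI = 1e-8
_MIN_T = 1e-8
_MAX_T = 50.0


# ---------------------------------------------------------------------------
# Frequencies and model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over the sense codons of a genetic code."""

    mode: str  # {"uniform", "F1x4", "F3x4", "F61"}
    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1 or np.any(pi < 0) or not math.isclose(pi.sum(), 1.0,
                                                              abs_tol=1e-8):
            raise ValueError("pi must be a non-negative vector summing to 1")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def uniform(cls, genetic_code: int = 1) -> "CodonFrequencies":
        n = get_code(genetic_code).n
        return cls("uniform", np.full(n, 1.0 / n))

    @classmethod
    def from_alignment(cls, aln: CodonAlignment, mode: str = "F3x4"
                       ) -> "CodonFrequencies":
        """Empirical frequencies: F61 (observed codons), F3x4 (product of
        position-specific nucleotide frequencies) or F1x4 (overall
        nucleotide frequencies); stops excluded, renormalized."""
        code = get_code(aln.genetic_code)
        nt_index = {c: i for i, c in enumerate("TCAG")}
        if mode == "uniform":
            return cls.uniform(aln.genetic_code)
        if mode == "F61":
            counts = np.zeros(code.n)
            for rec in aln.records:
                for k in range(0, len(rec.seq), 3):
                    cd = rec.seq[k : k + 3].upper().replace("U", "T")
                    if cd in code.index:
                        counts[code.index[cd]] += 1
            pi = _floor_and_normalize(counts)
            return cls("F61", pi)
        if mode in ("F3x4", "F1x4"):
            pos_counts = np.zeros((3, 4))
            for rec in aln.records:
                for k in range(0, len(rec.seq), 3):
                    cd = rec.seq[k : k + 3].upper().replace("U", "T")
                    if cd in code.index:
                        for p, c in enumerate(cd):
                            pos_counts[p, nt_index[c]] += 1
            if mode == "F1x4":
                pos_counts = np.tile(pos_counts.sum(axis=0), (3, 1))
            with np.errstate(invalid="ignore"):
                pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
            pos_freq = np.nan_to_num(pos_freq, nan=0.25)
            pi = np.array(
                [
                    pos_freq[0, nt_index[c[0]]]
                    * pos_freq[1, nt_index[c[1]]]
                    * pos_freq[2, nt_index[c[2]]]
                    for c in code.codons
                ]
            )
            return cls(mode, _floor_and_normalize(pi))
        raise ValueError(f"unknown frequency mode {mode!r}")


def _floor_and_normalize(v: np.ndarray) -> np.ndarray:
    v = np.maximum(np.asarray(v, dtype=float), _MIN_PI)
    return v / v.sum()


@dataclass(frozen=True)
class SiteClass:
    """One mixture component: a proportion and, per branch class, an omega."""

    proportion: float
    omega: Mapping[int, float]  # branch_class -> omega

    def omega_for(self, branch_class: int) -> float:
        if branch_class in self.omega:
            return self.omega[branch_class]
        return self.omega[0]


@dataclass(frozen=True)
class CodonModelSpec:
    """A fully parameterized codon model (family + numbers)."""

    family: str
    kappa: float
    site_classes: tuple[SiteClass, ...]
    frequencies: CodonFrequencies
    genetic_code: int = 1

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        props = [sc.proportion for sc in self.site_classes]
        if any(p < -1e-12 for p in props) or abs(sum(props) - 1.0) > 1e-8:
            raise ValueError("site-class proportions must be >=0 and sum to 1")
        for sc in self.site_classes:
            if any(w < 0 for w in sc.omega.values()):
                raise ValueError("omega must be >= 0")

    @classmethod
    def m0(cls, kappa: float, omega: float, frequencies: CodonFrequencies,
           genetic_code: int = 1) -> "CodonModelSpec":
        return cls("M0", kappa, (SiteClass(1.0, {0: omega}),), frequencies,
                   genetic_code)

    @classmethod
    def branch2(cls, kappa: float, omega_bg: float, omega_fg: float,
                frequencies: CodonFrequencies, genetic_code: int = 1
                ) -> "CodonModelSpec":
        return cls("branch2", kappa,
                   (SiteClass(1.0, {0: omega_bg, 1: omega_fg}),),
                   frequencies, genetic_code)

    def branch_classes(self) -> set[int]:
        out: set[int] = set()
        for sc in self.site_classes:
            out |= set(sc.omega)
        return out


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    family: str
    lnL: float
    params: dict
    n_free_params: int
    n_model_params: int
    converged: bool
    spec: CodonModelSpec
    tree: GeneTree
    starts: list[dict] = field(default_factory=list)

    def __repr__(self):
        return (f"FitResult(family={self.family!r}, lnL={self.lnL:.4f}, "
                f"params={ {k: round(v, 4) if isinstance(v, float) else v for k, v in self.params.items()} })")


@dataclass(frozen=True)
class LRTResult:
    stat: float
    df: int
    p_value: float
    null: str
    alt: str


# ---------------------------------------------------------------------------
# Rate matrix and eigendecomposition
# ---------------------------------------------------------------------------


def build_gy94_matrix(
    pi: np.ndarray | CodonFrequencies,
    kappa: float,
    omega: float,
    genetic_code: int = 1,
    scale: bool = True,
) -> np.ndarray:
    """GY94 generator over sense codons.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for single-
    nucleotide changes, 0 otherwise; rows sum to 0. With ``scale`` the
    matrix is divided by its expected rate so a branch length of 1 equals
    one expected substitution per codon (under *this* omega; mixture models
    rescale jointly — see :func:`_class_matrices`).
    """
    if isinstance(pi, CodonFrequencies):
        pi = pi.pi
    pi = np.asarray(pi, dtype=float)
    code = get_code(genetic_code)
    if pi.shape != (code.n,) or np.any(pi < 0) or not math.isclose(
            pi.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("invalid frequency vector")
    ii, jj, ts, syn = code.neighbor_pairs
    rates = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q = np.zeros((code.n, code.n))
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = expected_rate(Q, pi)
        if mu > 0:
            Q = Q / mu
    return Q


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    return float(-(pi * np.diag(Q)).sum())


def _eigen(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a pi-reversible generator: returns (w, A, B)
    with exp(Qt) = A @ diag(exp(w t)) @ B."""
    d = np.sqrt(np.maximum(pi, _MIN_PI))
    S = Q * d[:, None] / d[None, :]
    S = (S + S.T) / 2.0
    w, U = np.linalg.eigh(S)
    A = U / d[:, None]
    B = U.T * d[None, :]
    return w, A, B


def _p_matrix(eig, t: float) -> np.ndarray:
    w, A, B = eig
    P = (A * np.exp(w * t)) @ B
    np.clip(P, 0.0, None, out=P)
    return P


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Q t) for a pi-reversible generator (rows sum to 1)."""
    return _p_matrix(_eigen(Q, pi), t)


def _class_matrices(spec: CodonModelSpec, scale: bool = True
                    ) -> dict[int, list[np.ndarray]]:
    """Per branch class, the list of (scaled) site-class generators.

    Scaling divides every site class of a branch class by that branch
    class's mixture-average rate, so branch lengths are expected
    substitutions per codon under the site-class mixture.
    """
    pi = spec.frequencies.pi
    out: dict[int, list[np.ndarray]] = {}
    cache: dict[float, np.ndarray] = {}
    for bc in sorted(spec.branch_classes()) or [0]:
        mats = []
        for sc in spec.site_classes:
            om = sc.omega_for(bc)
            if om not in cache:
                cache[om] = build_gy94_matrix(pi, spec.kappa, om,
                                              spec.genetic_code, scale=False)
            mats.append(cache[om])
        if scale:
            mu = sum(
                sc.proportion * expected_rate(m, pi)
                for sc, m in zip(spec.site_classes, mats)
            )
            if mu > 0:
                mats = [m / mu for m in mats]
        out[bc] = mats
    return out


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------


class _WithFallback(dict):
    """Branch-class -> value map falling back to class 0 (a model that does
    not distinguish a class treats those branches as background)."""

    def __init__(self, mapping):
        super().__init__(mapping)

    def __missing__(self, key):
        return self[0]


class LikelihoodEngine:
    """Site-pattern-compressed pruning over one (alignment, tree) pair.

    The tree's node order, edge classes and leaf partial-likelihood rows are
    frozen at construction; likelihood evaluations take rate matrices and a
    branch-length vector, so optimizers can vary either cheaply.
    """

    def __init__(self, codon_aln: CodonAlignment, tree: GeneTree,
                 genetic_code: int | None = None):
        self.code = get_code(genetic_code or codon_aln.genetic_code)
        self.tree = tree
        missing = [n for n in tree.leaf_names if n not in codon_aln]
        if missing:
            raise ValueError(f"tree leaves without sequence: {missing}")
        self.nodes: list[TreeNode] = tree.postorder()
        self.node_index = {id(n): i for i, n in enumerate(self.nodes)}
        self.edge_class = np.array(
            [n.branch_class for n in self.nodes], dtype=int
        )
        self.lengths0 = np.array(
            [n.length if n.length is not None else 0.1 for n in self.nodes]
        )
        leaf_ids = [i for i, n in enumerate(self.nodes) if n.is_leaf]

        # pattern compression
        codon_rows = {n.name: codon_aln.codons_of(n.name)
                      for n in self.nodes if n.is_leaf}
        n_sites = codon_aln.n_codons
        cols = [
            tuple(codon_rows[self.nodes[i].name][s] for i in leaf_ids)
            for s in range(n_sites)
        ]
        uniq: dict[tuple, int] = {}
        weights: list[int] = []
        self.site_to_pattern = np.empty(n_sites, dtype=int)
        for s, col in enumerate(cols):
            if col not in uniq:
                uniq[col] = len(uniq)
                weights.append(0)
            self.site_to_pattern[s] = uniq[col]
            weights[uniq[col]] += 1
        self.weights = np.array(weights, dtype=float)
        self.n_patterns = len(uniq)

        self.leaf_partials: dict[int, np.ndarray] = {}
        for k, i in enumerate(leaf_ids):
            M = np.empty((self.n_patterns, self.code.n))
            for col, p in uniq.items():
                M[p] = codon_compatibility(col[k], self.code)
            self.leaf_partials[i] = M

    # -- generic mixture likelihood ----------------------------------------

    def loglik(
        self,
        class_eigs: Sequence[Mapping[int, tuple]],
        proportions: Sequence[float],
        pi: np.ndarray,
        lengths: np.ndarray,
        per_pattern: bool = False,
    ):
        """lnL for a site-class mixture.

        ``class_eigs[k][bc]`` is the eigendecomposition of site class k's
        generator on branch class bc; ``proportions[k]`` its weight.
        """
        mix = np.zeros(self.n_patterns)
        for k, eig_by_class in enumerate(class_eigs):
            eig_by_class = _WithFallback(eig_by_class)
            root_partial = self._class_partial(eig_by_class, lengths)
            mix += proportions[k] * (root_partial * pi).sum(axis=1)
        logs = np.log(np.maximum(mix, 1e-300))
        if per_pattern:
            return float(self.weights @ logs), mix
        return float(self.weights @ logs)

    def _class_partial(self, eig_by_class: Mapping[int, tuple],
                       lengths: np.ndarray) -> np.ndarray:
        partials: dict[int, np.ndarray] = {}
        for i, node in enumerate(self.nodes):
            if node.is_leaf:
                partials[i] = self.leaf_partials[i]
                continue
            M = np.ones((self.n_patterns, self.code.n))
            for child in node.children:
                ci = self.node_index[id(child)]
                P = _p_matrix(eig_by_class[self.edge_class[ci]], lengths[ci])
                M *= partials.pop(ci) @ P.T
            partials[i] = M
        return partials[len(self.nodes) - 1]

    def loglik_spec(self, spec: CodonModelSpec,
                    lengths: np.ndarray | None = None) -> float:
        mats = _class_matrices(spec)
        pi = spec.frequencies.pi
        eigs = [
            {bc: _eigen(mats[bc][k], pi) for bc in mats}
            for k in range(len(spec.site_classes))
        ]
        props = [sc.proportion for sc in spec.site_classes]
        t = self.lengths0 if lengths is None else lengths
        return self.loglik(eigs, props, pi, t)

    # -- branch-length optimization for single-class models ----------------

    def optimize_branch_lengths(self, eig, pi: np.ndarray,
                                lengths: np.ndarray, sweeps: int = 2
                                ) -> tuple[np.ndarray, float]:
        """Per-edge Brent optimization using up/down partials (single site
        class, single branch class). Returns (lengths, lnL)."""
        t = lengths.copy()
        lnL = -np.inf
        for _ in range(sweeps):
            down: dict[int, np.ndarray] = {}
            Ms: dict[int, np.ndarray] = {}
            for i, node in enumerate(self.nodes):
                if node.is_leaf:
                    down[i] = self.leaf_partials[i]
                else:
                    M = np.ones((self.n_patterns, self.code.n))
                    for child in node.children:
                        ci = self.node_index[id(child)]
                        P = _p_matrix(eig, t[ci])
                        Ms[ci] = down[ci] @ P.T
                        M *= Ms[ci]
                    down[i] = M
            up: dict[int, np.ndarray] = {}
            root_i = len(self.nodes) - 1
            order = list(range(root_i, -1, -1))  # preorder over node indices
            for i in order:
                node = self.nodes[i]
                if node.is_leaf:
                    continue
                parent_factor = (
                    np.tile(pi, (self.n_patterns, 1)) if i == root_i else up[i]
                )
                for child in node.children:
                    ci = self.node_index[id(child)]
                    sib = parent_factor.copy()
                    for other in node.children:
                        oi = self.node_index[id(other)]
                        if oi != ci:
                            sib *= Ms[oi]
                    # optimize edge ci: L(t) = sum_k X e^{w t} Y
                    w, A, B = eig
                    X = sib @ A
                    Y = down[ci] @ B.T

                    def neg(log_t):
                        e = np.exp(w * math.exp(log_t))
                        lik = np.maximum((X * e[None, :] * Y).sum(axis=1),
                                         1e-300)
                        return -(self.weights @ np.log(lik))

                    res = optimize.minimize_scalar(
                        neg, bounds=(math.log(_MIN_T), math.log(_MAX_T)),
                        method="bounded",
                        options={"xatol": 1e-7},
                    )
                    t[ci] = math.exp(res.x)
                    lnL = -res.fun
                    P = _p_matrix(eig, t[ci])
                    Ms[ci] = down[ci] @ P.T
                    if not node.is_leaf:
                        # parent-side factor for ci's own children
                        up[ci] = sib @ P
        return t, lnL

    def apply_lengths(self, lengths: np.ndarray) -> GeneTree:
        """Copy of the engine's tree carrying ``lengths`` on its edges."""
        tree = self.tree.copy()
        for i, node in enumerate(tree.postorder()):
            if node.parent is not None:
                node.length = float(lengths[i])
        return tree


def compute_tree_loglik(codon_aln: CodonAlignment, tree: GeneTree,
                        spec: CodonModelSpec) -> float:
    """Log-likelihood of an alignment on a tree under a codon model; branch
    lengths are read from the tree."""
    engine = LikelihoodEngine(codon_aln, tree, spec.genetic_code)
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValueError("tree must carry branch lengths")
    return engine.loglik_spec(spec)


# ---------------------------------------------------------------------------
# Parameter transforms
# ---------------------------------------------------------------------------


def _sig(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


class _Family:
    """Maps between an unconstrained parameter vector and a CodonModelSpec."""

    def __init__(self, family: str, freqs: CodonFrequencies,
                 branch_classes: Sequence[int], genetic_code: int):
        self.family = family
        self.freqs = freqs
        self.bcs = sorted(branch_classes)
        self.gc = genetic_code

    @property
    def n_params(self) -> int:
        return {
            "M0": 2, "branch2": 3, "M1a": 3, "M2a_rel": 5,
            "CmC": 4 + len(self.bcs), "branchsiteA": 5,
        }[self.family]

    def start_vector(self, omega: float, kappa: float) -> np.ndarray:
        lk = math.log(kappa)
        lo = math.log(max(omega, 1e-6))
        if self.family == "M0":
            return np.array([lk, lo])
        if self.family == "branch2":
            return np.array([lk, lo, lo])
        if self.family == "M1a":
            return np.array([lk, _logit(0.7), _logit(min(omega, 0.9))])
        if self.family == "M2a_rel":
            return np.array([lk, _logit(0.6), _logit(0.5),
                             _logit(min(omega, 0.9)), lo])
        if self.family == "CmC":
            return np.array([lk, _logit(0.6), _logit(0.5), _logit(0.2)]
                            + [lo] * len(self.bcs))
        if self.family == "branchsiteA":
            return np.array([lk, _logit(0.7), _logit(0.5), _logit(0.2),
                             math.log(max(omega - 1.0, 1e-3))])
        raise AssertionError

    def to_spec(self, x: np.ndarray) -> CodonModelSpec:
        f = self.family
        kappa = math.exp(min(x[0], 8.0))
        if f == "M0":
            scs = (SiteClass(1.0, {0: math.exp(min(x[1], 8.0))}),)
        elif f == "branch2":
            scs = (SiteClass(1.0, {0: math.exp(min(x[1], 8.0)),
                                   1: math.exp(min(x[2], 8.0))}),)
        elif f == "M1a":
            p0 = _sig(x[1])
            w0 = _sig(x[2])
            scs = (SiteClass(p0, {0: w0}), SiteClass(1 - p0, {0: 1.0}))
        elif f == "M2a_rel":
            p0 = _sig(x[1])
            p1 = (1 - p0) * _sig(x[2])
            w0 = _sig(x[3])
            w2 = math.exp(min(x[4], 8.0))
            scs = (SiteClass(p0, {0: w0}), SiteClass(p1, {0: 1.0}),
                   SiteClass(1 - p0 - p1, {0: w2}))
        elif f == "CmC":
            p0 = _sig(x[1])
            p1 = (1 - p0) * _sig(x[2])
            w0 = _sig(x[3])
            w2 = {bc: math.exp(min(x[4 + i], 8.0))
                  for i, bc in enumerate(self.bcs)}
            scs = (
                SiteClass(p0, {bc: w0 for bc in self.bcs}),
                SiteClass(p1, {bc: 1.0 for bc in self.bcs}),
                SiteClass(1 - p0 - p1, w2),
            )
        elif f == "branchsiteA":
            p0 = _sig(x[1])
            p1 = (1 - p0) * _sig(x[2])
            w0 = _sig(x[3])
            w2 = 1.0 + math.exp(min(x[4], 8.0))
            p2 = 1 - p0 - p1
            denom = max(p0 + p1, 1e-12)
            p2a = p2 * p0 / denom
            p2b = p2 * p1 / denom
            scs = (
                SiteClass(p0, {0: w0, 1: w0}),
                SiteClass(p1, {0: 1.0, 1: 1.0}),
                SiteClass(p2a, {0: w0, 1: w2}),
                SiteClass(p2b, {0: 1.0, 1: w2}),
            )
        else:
            raise AssertionError
        return CodonModelSpec(f, kappa, scs, self.freqs, self.gc)

    def describe(self, spec: CodonModelSpec) -> dict:
        out: dict = {"kappa": spec.kappa}
        f = self.family
        scs = spec.site_classes
        if f == "M0":
            out["omega"] = scs[0].omega[0]
        elif f == "branch2":
            out["omega_background"] = scs[0].omega[0]
            out["omega_foreground"] = scs[0].omega[1]
        elif f == "M1a":
            out.update(p0=scs[0].proportion, omega0=scs[0].omega[0])
        elif f == "M2a_rel":
            out.update(p0=scs[0].proportion, p1=scs[1].proportion,
                       p2=scs[2].proportion, omega0=scs[0].omega[0],
                       omega2=scs[2].omega[0])
        elif f == "CmC":
            out.update(p0=scs[0].proportion, p1=scs[1].proportion,
                       p2=scs[2].proportion, omega0=scs[0].omega_for(0))
            for bc in self.bcs:
                out[f"omega2_clade{bc}"] = scs[2].omega_for(bc)
        elif f == "branchsiteA":
            out.update(p0=scs[0].proportion, p1=scs[1].proportion,
                       p2a=scs[2].proportion, p2b=scs[3].proportion,
                       omega0=scs[0].omega[0],
                       omega2_foreground=scs[2].omega_for(1))
        return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit_m0_one_start(engine: LikelihoodEngine, freqs: CodonFrequencies,
                      genetic_code: int, omega0: float, kappa0: float,
                      t0: np.ndarray, estimate_bl: bool, tol: float):
    """Alternate (kappa, omega) quasi-Newton steps with per-edge branch
    sweeps until lnL stabilizes."""
    pi = freqs.pi
    x = np.array([math.log(kappa0), math.log(max(omega0, 1e-6))])
    t = t0.copy()

    def neg_rates(xv, tv):
        kappa = math.exp(min(xv[0], 8.0))
        omega = math.exp(min(xv[1], 8.0))
        Q = build_gy94_matrix(pi, kappa, omega, genetic_code)
        eig = _eigen(Q, pi)
        return -engine.loglik([{0: eig}], [1.0], pi, tv)

    lnL_prev = -np.inf
    lnL = -neg_rates(x, t)
    for _ in range(30):
        res = optimize.minimize(neg_rates, x, args=(t,), method="L-BFGS-B",
                                options={"maxiter": 60, "ftol": 1e-12})
        x = res.x
        if estimate_bl:
            kappa = math.exp(min(x[0], 8.0))
            omega = math.exp(min(x[1], 8.0))
            Q = build_gy94_matrix(pi, kappa, omega, genetic_code)
            eig = _eigen(Q, pi)
            t, lnL = engine.optimize_branch_lengths(eig, pi, t, sweeps=1)
        else:
            lnL = -res.fun
        if abs(lnL - lnL_prev) < tol:
            break
        lnL_prev = lnL
    kappa = math.exp(min(x[0], 8.0))
    omega = math.exp(min(x[1], 8.0))
    return lnL, kappa, omega, t


def fit_codon_model(
    codon_aln: CodonAlignment,
    tree: GeneTree,
    family: str,
    omega_starts: Sequence[float] | None = None,
    frequencies: str | CodonFrequencies = "F3x4",
    genetic_code: int | None = None,
    estimate_branch_lengths: bool | None = None,
    kappa_start: float = 2.0,
    tol: float = 1e-6,
) -> FitResult:
    """Maximum-likelihood fit of one model family.

    Branch lengths: under M0 they are co-estimated by default; the richer
    families keep the tree's lengths fixed (the usual workflow fits M0
    first and reuses its branch lengths — see :func:`fit_model_series`).
    Every ``omega_starts`` value launches an independent optimization; the
    best fit is returned with the per-start record in ``FitResult.starts``.
    """
    family = _canonical_family(family)
    gc = genetic_code or codon_aln.genetic_code
    if isinstance(frequencies, str):
        frequencies = CodonFrequencies.from_alignment(codon_aln, frequencies)
    engine = LikelihoodEngine(codon_aln, tree, gc)
    tree_classes = tree.branch_classes() | {0}
    if family in ("branch2", "branchsiteA") and 1 not in tree_classes:
        raise ValueError(f"{family} requires a foreground branch (class 1)")
    if family == "CmC" and len(tree_classes) < 2:
        raise ValueError("CmC requires at least two clade partitions")
    if estimate_branch_lengths is None:
        estimate_branch_lengths = family == "M0"
    starts = tuple(omega_starts) if omega_starts else DEFAULT_OMEGA_STARTS[family]

    start_log: list[dict] = []
    best: dict | None = None

    if family == "M0":
        t = engine.lengths0.copy()
        for om in starts:
            lnL, kappa, omega, t_fit = _fit_m0_one_start(
                engine, frequencies, gc, om, kappa_start, t,
                estimate_branch_lengths, tol,
            )
            rec = {"omega_start": om, "lnL": lnL, "kappa": kappa,
                   "omega": omega}
            start_log.append(rec)
            if best is None or lnL > best["lnL"]:
                best = {**rec, "lengths": t_fit}
            t = t_fit  # warm start the next run
        spec = CodonModelSpec.m0(best["kappa"], best["omega"], frequencies, gc)
        fitted_tree = engine.apply_lengths(best["lengths"])
        n_free = 2 + (len(engine.nodes) - 1 if estimate_branch_lengths else 0)
        return FitResult(
            family="M0", lnL=best["lnL"],
            params={"kappa": best["kappa"], "omega": best["omega"]},
            n_free_params=n_free, n_model_params=2, converged=True, spec=spec,
            tree=fitted_tree, starts=start_log,
        )

    fam = _Family(family, frequencies, sorted(tree_classes), gc)
    pi = frequencies.pi
    n_extra = len(engine.nodes) - 1 if estimate_branch_lengths else 0

    def unpack(xv):
        spec = fam.to_spec(xv[: fam.n_params])
        if estimate_branch_lengths:
            t = np.exp(np.clip(xv[fam.n_params :], math.log(_MIN_T),
                               math.log(_MAX_T)))
        else:
            t = engine.lengths0
        return spec, t

    def neg(xv):
        spec, t = unpack(xv)
        mats = _class_matrices(spec)
        eig_cache: dict[int, dict[int, tuple]] = {}
        eigs = []
        for k in range(len(spec.site_classes)):
            eigs.append({bc: _eigen(mats[bc][k], pi) for bc in mats})
        props = [sc.proportion for sc in spec.site_classes]
        return -engine.loglik(eigs, props, pi, t)

    for om in starts:
        x0 = fam.start_vector(om, kappa_start)
        if estimate_branch_lengths:
            x0 = np.concatenate([
                x0, np.log(np.maximum(engine.lengths0, _MIN_T))
            ])
        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12})
        spec, _t = unpack(res.x)
        rec = {"omega_start": om, "lnL": -res.fun,
               "converged": bool(res.success), **fam.describe(spec)}
        start_log.append(rec)
        if best is None or rec["lnL"] > best["lnL"]:
            best = {**rec, "x": res.x}

    spec, t = unpack(best["x"])
    fitted_tree = engine.apply_lengths(t)
    params = fam.describe(spec)
    return FitResult(
        family=family, lnL=best["lnL"], params=params,
        n_free_params=fam.n_params + n_extra, n_model_params=fam.n_params,
        converged=bool(best.get("converged", True)), spec=spec,
        tree=fitted_tree, starts=start_log,
    )


def _canonical_family(name: str) -> str:
    aliases = {
        "m0": "M0", "one-ratio": "M0", "two-ratio": "branch2",
        "branch2": "branch2", "m1a": "M1a",
        "m2a_rel": "M2a_rel", "m2a_ref": "M2a_rel",
        "cmc": "CmC", "clademodelc": "CmC", "clade-model-c": "CmC",
        "branchsitea": "branchsiteA", "branch-site-a": "branchsiteA",
        "modela": "branchsiteA",
    }
    key = name.replace("_", "_").lower().replace(" ", "")
    if name in MODEL_FAMILIES:
        return name
    if key in aliases:
        return aliases[key]
    raise ValueError(f"unknown model family {name!r}")


def fit_model_series(
    codon_aln: CodonAlignment,
    tree: GeneTree,
    families: Sequence[str],
    **kwargs,
) -> dict[str, FitResult]:
    """Fit several families, sharing M0-estimated branch lengths.

    M0 is always fitted first (added if absent); its optimized branch
    lengths are written into the tree used by every subsequent family.
    """
    families = [_canonical_family(f) for f in families]
    if "M0" not in families:
        families = ["M0"] + families
    out: dict[str, FitResult] = {}
    m0 = fit_codon_model(codon_aln, tree, "M0", **kwargs)
    out["M0"] = m0
    shared_tree = m0.tree
    for f in families:
        if f == "M0":
            continue
        out[f] = fit_codon_model(codon_aln, shared_tree, f, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Tests and corrections
# ---------------------------------------------------------------------------

#: nested null -> alternative pairs of the model zoo
NESTED_PAIRS = {
    "branch2": "M0",
    "CmC": "M2a_rel",
    "branchsiteA": "M1a",
}


def likelihood_ratio_test(null_fit: FitResult, alt_fit: FitResult,
                          df: int | None = None,
                          tolerance: float = 1e-6) -> LRTResult:
    """LRT of a nested model pair: stat = 2(lnL_alt - lnL_null), chi-square
    upper tail. ``df`` defaults to the free-parameter difference; an
    explicit override is accepted (reported degrees of freedom sometimes
    differ from the parameter count in published tables)."""
    if NESTED_PAIRS.get(alt_fit.family) not in (None, null_fit.family):
        raise ValueError(
            f"{alt_fit.family} is not nested above {null_fit.family}"
        )
    raw = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if raw < -tolerance * max(1.0, abs(null_fit.lnL)) - 1e-6:
        raise ValueError(
            f"alternative lnL {alt_fit.lnL:.6f} below null {null_fit.lnL:.6f}"
            " beyond tolerance: optimization failure"
        )
    stat = max(raw, 0.0)
    if df is None:
        # branch lengths are shared between the members of a nested pair
        # (the M0-first workflow), so df counts model parameters only
        df = alt_fit.n_model_params - null_fit.n_model_params
    if df < 1:
        raise ValueError("df must be >= 1")
    p = float(stats.chi2.sf(stat, df))
    return LRTResult(stat=stat, df=df, p_value=p,
                     null=null_fit.family, alt=alt_fit.family)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
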