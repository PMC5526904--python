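"""Type-I functional divergence between two paralog clusters.

After gene duplication, a site may keep its substitution rate in one
duplicate cluster but shift it in the other — type-I functional divergence
(altered functional constraint). The model here follows the classic
two-state site mixture: a fraction theta of sites draw *independent*
evolutionary rates in the two clusters, while the remaining 1 - theta share
one rate; rates are gamma distributed. Observable per-site data are the
minimum substitution counts on each cluster's subtree (Fitch parsimony; an
ML expected-count variant is exposed as an option), which under a gamma
rate follow a negative-binomial law — correlated across clusters for shared
sites, independent for divergent ones.

Estimation: cluster rate scales d_j are set to the mean counts; theta and
the gamma shape alpha are then estimated jointly by maximum likelihood over
the two-component mixture (method-of-moments shapes seed the optimizer, and
the theta = 0 null re-profiles alpha so the LRT keeps one degree of freedom
for theta). Parsimony counts saturate on deep subtrees — an unobserved
multiple hit inflates the apparent rate correlation between clusters and
biases theta down — so the default count estimator applies the per-edge
saturation correction -E*log(1 - c/E) (E = subtree edges); raw parsimony
counts remain available. Per-site posterior probabilities of the divergent
state and a bootstrap (column-resampling) standard error complete the fit.

Site selection mirrors the stepwise cutoff procedure: sites are removed in
descending posterior order, theta refitted each time, until the divergence
test loses significance; the highest posterior among the surviving sites is
the cutoff, and the removed sites are the predicted divergent sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .core_io import Alignment, GeneTree

__all__ = [
    "SiteRateProfile",
    "DivergenceResult",
    "Type1Divergence",
    "fitch_counts",
    "estimate_type1_divergence",
    "select_divergent_sites",
]

_MISSING = frozenset("-X?*.")


@dataclass(frozen=True)
class SiteRateProfile:
    """Per-column substitution counts within each of the two clusters."""

    counts_a: np.ndarray
    counts_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.counts_a, dtype=float)
        b = np.asarray(self.counts_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("count vectors must be 1-D and equal length")
        if np.any(a < 0) or np.any(b < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts_a", a)
        object.__setattr__(self, "counts_b", b)

    @property
    def n_columns(self) -> int:
        return self.counts_a.size


@dataclass
class DivergenceResult:
    theta: float
    se_theta: float | None
    lrt_stat: float
    p_value: float
    site_posteriors: np.ndarray
    cutoff: float | None = None
    selected_sites: tuple[int, ...] = ()
    alpha: tuple[float, float] = (1.0, 1.0)
    scale: tuple[float, float] = (0.0, 0.0)


def fitch_counts(aln: Alignment, tree: GeneTree) -> np.ndarray:
    """Minimum substitution count per column on a tree (Fitch parsimony).

    Gaps and unknown residues are wildcards (compatible with any state) and
    never force a change.
    """
    leaves = tree.leaf_names
    missing = [l for l in leaves if l not in aln]
    if missing:
        raise KeyError(f"tree leaves absent from alignment: {missing}")
    seqs = {l: aln[l].seq for l in leaves}
    n_cols = len(aln)
    counts = np.zeros(n_cols, dtype=float)
    postorder = tree.postorder()
    index = {id(n): i for i, n in enumerate(postorder)}
    children = [
        [index[id(c)] for c in n.children] for n in postorder
    ]
    for col in range(n_cols):
        sets: list[frozenset] = [frozenset()] * len(postorder)
        changes = 0
        for i, node in enumerate(postorder):
            if node.is_leaf:
                ch = seqs[node.name][col].upper()
                sets[i] = frozenset() if ch in _MISSING else frozenset(ch)
                continue
            cur: frozenset | None = None
            for j in children[i]:
                s = sets[j]
                if not s:
                    continue  # missing data constrains nothing
                if cur is None:
                    cur = s
                    continue
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    changes += 1
            sets[i] = cur if cur is not None else frozenset()
        counts[col] = changes
    return counts


def _nb_logpmf(x: np.ndarray, d: float, alpha: float) -> np.ndarray:
    """log P(X = x) for a Poisson(rate * d) count with rate ~ Gamma(alpha,
    alpha) (mean 1): a negative binomial."""
    return (
        special.gammaln(x + alpha)
        - special.gammaln(alpha)
        - special.gammaln(x + 1)
        + x * (math.log(d) - math.log(d + alpha))
        + alpha * (math.log(alpha) - math.log(d + alpha))
    )


def _joint_logpmf(x1: np.ndarray, x2: np.ndarray, d1: float, d2: float,
                  alpha: float) -> np.ndarray:
    """Joint log pmf of two Poisson counts sharing one gamma rate."""
    s = x1 + x2
    return (
        special.gammaln(s + alpha)
        - special.gammaln(alpha)
        - special.gammaln(x1 + 1)
        - special.gammaln(x2 + 1)
        + x1 * math.log(d1)
        + x2 * math.log(d2)
        + alpha * math.log(alpha)
        - (s + alpha) * math.log(d1 + d2 + alpha)
    )


def _moment_shape(x: np.ndarray) -> float:
    """Gamma shape by method of moments on an overdispersed count vector;
    large shape (rate homogeneity) capped at 100."""
    d = x.mean()
    v = x.var(ddof=1) if x.size > 1 else 0.0
    excess = v - d
    if excess <= d * d / 100.0:
        return 100.0
    return float(max(d * d / excess, 0.05))


class Type1Divergence:
    """Recomputable type-I divergence fit over a fixed count profile.

    Built from an alignment + tree + two disjoint leaf clusters (counts via
    Fitch parsimony on each cluster's subtree) or directly from a
    :class:`SiteRateProfile`. ``fit`` accepts a column subset so the
    stepwise site-selection procedure can refit after removals.
    """

    def __init__(self, profile: SiteRateProfile, n_bootstrap: int = 500,
                 seed: int = 0):
        self.profile = profile
        self.n_bootstrap = n_bootstrap
        self.seed = seed
        if profile.counts_a.max() == 0 and profile.counts_b.max() == 0:
            raise ValueError("zero-variation alignment: no substitutions")

    @classmethod
    def from_alignment(cls, aln: Alignment, tree: GeneTree,
                       cluster_a_ids, cluster_b_ids,
                       method: str = "expected", n_bootstrap: int = 500,
                       seed: int = 0) -> "Type1Divergence":
        a = list(cluster_a_ids)
        b = list(cluster_b_ids)
        if set(a) & set(b):
            raise ValueError("clusters must be disjoint")
        if len(a) < 4 or len(b) < 4:
            raise ValueError("each cluster needs >= 4 members")
        if method not in ("fitch", "expected"):
            raise ValueError(f"unknown count method {method!r}")
        sub_a = tree.extract_subtree(a)
        sub_b = tree.extract_subtree(b)
        counts_a = fitch_counts(aln, sub_a)
        counts_b = fitch_counts(aln, sub_b)
        if method == "expected":
            # with E edges, parsimony sees at most one change per edge;
            # invert the per-edge change probability to approximate the
            # true substitution number
            for counts, sub in ((counts_a, sub_a), (counts_b, sub_b)):
                n_edges = sum(
                    1 for nd in sub.postorder() if nd.parent is not None
                )
                frac = np.minimum(counts / n_edges, 0.9)
                counts[:] = -n_edges * np.log1p(-frac)
        return cls(SiteRateProfile(counts_a, counts_b),
                   n_bootstrap=n_bootstrap, seed=seed)

    # -- core fit ----------------------------------------------------------

    @staticmethod
    def _mixture_loglik_terms(x1, x2, d1, d2, alpha):
        log_joint = _joint_logpmf(x1, x2, d1, d2, alpha)
        log_indep = _nb_logpmf(x1, d1, alpha) + _nb_logpmf(x2, d2, alpha)
        return log_joint, log_indep

    @staticmethod
    def _profile_loglik(theta: float, log_joint, log_indep) -> float:
        # log((1-t) e^j + t e^i) computed stably
        m = np.maximum(log_joint, log_indep)
        val = np.log(
            np.maximum(
                (1 - theta) * np.exp(log_joint - m)
                + theta * np.exp(log_indep - m),
                1e-300,
            )
        ) + m
        return float(val.sum())

    @classmethod
    def _ml_fit(cls, x1, x2):
        """ML over (theta, alpha) with d fixed at the mean counts; returns
        (theta, alpha, lnl, lnl0) where lnl0 profiles alpha at theta=0."""
        d1 = max(x1.mean(), 1e-6)
        d2 = max(x2.mean(), 1e-6)
        a_mom = (_moment_shape(x1) + _moment_shape(x2)) / 2.0

        def neg(p):
            theta = 1.0 / (1.0 + math.exp(-p[0]))
            alpha = math.exp(min(p[1], 6.0))
            lj, li = cls._mixture_loglik_terms(x1, x2, d1, d2, alpha)
            return -cls._profile_loglik(theta, lj, li)

        def neg0(p):
            alpha = math.exp(min(p[0], 6.0))
            return -float(_joint_logpmf(x1, x2, d1, d2, alpha).sum())

        best = None
        for theta0 in (0.1, 0.5, 0.9):
            res = optimize.minimize(
                neg, [math.log(theta0 / (1 - theta0)), math.log(a_mom)],
                method="L-BFGS-B", options={"ftol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        res0 = optimize.minimize(neg0, [math.log(a_mom)], method="L-BFGS-B",
                                 options={"ftol": 1e-12})
        theta = 1.0 / (1.0 + math.exp(-best.x[0]))
        alpha = math.exp(min(best.x[1], 6.0))
        lnl = -best.fun
        lnl0 = -res0.fun
        return theta, alpha, lnl, lnl0, (d1, d2)

    def fit(self, columns: np.ndarray | None = None,
            bootstrap: bool = False) -> DivergenceResult:
        x1 = self.profile.counts_a
        x2 = self.profile.counts_b
        if columns is not None:
            x1 = x1[columns]
            x2 = x2[columns]
        theta, alpha, lnl, lnl0, scale = self._ml_fit(x1, x2)
        stat = max(2.0 * (lnl - lnl0), 0.0)
        p = float(stats.chi2.sf(stat, 1))
        if theta < 1e-6:
            theta = 0.0
        lj, li = self._mixture_loglik_terms(x1, x2, *scale, alpha)
        m = np.maximum(lj, li)
        num = theta * np.exp(li - m)
        den = num + (1 - theta) * np.exp(lj - m)
        post = num / np.maximum(den, 1e-300)

        se = None
        if bootstrap and self.n_bootstrap > 0:
            rng = np.random.default_rng(self.seed)
            thetas = np.empty(self.n_bootstrap)
            n = x1.size
            for b in range(self.n_bootstrap):
                idx = rng.integers(0, n, size=n)
                thetas[b] = self._ml_fit(x1[idx], x2[idx])[0]
            se = float(thetas.std(ddof=1))

        return DivergenceResult(
            theta=theta, se_theta=se, lrt_stat=stat, p_value=p,
            site_posteriors=post, alpha=(alpha, alpha), scale=scale,
        )


def estimate_type1_divergence(
    protein_aln: Alignment,
    tree: GeneTree,
    cluster_a_ids,
    cluster_b_ids,
    n_bootstrap: int = 500,
    method: str = "expected",
    seed: int = 0,
) -> DivergenceResult:
    """Fit the type-I divergence model between two paralog clusters.

    Returns theta with bootstrap SE, the LRT of theta = 0 (chi-square,
    1 df) and per-column posterior probabilities of the divergent state.
    The returned result carries its estimator so the stepwise site
    selection can refit (``result._estimator``).
    """
    est = Type1Divergence.from_alignment(
        protein_aln, tree, cluster_a_ids, cluster_b_ids,
        method=method, n_bootstrap=n_bootstrap, seed=seed,
    )
    result = est.fit(bootstrap=n_bootstrap > 0)
    result._estimator = est  # type: ignore[attr-defined]
    return result


def select_divergent_sites(
    estimator: Type1Divergence | DivergenceResult,
    alpha: float = 0.05,
) -> tuple[float | None, tuple[int, ...]]:
    """Stepwise posterior-cutoff selection of divergent sites.

    Columns are removed one at a time in descending order of the *initial*
    fit's posteriors (ties by column index), refitting theta on the
    remaining columns, until the divergence LRT p-value exceeds ``alpha``.
    The cutoff is the highest initial posterior among the remaining
    columns; the removed columns (all with posterior above the cutoff) are
    the selected sites. If the initial fit is already non-significant the
    selection is empty and the cutoff undefined.
    """
    if isinstance(estimator, DivergenceResult):
        est = getattr(estimator, "_estimator", None)
        if est is None:
            raise ValueError("result does not carry a recomputable estimator")
        initial = estimator
    else:
        est = estimator
        initial = est.fit()
    if initial.p_value > alpha:
        return None, ()
    post = initial.site_posteriors
    order = sorted(range(post.size), key=lambda i: (-post[i], i))
    n = post.size
    removed: list[int] = []
    mask = np.ones(n, dtype=bool)
    for nxt in order:
        if mask.sum() <= 2:
            break
        mask[nxt] = False
        removed.append(nxt)
        refit = est.fit(columns=np.nonzero(mask)[0])
        if refit.p_value > alpha:
            break
    remaining = np.nonzero(mask)[0]
    cutoff = float(post[remaining].max()) if remaining.size else 0.0
    # sites are those scoring strictly above the cutoff; a removed column
    # tying the highest survivor is, by that rule, not selected
    selected = tuple(i for i in sorted(removed) if post[i] > cutoff)
    return cutoff, selected
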