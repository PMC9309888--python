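"""Constrained 5-taxon branch-length optimization and the category contrast.

The tree shape is fixed: an unrooted 5-taxon topology
``((Pm,Pt),(Mars,YPF),focal)`` in which the two pedinophyte cherries are
enforced and the focal taxon (the green-plastid dinoflagellate) attaches
to the central node.  Branch lengths are optimized per protein alignment
by coordinate-wise Brent search under an amino-acid substitution model
(LG/WAG/Poisson exchangeabilities, optional +F frequencies, discrete-gamma
among-site rate variation), likelihoods computed by Felsenstein pruning
over compressed site patterns.

The per-protein statistic contrasts the focal terminal branch ``b_f``
against the summed length ``S`` of the remaining six branches: both the
ratio ``b_f / S`` (the headline "branch length-ratio") and the difference
``b_f - S`` are computed.  The photosynthetic vs non-photosynthetic
category contrast is a two-sided Wilcoxon rank-sum test on those values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, rankdata

from .aa_models import (
    AA_ORDER,
    LG_EXCHANGEABILITIES,
    LG_FREQUENCIES,
    WAG_EXCHANGEABILITIES,
    WAG_FREQUENCIES,
)

N_STATES = 20
MISSING = 20  # code for gap/ambiguous residues

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 10.0
ALPHA_BOUNDS = (0.02, 100.0)

BRANCH_NAMES = ("pm", "pt", "mars", "ypf", "focal", "pm_pt", "mars_ypf")

_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


# ------------------------------------------------------------ alignment

@dataclass
class ProteinAlignment:
    """Equal-length amino-acid rows over the 20-letter alphabet plus gap."""

    name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise ValueError("alignment needs >= 2 taxa")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels")
        if len({len(r) for r in self.rows}) != 1 or len(self.rows) != len(self.taxa):
            raise ValueError("rows must be equal-length, one per taxon")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def encoded(self) -> np.ndarray:
        """Integer codes (n_taxa, n_sites); gaps/ambiguity -> MISSING."""
        out = np.full((len(self.taxa), self.n_sites), MISSING, dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j, c in enumerate(row):
                out[i, j] = _AA_INDEX.get(c, MISSING)
        return out


# ------------------------------------------------------------ model

def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability gamma(alpha, 1/alpha) bins."""
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    cum = np.concatenate([[0.0], gammainc(alpha + 1, alpha * bounds), [1.0]])
    return k * np.diff(cum)


def _expand_lower_triangle(values) -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    it = iter(values)
    for j in range(N_STATES - 1):  # column-major lower triangle
        for i in range(j + 1, N_STATES):
            s[i, j] = s[j, i] = next(it)
    return s


class SubstitutionModel:
    """Reversible amino-acid model with discrete-gamma rate variation.

    ``Q[i, j] = s[i, j] * pi[j]`` off-diagonal, rows summing to zero,
    scaled so the mean substitution rate at equilibrium is 1.
    """

    def __init__(
        self,
        name: str,
        exchangeabilities: np.ndarray,
        frequencies: np.ndarray,
        gamma_shape: float | None = None,
        n_rate_categories: int = 4,
    ):
        s = np.asarray(exchangeabilities, dtype=float)
        if s.ndim == 1:
            s = _expand_lower_triangle(s)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        pi = np.asarray(frequencies, dtype=float)
        if pi.shape != (N_STATES,) or np.any(pi <= 0):
            raise ValueError("frequencies must be 20 positive values")
        pi = pi / pi.sum()

        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        q /= scale

        self.name = name
        self.exchangeabilities = s
        self.frequencies = pi
        self.rate_matrix = q
        self.gamma_shape = gamma_shape
        self.n_rate_categories = n_rate_categories if gamma_shape is not None else 1

        # eigendecomposition of the pi-symmetrized generator
        sqrt_pi = np.sqrt(pi)
        b = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        self._eigenvalues = w
        self._right = v / sqrt_pi[:, None]
        self._left = v.T * sqrt_pi[None, :]

    # -- constructors ------------------------------------------------
    @classmethod
    def lg(cls, frequencies=None, gamma_shape=None, n_rate_categories=4):
        return cls(
            "LG" + ("+F" if frequencies is not None else ""),
            np.array(LG_EXCHANGEABILITIES),
            LG_FREQUENCIES if frequencies is None else frequencies,
            gamma_shape,
            n_rate_categories,
        )

    @classmethod
    def wag(cls, frequencies=None, gamma_shape=None, n_rate_categories=4):
        return cls(
            "WAG" + ("+F" if frequencies is not None else ""),
            np.array(WAG_EXCHANGEABILITIES),
            WAG_FREQUENCIES if frequencies is None else frequencies,
            gamma_shape,
            n_rate_categories,
        )

    @classmethod
    def poisson(cls, gamma_shape=None, n_rate_categories=4):
        return cls(
            "Poisson",
            np.ones((N_STATES, N_STATES)) - np.eye(N_STATES),
            np.full(N_STATES, 1.0 / N_STATES),
            gamma_shape,
            n_rate_categories,
        )

    @classmethod
    def named(cls, name: str, **kwargs) -> "SubstitutionModel":
        name = name.lower()
        if name == "lg":
            return cls.lg(**kwargs)
        if name == "wag":
            return cls.wag(**kwargs)
        if name == "poisson":
            return cls.poisson(**kwargs)
        raise ValueError(f"unknown model {name!r}; use LG, WAG or Poisson")

    # -- machinery ---------------------------------------------------
    def with_shape(self, alpha: float) -> "SubstitutionModel":
        """Copy sharing the eigensystem but with a new gamma shape."""
        clone = object.__new__(SubstitutionModel)
        clone.__dict__.update(self.__dict__)
        clone.gamma_shape = alpha
        return clone

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None or self.n_rate_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    def transition_matrix(self, t: float, category_rate: float = 1.0) -> np.ndarray:
        """``P = expm(Q * rate * t)``; rows sum to 1; ``P(0)`` is identity."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        p = (self._right * np.exp(self._eigenvalues * (t * category_rate))) @ self._left
        np.clip(p, 0.0, None, out=p)
        return p


def transition_probabilities(
    model: SubstitutionModel, t: float, category_rate: float = 1.0
) -> np.ndarray:
    return model.transition_matrix(t, category_rate)


# ------------------------------------------------------------ tree

@dataclass
class Tree5:
    """The fixed unrooted 5-taxon tree ``((pm,pt),(mars,ypf),focal)``.

    ``taxa`` lists the tips in role order (pm, pt, mars, ypf, focal);
    ``branch_lengths`` holds the 7 branches in :data:`BRANCH_NAMES` order
    (5 terminal, then the two cherry-internal branches).
    """

    taxa: tuple[str, str, str, str, str]
    branch_lengths: np.ndarray = field(
        default_factory=lambda: np.full(7, 0.1)
    )

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(self.taxa) != 5 or len(set(self.taxa)) != 5:
            raise ValueError("need 5 distinct taxon labels")
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)
        if self.branch_lengths.shape != (7,):
            raise ValueError("need exactly 7 branch lengths")
        if np.any(self.branch_lengths < 0):
            raise ValueError("branch lengths must be >= 0")

    @property
    def focal_taxon(self) -> str:
        return self.taxa[4]

    @property
    def focal_branch_length(self) -> float:
        return float(self.branch_lengths[4])

    def to_newick(self) -> str:
        b = self.branch_lengths
        t = self.taxa
        return (
            f"(({t[0]}:{b[0]:.8f},{t[1]}:{b[1]:.8f}):{b[5]:.8f},"
            f"({t[2]}:{b[2]:.8f},{t[3]}:{b[3]:.8f}):{b[6]:.8f},"
            f"{t[4]}:{b[4]:.8f});"
        )


def read_tree5(source: str, focal_taxon: str) -> Tree5:
    """Ingest a Newick tree (string or path), checking the fixed topology.

    The tree must be the unrooted 5-taxon shape with two cherries not
    involving ``focal_taxon``.
    """
    import dendropy
    from pathlib import Path

    text = source
    p = Path(source)
    if p.exists():
        text = p.read_text()
    tree = dendropy.Tree.get(data=text, schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != 5:
        raise ValueError(f"expected 5 taxa, found {len(labels)}")
    if focal_taxon not in labels:
        raise ValueError(f"focal taxon {focal_taxon!r} not among {labels}")
    tree.encode_bipartitions()
    cherries = []
    for node in tree.preorder_internal_node_iter():
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if len(leaves) == 2:
            cherries.append((tuple(leaves), node.edge.length or 0.0))
    non_focal_cherries = [c for c in cherries if focal_taxon not in c[0]]
    if len(non_focal_cherries) != 2:
        raise ValueError(
            "tree does not match the fixed topology "
            "((pm,pt),(mars,ypf),focal): need two cherries excluding the "
            "focal taxon"
        )
    (pair1, len1), (pair2, len2) = non_focal_cherries
    edge_len = {
        lf.taxon.label: (lf.edge.length or 0.0) for lf in tree.leaf_node_iter()
    }
    taxa = (*pair1, *pair2, focal_taxon)
    lengths = [
        edge_len[pair1[0]],
        edge_len[pair1[1]],
        edge_len[pair2[0]],
        edge_len[pair2[1]],
        edge_len[focal_taxon],
        len1,
        len2,
    ]
    return Tree5(taxa, np.array(lengths))


# ------------------------------------------------------------ likelihood

class LikelihoodEngine:
    """Felsenstein pruning over the fixed topology, pattern-compressed.

    Rooted (for computation only) at the central trifurcation; the model is
    reversible, so the root placement does not affect the likelihood.
    """

    def __init__(self, aln: ProteinAlignment, tree_taxa, model: SubstitutionModel):
        missing = [t for t in tree_taxa if t not in aln.taxa]
        if missing:
            raise ValueError(
                f"alignment {aln.name!r} lacks taxa: {missing}"
            )
        codes = aln.encoded()
        order = [aln.taxa.index(t) for t in tree_taxa]
        cols = codes[order].T  # (n_sites, 5)
        keep = ~np.all(cols == MISSING, axis=1)  # drop all-gap columns
        patterns, counts = np.unique(cols[keep], axis=0, return_counts=True)
        self.codes = patterns.T.copy()  # (5, n_pat)
        self.counts = counts.astype(float)
        self.n_patterns = patterns.shape[0]
        self.model = model
        self._paug_cache: dict = {}
        self._cond_cache: dict = {}

    # -- helpers -----------------------------------------------------
    def _paug(self, t: float, rate: float) -> np.ndarray:
        # memoized: during coordinate sweeps only one branch length moves
        cache = self._paug_cache
        key = (t, rate)
        if key not in cache:
            p = self.model.transition_matrix(t, rate)
            cache[key] = np.hstack([p, np.ones((N_STATES, 1))])
            if len(cache) > 256:
                cache.clear()
        return cache[key]

    def _tip_cond(self, paug: np.ndarray, tip: int, t: float, rate: float):
        # (n_pat, 20): row u = P[u, observed]; missing -> ones
        cache = self._cond_cache
        key = (tip, t, rate)
        if key not in cache:
            cache[key] = paug[:, self.codes[tip]].T.copy()
            if len(cache) > 256:
                cache.clear()
        return cache[key]

    def _category_parts(self, bl, rate):
        paugs = [self._paug(bl[k], rate) for k in range(7)]
        c = [self._tip_cond(paugs[i], i, bl[i], rate) for i in range(5)]
        a = c[0] * c[1]
        b = c[2] * c[3]
        ea = a @ paugs[5][:, :N_STATES].T
        eb = b @ paugs[6][:, :N_STATES].T
        return paugs, c, a, b, ea, eb

    def site_likelihoods(self, bl, model: SubstitutionModel | None = None):
        model = model or self.model
        saved, self.model = self.model, model
        try:
            rates = model.category_rates()
            pi = model.frequencies
            lik = np.zeros(self.n_patterns)
            for r in rates:
                _, c, _a, _b, ea, eb = self._category_parts(bl, r)
                lik += (ea * eb * c[4]) @ pi / len(rates)
        finally:
            self.model = saved
        return lik

    def log_likelihood(self, bl, model: SubstitutionModel | None = None) -> float:
        lik = self.site_likelihoods(bl, model)
        return float(self.counts @ np.log(np.maximum(lik, 1e-300)))

    def _tip_left_gather(self, tip: int) -> np.ndarray:
        # (n_pat, 20): row = left-eigenvector column for the observed state;
        # for missing data the column sums (P -> row sums of 1)
        cache = getattr(self, "_left_gather", None)
        if cache is None:
            cache = self._left_gather = {}
        if tip not in cache:
            left = self.model._left
            aug = np.hstack([left, left.sum(axis=1, keepdims=True)])
            cache[tip] = aug[:, self.codes[tip]].T.copy()
        return cache[tip]

    def branch_closure(self, bl, branch: int):
        """A cheap ``lnL(t)`` for one branch, all else held fixed.

        With ``P(t) = R diag(exp(w t)) L`` from the cached eigensystem, the
        site likelihood restricted to one branch collapses to
        ``A @ exp(w * t * rate)`` for a per-category matrix ``A`` computed
        once, so each Brent evaluation is a 20-vector matvec.
        """
        rates = self.model.category_rates()
        pi = self.model.frequencies
        right = self.model._right
        left = self.model._left
        w = self.model._eigenvalues
        amats = []  # per category: (A, rate)
        for r in rates:
            paugs, c, a, b, ea, eb = self._category_parts(bl, r)
            if branch == 4:
                f, g = pi * ea * eb, None
            elif branch in (0, 1):
                other = c[1] if branch == 0 else c[0]
                f = ((pi * eb * c[4]) @ paugs[5][:, :N_STATES]) * other
                g = None
            elif branch in (2, 3):
                other = c[3] if branch == 2 else c[2]
                f = ((pi * ea * c[4]) @ paugs[6][:, :N_STATES]) * other
                g = None
            elif branch == 5:
                f, g = pi * eb * c[4], a
            elif branch == 6:
                f, g = pi * ea * c[4], b
            else:
                raise ValueError(f"branch index {branch} out of range")
            if g is None:
                amat = (f @ right) * self._tip_left_gather(branch)
            else:
                amat = (f @ right) * (g @ left.T)
            amats.append((amat, r))
        k = len(rates)
        counts = self.counts

        def lnl(t: float) -> float:
            lik = amats[0][0] @ np.exp(w * (t * amats[0][1]))
            for amat, r in amats[1:]:
                lik += amat @ np.exp(w * (t * r))
            return float(counts @ np.log(np.maximum(lik / k, 1e-300)))

        return lnl


def log_likelihood(
    aln: ProteinAlignment, tree: Tree5, model: SubstitutionModel
) -> float:
    """Log-likelihood of the alignment on the fixed-topology tree."""
    engine = LikelihoodEngine(aln, tree.taxa, model)
    return engine.log_likelihood(tree.branch_lengths)


# ------------------------------------------------------------ optimization

def optimize_branch_lengths(
    aln: ProteinAlignment,
    model: SubstitutionModel,
    focal: str,
    sister_pairs: tuple[tuple[str, str], tuple[str, str]] | None = None,
    init: float = 0.1,
    max_sweeps: int = 100,
    tol: float = 1e-6,
    optimize_shape: bool | None = None,
) -> tuple[Tree5, dict]:
    """Coordinate-wise Brent optimization of the 7 branch lengths.

    Branches are swept in canonical order (terminals then internals), the
    gamma shape last in each sweep when the model has rate variation, until
    the largest branch-length change drops below ``tol`` or ``max_sweeps``
    is reached.  Lengths are clamped to [1e-8, 10].

    ``sister_pairs`` fixes which non-focal taxa form the two enforced
    cherries; by default the four non-focal taxa are paired in alignment
    row order.
    """
    if focal not in aln.taxa:
        raise ValueError(f"focal taxon {focal!r} not in alignment")
    if sister_pairs is None:
        others = [t for t in aln.taxa if t != focal]
        if len(others) != 4:
            raise ValueError("alignment must contain exactly 5 taxa")
        sister_pairs = ((others[0], others[1]), (others[2], others[3]))
    taxa = (*sister_pairs[0], *sister_pairs[1], focal)

    if optimize_shape is None:
        optimize_shape = model.gamma_shape is not None and model.n_rate_categories > 1

    engine = LikelihoodEngine(aln, taxa, model)
    bl = np.full(7, init, dtype=float)
    converged = False
    delta = np.inf
    for _sweep in range(max_sweeps):
        delta = 0.0
        for k in range(7):
            f = engine.branch_closure(bl, k)
            res = minimize_scalar(
                lambda t: -f(t),
                bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
                method="bounded",
                options={"xatol": 1e-7},
            )
            delta = max(delta, abs(res.x - bl[k]))
            bl[k] = res.x
        if optimize_shape:
            res = minimize_scalar(
                lambda a: -engine.log_likelihood(bl, engine.model.with_shape(a)),
                bounds=ALPHA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-3},
            )
            engine.model = engine.model.with_shape(res.x)
        if delta < tol:
            converged = True
            break
    info = {
        "converged": converged,
        "log_likelihood": engine.log_likelihood(bl),
        "gamma_shape": engine.model.gamma_shape,
        "max_delta": delta,
    }
    return Tree5(taxa, bl), info


def pairwise_distance(
    row1: str, row2: str, model: SubstitutionModel
) -> float:
    """ML distance between two sequences (2-taxon reduction)."""
    aln = ProteinAlignment("pair", ["a", "b"], [row1, row2])
    codes = aln.encoded()
    keep = (codes[0] != MISSING) & (codes[1] != MISSING)
    x, y = codes[0][keep], codes[1][keep]
    pi = model.frequencies

    def neg_lnl(t: float) -> float:
        p = model.transition_matrix(t)
        lik = pi[x] * p[x, y]
        return -float(np.sum(np.log(np.maximum(lik, 1e-300))))

    res = minimize_scalar(
        neg_lnl,
        bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ------------------------------------------------------------ contrast

def branch_length_contrast(tree: Tree5) -> tuple[float, float]:
    """Focal-branch statistic: ratio ``b_f / S`` and difference ``b_f - S``.

    ``S`` is the summed length of the six non-focal branches; the ratio is
    NaN when ``S`` is zero.
    """
    b_f = tree.focal_branch_length
    s = float(tree.branch_lengths.sum() - b_f)
    diff = b_f - s
    ratio = b_f / s if s > 0 else (0.0 if b_f == 0 else float("nan"))
    return ratio, diff


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns ``(W, p_two_sided)``.

    ``W`` is the rank sum of ``x`` (midranks for ties).  Exact mode
    enumerates all C(m+n, m) rank assignments; normal mode uses the
    tie-corrected variance with a continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    m, n = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w = float(ranks[:m].sum())
    has_ties = np.unique(combined).size < combined.size

    if mode == "auto":
        mode = "exact" if (m + n <= 12 and not has_ties) else "normal"

    if mode == "exact":
        sums = [sum(c) for c in itertools.combinations(ranks, m)]
        total = len(sums)
        eps = 1e-9
        p_le = sum(1 for s in sums if s <= w + eps) / total
        p_ge = sum(1 for s in sums if s >= w - eps) / total
        return w, min(1.0, 2.0 * min(p_le, p_ge))

    total_n = m + n
    mu = m * (total_n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = m * n / 12.0 * ((total_n + 1) - tie_term / (total_n * (total_n - 1)))
    if var <= 0:
        return w, 1.0
    sd = math.sqrt(var)
    if w > mu:
        z = (w - mu - 0.5) / sd
    elif w < mu:
        z = (w - mu + 0.5) / sd
    else:
        z = 0.0
    return w, min(1.0, 2.0 * norm.sf(abs(z)))


@dataclass
class ContrastResult:
    per_protein: list[tuple[str, str, float, float]]
    W: float
    p_two_sided: float
    medians: dict[str, float]
    n: dict[str, int]
    statistic: str
    direction: str


def run_category_contrast(
    alignments: list[ProteinAlignment],
    categories: dict[str, str],
    model: SubstitutionModel,
    focal: str,
    statistic: str = "ratio",
    sister_pairs=None,
    wilcoxon_mode: str = "auto",
) -> ContrastResult:
    """Optimize every alignment, then contrast the two protein categories.

    ``categories`` maps protein name to ``photosynthetic`` or
    ``non_photosynthetic``; the rank-sum test compares the per-protein
    statistic (ratio by default, difference optionally) between them.
    """
    if statistic not in ("ratio", "difference"):
        raise ValueError("statistic must be 'ratio' or 'difference'")
    per_protein = []
    for aln in alignments:
        if aln.name not in categories:
            raise ValueError(f"no category for protein {aln.name!r}")
        tree, _info = optimize_branch_lengths(
            aln, model, focal, sister_pairs=sister_pairs
        )
        ratio, diff = branch_length_contrast(tree)
        per_protein.append((aln.name, categories[aln.name], ratio, diff))

    col = 2 if statistic == "ratio" else 3
    photo = [p[col] for p in per_protein if p[1] == "photosynthetic"]
    nonphoto = [p[col] for p in per_protein if p[1] == "non_photosynthetic"]
    if not photo or not nonphoto:
        raise ValueError("both categories must be non-empty")
    w, p = wilcoxon_rank_sum(photo, nonphoto, mode=wilcoxon_mode)
    med_p = float(np.median(photo))
    med_np = float(np.median(nonphoto))
    if med_np > med_p:
        direction = "non_photosynthetic > photosynthetic"
    elif med_p > med_np:
        direction = "photosynthetic > non_photosynthetic"
    else:
        direction = "equal medians"
    return ContrastResult(
        per_protein=per_protein,
        W=w,
        p_two_sided=p,
        medians={"photosynthetic": med_p, "non_photosynthetic": med_np},
        n={"photosynthetic": len(photo), "non_photosynthetic": len(nonphoto)},
        statistic=statistic,
        direction=direction,
    )
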