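"""Repeated-measures network-based statistic (NBS).

The NBS tests whether connected sets of edges in a connectome relate to a
per-scan predictor more strongly than chance.  Per edge, an ordinary
least-squares GLM regresses the edge value across scans on the predictor
(here a per-scan partial factor score) with subject effects as nuisance.
Edges whose t-statistic exceeds a primary threshold form a graph; its
connected components are the candidate networks, sized by *extent* (edge
count).  Significance is family-wise-error controlled against a null
distribution of maximal component sizes built by Freedman-Lane permutation:
the nuisance-only model is fitted, its residuals are permuted — only within
each subject's scans, the exchangeability blocks of a repeated-measures
design — added back to the nuisance fit, and the full model is refitted.

Because subject indicators absorb every subject-constant signal, the test
is sensitive only to within-subject covariation between connectivity and
the predictor.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .connectivity import SCAN_KEYS, ConnectivityStack, edge_index, n_nodes_from_edges
from .exceptions import DesignError, InvalidParameterError

TAILS = ("positive", "negative", "two_sided")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class EdgeGLMStats:
    """Edge-wise GLM output: slope, t-statistic and residual df."""

    t: np.ndarray
    beta_hat: np.ndarray
    df: int


@dataclass
class NBSComponent:
    """One connected supra-threshold network."""

    edges: list  # canonical (i, j) node pairs, i < j
    nodes: list
    size_extent: int
    intensity: float = 0.0  # sum over edges of |t| - threshold
    p_fwe: float = None
    cohens_d: float = None
    mean_abs_t: float = None


@dataclass
class NBSRun:
    """Full record of one NBS contrast."""

    threshold: float
    tail: str
    n_perm: int
    seed: object
    null_max_sizes: np.ndarray
    components: list
    stats: EdgeGLMStats
    score_component: int = None
    component_stat: str = "extent"

    @property
    def best_p(self) -> float:
        return min((c.p_fwe for c in self.components), default=1.0)


@dataclass
class NBSFamilyResult:
    """A family of contrasts with FDR-adjusted network p-values."""

    runs: dict  # (score_component, tail) -> NBSRun
    family_table: pd.DataFrame
    threshold: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# GLM


def _group_codes(groups, n_default: int = None) -> tuple[np.ndarray, int]:
    if groups is None:
        # one exchangeability block spanning all scans: intercept-only
        # nuisance and unrestricted permutation
        return np.zeros(n_default, dtype=int), 1
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def _group_demean(y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Residualize against subject indicator columns (within-subject center)."""
    y = np.asarray(y, dtype=float)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if y.ndim == 1:
        means = np.bincount(codes, weights=y, minlength=n_groups) / counts
        return y - means[codes]
    sums = np.zeros((n_groups, y.shape[1]))
    np.add.at(sums, codes, y)
    return y - (sums / counts[:, None])[codes]


def _subject_mean_residualize(y, codes, n_groups, m_centered, mm):
    """Residualize against [intercept, per-edge subject-mean covariate].

    ``m_centered`` is the centered covariate matrix (scans x edges), ``mm``
    its per-edge sum of squares.  ``y`` may be (scans,) or (scans, edges).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        yc = y - y.mean()
        proj = (m_centered * yc[:, None]).sum(axis=0) / mm
        return yc[:, None] - m_centered * proj[None, :]
    yc = y - y.mean(axis=0)
    proj = (m_centered * yc).sum(axis=0) / mm
    return yc - m_centered * proj[None, :]


def _t_from_residuals(y_res: np.ndarray, x_res: np.ndarray, df: int):
    """Slope and t of the residualized regression, vectorized over edges."""
    if x_res.ndim == 1:
        sxx = float(x_res @ x_res)
        if sxx < _EPS:
            raise DesignError(
                "predictor is constant after removing nuisance "
                "(rank-deficient design)"
            )
        num = x_res @ y_res
        beta = num / sxx
        rss = np.einsum("ij,ij->j", y_res, y_res) - beta * num
    else:
        sxx = np.einsum("ij,ij->j", x_res, x_res)
        if np.any(sxx < _EPS):
            raise DesignError(
                "predictor is collinear with the nuisance for some edge "
                "(rank-deficient design)"
            )
        num = np.einsum("ij,ij->j", x_res, y_res)
        beta = num / sxx
        rss = np.einsum("ij,ij->j", y_res, y_res) - beta * num
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta * np.sqrt(df * sxx / np.where(rss > 0, rss, np.nan))
    t = np.where(np.isnan(t) & (np.abs(beta) < _EPS), 0.0, t)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return beta, t


class _GLMContext:
    """Precomputed residualization shared by observed fit and permutations."""

    def __init__(self, edge_matrix, predictor, groups, nuisance):
        y = np.asarray(edge_matrix, dtype=float)
        x = np.asarray(predictor, dtype=float).ravel()
        if y.ndim != 2:
            raise InvalidParameterError("edge matrix must be 2-D (scans x edges)")
        if x.size != y.shape[0]:
            raise DesignError(
                f"predictor has {x.size} rows but the stack has {y.shape[0]} scans"
            )
        self.codes, self.n_groups = _group_codes(groups, n_default=y.shape[0])
        sizes = np.bincount(self.codes)
        if np.all(sizes == 1) and self.n_groups > 1:
            warnings.warn(
                "every exchangeability block has a single scan; "
                "no within-subject permutation is possible",
                UserWarning,
                stacklevel=3,
            )
        self.nuisance = nuisance
        n = y.shape[0]
        if nuisance == "subject_indicators":
            self.df = n - self.n_groups - 1
            if self.df <= 0:
                raise DesignError("no residual degrees of freedom")
            self.y_res = _group_demean(y, self.codes, self.n_groups)
            self.x_res = _group_demean(x, self.codes, self.n_groups)
        elif nuisance == "subject_mean":
            # alternative reading: one covariate, the subject's mean value of
            # the edge, plus an intercept; nuisance differs per edge
            means = np.zeros((self.n_groups, y.shape[1]))
            np.add.at(means, self.codes, y)
            means /= np.bincount(self.codes).astype(float)[:, None]
            m = means[self.codes]
            mc = m - m.mean(axis=0)
            mm = np.einsum("ij,ij->j", mc, mc)
            if np.any(mm < _EPS):
                raise DesignError(
                    "subject-mean covariate is constant for some edge"
                )
            self._mc, self._mm = mc, mm
            self.df = n - 3
            if self.df <= 0:
                raise DesignError("no residual degrees of freedom")
            self.y_res = _subject_mean_residualize(y, self.codes, self.n_groups, mc, mm)
            self.x_res = _subject_mean_residualize(x, self.codes, self.n_groups, mc, mm)
        else:
            raise InvalidParameterError(
                f"unknown nuisance coding {nuisance!r}; "
                "use 'subject_indicators' or 'subject_mean'"
            )

    def reresidualize(self, y_perm):
        """Apply the nuisance projector to permuted residuals.

        With subject indicators the residuals are already within-subject
        centered and the permutation acts within subjects, so the projector
        is a no-op; per-edge nuisance needs an explicit pass.
        """
        if self.nuisance == "subject_indicators":
            return y_perm
        return _subject_mean_residualize(
            y_perm, self.codes, self.n_groups, self._mc, self._mm
        )


def fit_edge_glm(
    stack,
    predictor,
    groups=None,
    nuisance: str = "subject_indicators",
) -> EdgeGLMStats:
    """Edge-wise OLS of connectivity on the predictor with subject nuisance.

    Parameters
    ----------
    stack : ConnectivityStack or ndarray (scans x edges)
    predictor : per-scan values (e.g. partial factor scores)
    groups : per-scan subject labels; taken from the stack metadata when a
        :class:`ConnectivityStack` is given.
    nuisance : 'subject_indicators' (default; one indicator per subject,
        equivalent to within-subject centering) or 'subject_mean' (the
        subject's mean value of each edge as a single covariate).
    """
    if isinstance(stack, ConnectivityStack):
        if groups is None:
            groups = stack.meta["subject_id"].to_numpy()
        stack = stack.edge_matrix
    ctx = _GLMContext(stack, predictor, groups, nuisance)
    beta, t = _t_from_residuals(ctx.y_res, ctx.x_res, ctx.df)
    return EdgeGLMStats(t=t, beta_hat=beta, df=ctx.df)


# ---------------------------------------------------------------------------
# permutation machinery


def permute_within_blocks(groups, rng: np.random.Generator) -> np.ndarray:
    """One uniformly random permutation of scan indices within each block."""
    codes, n_groups = _group_codes(groups)
    perm = np.arange(codes.size)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def count_within_block_permutations(groups) -> int:
    """prod of n_b! over exchangeability blocks."""
    codes, n_groups = _group_codes(groups)
    sizes = np.bincount(codes, minlength=n_groups)
    return math.prod(math.factorial(int(s)) for s in sizes)


def enumerate_within_blocks(groups):
    """Yield every within-block permutation (index arrays).

    Intended for small designs; the count is prod(n_b!).
    """
    codes, n_groups = _group_codes(groups)
    block_idx = [np.flatnonzero(codes == g) for g in range(n_groups)]
    per_block = [
        [np.asarray(p) for p in itertools.permutations(idx)] for idx in block_idx
    ]
    for combo in itertools.product(*per_block):
        perm = np.arange(codes.size)
        for idx, tgt in zip(block_idx, combo):
            perm[idx] = tgt
        yield perm


def threshold_edges(stats: EdgeGLMStats, threshold: float, tail: str) -> np.ndarray:
    """Indices of supra-threshold edges for the given tail."""
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    return np.flatnonzero(_supra_mask(stats.t, threshold, tail))


def _supra_mask(t: np.ndarray, threshold: float, tail: str) -> np.ndarray:
    if tail == "positive":
        return t > threshold
    if tail == "negative":
        return t < -threshold
    if tail == "two_sided":
        return np.abs(t) > threshold
    raise InvalidParameterError(f"tail must be one of {TAILS}, got {tail!r}")


def find_components(edges, edge_values=None, threshold: float = 0.0) -> list:
    """Connected components of the supra-threshold graph.

    Parameters
    ----------
    edges : sequence of canonical (i, j) node pairs.
    edge_values : optional per-edge statistics (aligned with ``edges``);
        used to compute component intensity sum(|t| - threshold).

    Returns
    -------
    list of :class:`NBSComponent`, sorted by extent descending with smallest
    node index as the tie-break.
    """
    edges = [tuple(int(v) for v in e) for e in edges]
    g = nx.Graph()
    if edge_values is None:
        edge_values = np.zeros(len(edges))
    for (i, j), t in zip(edges, np.asarray(edge_values, dtype=float)):
        g.add_edge(i, j, t=t)
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comp_edges = sorted(tuple(sorted(e)) for e in sub.edges)
        tvals = np.array([g.edges[e]["t"] for e in comp_edges])
        comps.append(
            NBSComponent(
                edges=comp_edges,
                nodes=sorted(nodes),
                size_extent=len(comp_edges),
                intensity=float(np.sum(np.abs(tvals) - threshold)),
            )
        )
    comps.sort(key=lambda c: (-c.size_extent, c.nodes[0]))
    return comps


def _max_component_stat(ii, jj, weights=None, n_nodes=None):
    """Largest component statistic (extent, or weight sum) via union-find.

    Also reports whether the supra graph is a single component spanning all
    ``n_nodes`` (used for the uninformative-threshold warning).
    """
    m = len(ii)
    if m == 0:
        return 0.0, False
    parent = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    for a, b in zip(ii, jj):
        if a not in parent:
            parent[a] = a
        if b not in parent:
            parent[b] = b
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    if weights is None:
        weights = np.ones(m)
    sums = {}
    for a, w in zip(ii, weights):
        r = find(a)
        sums[r] = sums.get(r, 0.0) + float(w)
    best = max(sums.values())
    spanning = (
        n_nodes is not None
        and len(parent) == n_nodes
        and len(sums) == 1
    )
    return best, spanning


def freedman_lane_null(
    stack,
    predictor,
    groups=None,
    threshold: float = 4.7,
    tail: str = "positive",
    n_perm: int = 5000,
    seed=None,
    nuisance: str = "subject_indicators",
    component_stat: str = "extent",
    exhaustive: bool = False,
    n_nodes: int = None,
) -> np.ndarray:
    """Null distribution of maximal supra-threshold component sizes.

    For each permutation pi (within-subject only): the nuisance-only fit's
    residuals are permuted and added back to the nuisance fit, the full
    model is refitted on the reconstructed data, the t-field is thresholded,
    and the largest connected-component statistic is recorded.

    With ``exhaustive=True`` all prod(n_b!) within-block permutations are
    enumerated instead of sampled (small designs only).
    """
    if isinstance(stack, ConnectivityStack):
        if groups is None:
            groups = stack.meta["subject_id"].to_numpy()
        if n_nodes is None:
            n_nodes = stack.n_nodes
        stack = stack.edge_matrix
    if n_nodes is None:
        n_nodes = n_nodes_from_edges(np.asarray(stack).shape[1])
    if groups is None:
        groups = np.zeros(np.asarray(stack).shape[0], dtype=int)
    ctx = _GLMContext(stack, predictor, groups, nuisance)
    ii, jj = edge_index(n_nodes)

    if exhaustive:
        total = count_within_block_permutations(groups)
        if total > 50_000:
            raise InvalidParameterError(
                f"{total} within-block permutations; exhaustive mode is for "
                "small designs"
            )
        perms = enumerate_within_blocks(groups)
        n_perm = total
    else:
        if n_perm < 100:
            raise InvalidParameterError("n_perm must be at least 100")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perms = (permute_within_blocks(groups, rng) for _ in range(n_perm))

    null = np.empty(n_perm)
    n_spanning = 0
    for k, perm in enumerate(perms):
        y_star = ctx.reresidualize(ctx.y_res[perm])
        _, t = _t_from_residuals(y_star, ctx.x_res, ctx.df)
        mask = _supra_mask(t, threshold, tail)
        w = (np.abs(t[mask]) - threshold) if component_stat == "intensity" else None
        null[k], spanning = _max_component_stat(
            ii[mask], jj[mask], weights=w, n_nodes=n_nodes
        )
        n_spanning += spanning
    if n_spanning > 0.5 * n_perm:
        warnings.warn(
            f"supra-threshold graph spans all nodes in {n_spanning}/{n_perm} "
            "permutations; the threshold is too low for an informative null",
            UserWarning,
            stacklevel=2,
        )
    return null


def component_pvalue(
    observed: float, null_max_sizes: np.ndarray, exact: bool = False
) -> float:
    """FWE p-value against the max-component null.

    Sampled permutations use the add-one formula
    (1 + #{null >= observed}) / (1 + n_perm), which can never return zero.
    With ``exact=True`` (exhaustive enumeration, which already contains the
    identity permutation) the p-value is #{null >= observed} / n_perm.
    """
    null = np.asarray(null_max_sizes, dtype=float)
    if null.size == 0:
        raise InvalidParameterError("null distribution is empty")
    if observed <= 0:
        return 1.0
    hits = np.sum(null >= observed)
    if exact:
        return float(hits / null.size)
    return float((1 + hits) / (1 + null.size))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment across a contrast family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def network_cohens_d(stats: EdgeGLMStats, component: NBSComponent, n_nodes: int):
    """Component effect size: mean over edges of |2 t / sqrt(df)|.

    The per-edge conversion d = 2t/sqrt(df) treats each edge's t as a
    standardized effect; the component value is the mean magnitude over its
    edges.  This is a declared convention for summarizing a network.
    """
    if stats.df <= 0:
        raise DesignError("non-positive residual degrees of freedom")
    if not component.edges:
        raise InvalidParameterError("component has no edges")
    ii, jj = edge_index(n_nodes)
    pos = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(ii, jj))}
    idx = [pos[e] for e in component.edges]
    d = 2.0 * stats.t[idx] / np.sqrt(stats.df)
    return float(np.mean(np.abs(d)))


# ---------------------------------------------------------------------------
# estimator


class NetworkBasedStatistic(BaseEstimator):
    """Network-based statistic for repeated-measures connectivity.

    Parameters
    ----------
    threshold : float, default 4.7
        Primary t threshold defining supra-threshold edges.
    tail : {'positive', 'negative', 'two_sided'}
    n_perm : int, default 5000
        Freedman-Lane permutations (within-subject only).
    nuisance : {'subject_indicators', 'subject_mean'}
    component_stat : {'extent', 'intensity'}
        Component size measure: edge count, or sum of (|t| - threshold).
    random_state : int or Generator
        Seed of the permutation stream (mandatory for reproducible runs).
    exhaustive : bool, default False
        Enumerate all within-block permutations instead of sampling.

    Attributes
    ----------
    t_, beta_, df_ : edge-wise GLM statistics
    components_ : list of :class:`NBSComponent` with p_fwe and cohens_d
    null_max_sizes_ : permutation null of maximal component statistics
    p_values_ : array of component FWE p-values (aligned with components_)
    """

    def __init__(
        self,
        threshold: float = 4.7,
        tail: str = "positive",
        n_perm: int = 5000,
        nuisance: str = "subject_indicators",
        component_stat: str = "extent",
        random_state=None,
        exhaustive: bool = False,
    ):
        self.threshold = threshold
        self.tail = tail
        self.n_perm = n_perm
        self.nuisance = nuisance
        self.component_stat = component_stat
        self.random_state = random_state
        self.exhaustive = exhaustive

    def fit(self, X, y, groups=None):
        """Run the full NBS on an edge matrix (or ConnectivityStack).

        Parameters
        ----------
        X : ConnectivityStack or ndarray (scans x edges)
        y : per-scan predictor values
        groups : per-scan subject labels (taken from stack metadata when
            omitted and X is a ConnectivityStack)
        """
        if self.threshold <= 0:
            raise InvalidParameterError("threshold must be positive")
        if self.tail not in TAILS:
            raise InvalidParameterError(f"tail must be one of {TAILS}")
        if isinstance(X, ConnectivityStack):
            if groups is None:
                groups = X.meta["subject_id"].to_numpy()
            self.n_nodes_ = X.n_nodes
            edge_matrix = X.edge_matrix
        else:
            edge_matrix = np.asarray(X, dtype=float)
            self.n_nodes_ = n_nodes_from_edges(edge_matrix.shape[1])

        stats = fit_edge_glm(edge_matrix, y, groups, nuisance=self.nuisance)
        self.stats_ = stats
        self.t_ = stats.t
        self.beta_ = stats.beta_hat
        self.df_ = stats.df

        ii, jj = edge_index(self.n_nodes_)
        supra = threshold_edges(stats, self.threshold, self.tail)
        pairs = list(zip(ii[supra], jj[supra]))
        self.components_ = find_components(
            pairs, edge_values=stats.t[supra], threshold=self.threshold
        )
        self.null_max_sizes_ = freedman_lane_null(
            edge_matrix,
            y,
            groups,
            threshold=self.threshold,
            tail=self.tail,
            n_perm=self.n_perm,
            seed=self.random_state,
            nuisance=self.nuisance,
            component_stat=self.component_stat,
            exhaustive=self.exhaustive,
            n_nodes=self.n_nodes_,
        )
        for comp in self.components_:
            observed = (
                comp.intensity
                if self.component_stat == "intensity"
                else comp.size_extent
            )
            comp.p_fwe = component_pvalue(
                observed, self.null_max_sizes_, exact=self.exhaustive
            )
            comp.cohens_d = network_cohens_d(stats, comp, self.n_nodes_)
            idx = [
                int(np.flatnonzero((ii == a) & (jj == b))[0])
                for a, b in comp.edges
            ]
            comp.mean_abs_t = float(np.mean(np.abs(stats.t[idx])))
        self.p_values_ = np.array([c.p_fwe for c in self.components_])
        return self

    def to_run(self, score_component: int = None) -> NBSRun:
        """Package the fitted state as an :class:`NBSRun` record."""
        if not hasattr(self, "components_"):
            raise InvalidParameterError("estimator is not fitted yet")
        return NBSRun(
            threshold=self.threshold,
            tail=self.tail,
            n_perm=len(self.null_max_sizes_),
            seed=self.random_state,
            null_max_sizes=self.null_max_sizes_,
            components=self.components_,
            stats=self.stats_,
            score_component=score_component,
            component_stat=self.component_stat,
        )


def run_nbs(
    stack: ConnectivityStack,
    scores: pd.DataFrame,
    components=(1, 2, 3),
    tails=("positive", "negative"),
    threshold: float = 4.7,
    n_perm: int = 5000,
    seed: int = 0,
    nuisance: str = "subject_indicators",
    component_stat: str = "extent",
) -> NBSFamilyResult:
    """Full contrast family: retained components x one-sided tails.

    ``scores`` is the long partial-score table (subject_id, day, run,
    score_1..score_L) from the factor analysis; rows are matched 1:1 with
    the stack's scans.  Each contrast gets its own NBS run with a child
    seed; the per-contrast best network p-values are then FDR-adjusted
    (Benjamini-Hochberg) across the family — by default 3 components x
    2 tails = 6 tests.
    """
    merged = stack.meta.merge(scores, on=SCAN_KEYS, how="left", validate="1:1")
    score_cols = [f"score_{c}" for c in components]
    missing = [c for c in score_cols if c not in merged.columns]
    if missing:
        raise InvalidParameterError(f"score table lacks columns {missing}")
    if merged[score_cols].isna().any().any():
        bad = merged.loc[merged[score_cols].isna().any(axis=1), SCAN_KEYS]
        raise InvalidParameterError(
            f"scans without matching scores: {bad.values.tolist()}"
        )

    contrasts = [(c, t) for c in components for t in tails]
    children = np.random.SeedSequence(seed).spawn(len(contrasts))
    runs = {}
    rows = []
    for (comp, tail), child in zip(contrasts, children):
        est = NetworkBasedStatistic(
            threshold=threshold,
            tail=tail,
            n_perm=n_perm,
            nuisance=nuisance,
            component_stat=component_stat,
            random_state=np.random.default_rng(child),
        )
        est.fit(stack, merged[f"score_{comp}"].to_numpy())
        run = est.to_run(score_component=comp)
        runs[(comp, tail)] = run
        top = run.components[0] if run.components else None
        rows.append(
            {
                "score_component": comp,
                "tail": tail,
                "n_networks": len(run.components),
                "max_extent": top.size_extent if top else 0,
                "cohens_d": top.cohens_d if top else np.nan,
                "p_fwe": run.best_p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = adjust_fdr(table["p_fwe"].to_numpy())
    return NBSFamilyResult(
        runs=runs,
        family_table=table,
        threshold=threshold,
        n_perm=n_perm,
        seed=seed,
    )
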