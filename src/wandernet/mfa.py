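"""Multiple factor analysis (MFA) for repeated-measures questionnaires.

MFA is a principal-component analysis for multi-block data: the same items
observed on the same subjects at several time points.  Each time point is a
*block*; blocks are standardized and then weighted by the inverse of their
squared first singular value so every block contributes equal inertia to the
grand decomposition.  Here the four blocks form a 2 x 2 crossed design
(day x run within day), and a *nested* normalization additionally divides
each block's weight by the inertia of its day group and of its run group.

The grand decomposition yields, per component:

* a **loading** per item x block column (scaled so that the block-weighted
  sum of squared loadings equals the component eigenvalue),
* a **compromise factor score** per subject,
* a **partial factor score** per subject per block, whose barycenter (mean
  over blocks) is exactly the compromise score,
* a **contribution** per column: block weight x squared loading / eigenvalue,
  the fraction of the component's variance carried by that column.
  Contributions sum to 1 within a component; summed over the 4 blocks of an
  item their expected share under equal contribution is 1/12.

Reliability of an item's loading is assessed by bootstrap: resample its four
per-block contributions with replacement, sum, and build a percentile
confidence interval; an item whose interval lies entirely above 1/12
contributes reliably to the component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, InvalidParameterError

N_BLOCKS = 4
N_ITEMS = 12
#: (day, run) labels of the four blocks in canonical order
DEFAULT_BLOCK_LABELS = ((1, 1), (1, 2), (2, 1), (2, 2))

_RANK_TOL = 1e-12


# ---------------------------------------------------------------------------
# containers


@dataclass
class MultiBlockTable:
    """Questionnaire responses in multi-block layout.

    ``values`` is subjects x (items x 4 blocks), block-major: the first
    ``n_items`` columns are block 1 (day 1, run 1), the next are block 2,
    and so on following ``block_labels``.
    """

    values: np.ndarray
    subject_ids: list
    item_names: list
    block_labels: tuple = DEFAULT_BLOCK_LABELS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.block_labels) != N_BLOCKS:
            raise InvalidParameterError("a MultiBlockTable has exactly 4 blocks")
        j = len(self.item_names)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.subject_ids),
            j * N_BLOCKS,
        ):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {j} items x {N_BLOCKS} blocks"
            )
        if np.isnan(self.values).any():
            raise InvalidParameterError("missing values are not supported")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    def blocks(self) -> list:
        """Split into the 4 per-block subjects x items arrays."""
        j = self.n_items
        return [self.values[:, b * j : (b + 1) * j] for b in range(N_BLOCKS)]

    @classmethod
    def from_long(cls, df: pd.DataFrame, item_names=None) -> "MultiBlockTable":
        """Build from a long table with subject_id, day, run, item columns.

        Subjects without all 4 (day, run) rows are dropped with a warning;
        duplicated (subject, day, run) rows are an error.
        """
        if item_names is None:
            item_names = [c for c in df.columns if c.startswith("item_")]
        required = ["subject_id", "day", "run"] + list(item_names)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise InvalidParameterError(f"questionnaire lacks columns {missing}")
        dup = df.duplicated(subset=["subject_id", "day", "run"])
        if dup.any():
            rows = df.loc[dup, ["subject_id", "day", "run"]].values.tolist()
            raise InvalidParameterError(f"duplicate (subject, day, run) rows: {rows}")
        counts = df.groupby("subject_id").size()
        complete = counts.index[counts == N_BLOCKS]
        dropped = sorted(set(counts.index) - set(complete))
        if dropped:
            warnings.warn(
                f"dropping subject(s) without all {N_BLOCKS} blocks: {dropped}",
                UserWarning,
                stacklevel=2,
            )
        df = df[df["subject_id"].isin(complete)]
        if df.empty:
            raise DegenerateInputError("no subject has all 4 questionnaire blocks")
        subjects = sorted(df["subject_id"].unique())
        panels = []
        for day, run in DEFAULT_BLOCK_LABELS:
            blk = df[(df["day"] == day) & (df["run"] == run)]
            if set(blk["subject_id"]) != set(subjects):
                raise InvalidParameterError(
                    f"block (day={day}, run={run}) does not cover every subject"
                )
            blk = blk.set_index("subject_id").loc[subjects, list(item_names)]
            panels.append(blk.to_numpy(dtype=float))
        return cls(
            values=np.hstack(panels),
            subject_ids=list(subjects),
            item_names=list(item_names),
        )

    def to_long(self) -> pd.DataFrame:
        j = self.n_items
        rows = []
        for b, (day, run) in enumerate(self.block_labels):
            blk = pd.DataFrame(
                self.values[:, b * j : (b + 1) * j], columns=self.item_names
            )
            blk.insert(0, "run", run)
            blk.insert(0, "day", day)
            blk.insert(0, "subject_id", self.subject_ids)
            rows.append(blk)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["subject_id", "day", "run"], ignore_index=True)


@dataclass
class MFAWeights:
    """Column weights of the multi-block decomposition.

    ``block_sv1`` holds each standardized block's first singular value;
    the base weight is its inverse square, so that after weighting every
    block's first singular value is 1.  With nested normalization the base
    weight is further divided by ``day_factor`` and ``time_factor`` — the
    squared first singular values of the base-weighted day-group and
    run-group concatenations.
    """

    block_weight: np.ndarray
    block_sv1: np.ndarray
    day_factor: dict
    time_factor: dict
    block_labels: tuple = DEFAULT_BLOCK_LABELS

    def __post_init__(self):
        self.block_weight = np.asarray(self.block_weight, dtype=float)
        if not np.all(np.isfinite(self.block_weight)) or np.any(
            self.block_weight <= 0
        ):
            raise InvalidParameterError("block weights must be finite and positive")


@dataclass
class MFAResult:
    """Fitted multi-block factor analysis.

    ``eigenvalues`` is the full spectrum; ``loadings``, scores and
    ``contributions`` cover the ``n_components`` retained components.
    ``partial_scores`` has shape (blocks, subjects, components) and its mean
    over blocks equals ``compromise_scores`` (barycenter property).
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    compromise_scores: np.ndarray
    partial_scores: np.ndarray
    variance_explained: np.ndarray
    contributions: np.ndarray
    weights: MFAWeights
    n_components: int
    item_names: list
    block_labels: tuple
    column_means: np.ndarray
    column_stds: np.ndarray
    axes: np.ndarray = field(repr=False, default=None)  # generalized right vectors Q

    @property
    def n_items(self) -> int:
        return len(self.item_names)


@dataclass
class ContributionSummary:
    """Bootstrap assessment of item contributions for one component.

    ``table`` has one row per item: the observed contribution summed over
    the 4 blocks, bootstrap median, percentile CI bounds (Bonferroni-corrected
    and uncorrected), and significance flags (CI lower bound above the equal
    contribution value 1/n_items).
    """

    table: pd.DataFrame
    component: int
    expected_null: float
    n_boot: int
    alpha: float
    bonferroni: bool


# ---------------------------------------------------------------------------
# core operations


def preprocess_blocks(blocks, scale: bool = True):
    """Center (and optionally unit-scale) every column within its block.

    Returns ``(standardized_blocks, means, stds)`` where means/stds are
    lists of per-block 1-D arrays (stds are ones when ``scale=False``).
    Raises :class:`DegenerateInputError` naming the first zero-variance
    column when ``scale=True``.
    """
    out, means, stds = [], [], []
    for b, blk in enumerate(blocks):
        blk = np.asarray(blk, dtype=float)
        if blk.shape[0] < 3:
            raise InvalidParameterError("need at least 3 subjects")
        mu = blk.mean(axis=0)
        centered = blk - mu
        if scale:
            sd = centered.std(axis=0, ddof=1)
            if np.any(sd == 0):
                j = int(np.flatnonzero(sd == 0)[0])
                raise DegenerateInputError(
                    f"column {j} of block {b} has zero variance; "
                    "cannot scale to unit variance"
                )
        else:
            sd = np.ones(blk.shape[1])
        out.append(centered / sd)
        means.append(mu)
        stds.append(sd)
    return out, means, stds


def _first_sv(x: np.ndarray) -> float:
    return float(np.linalg.svd(x, compute_uv=False)[0])


def compute_block_weights(blocks, block_labels=None, nested: bool = True) -> MFAWeights:
    """Inverse-first-eigenvalue block weights, optionally nested by day/run.

    ``blocks`` must already be standardized.  The base weight of block ``b``
    is ``1 / sv1_b**2`` where ``sv1_b`` is the first singular value of the
    row-normalized block (rows scaled by 1/sqrt(n-1), so a standardized
    column has unit inertia).  With ``nested=True`` the blocks sharing a day
    and those sharing a run are concatenated after base weighting, and each
    block's weight is further divided by the squared first singular value of
    both of its groups.
    """
    if block_labels is None:
        if len(blocks) == N_BLOCKS:
            block_labels = DEFAULT_BLOCK_LABELS
        elif nested:
            raise InvalidParameterError(
                "nested weighting needs (day, run) block labels"
            )
        else:
            block_labels = tuple((1, b + 1) for b in range(len(blocks)))
    n = blocks[0].shape[0]
    c = 1.0 / np.sqrt(n - 1)
    sv1 = np.array([_first_sv(c * np.asarray(b, dtype=float)) for b in blocks])
    if np.any(sv1 <= _RANK_TOL):
        bad = int(np.flatnonzero(sv1 <= _RANK_TOL)[0])
        raise DegenerateInputError(f"block {bad} is all zero after standardization")
    base = 1.0 / sv1**2

    day_factor = {d: 1.0 for d, _ in block_labels}
    time_factor = {t: 1.0 for _, t in block_labels}
    if nested:
        for level, factors in ((0, day_factor), (1, time_factor)):
            for g in factors:
                members = [
                    i for i, lab in enumerate(block_labels) if lab[level] == g
                ]
                concat = np.hstack(
                    [np.sqrt(base[i]) * c * np.asarray(blocks[i]) for i in members]
                )
                factors[g] = _first_sv(concat) ** 2

    weight = np.array(
        [
            base[i] / (day_factor[d] * time_factor[t])
            for i, (d, t) in enumerate(block_labels)
        ]
    )
    return MFAWeights(
        block_weight=weight,
        block_sv1=sv1,
        day_factor=day_factor,
        time_factor=time_factor,
        block_labels=tuple(block_labels),
    )


def fit_mfa(
    blocks,
    weights: MFAWeights,
    n_components: int,
    item_names=None,
    block_labels=None,
    fix_signs: bool = True,
    column_means=None,
    column_stds=None,
) -> MFAResult:
    """Grand decomposition of the column-weighted concatenated table.

    Computes the generalized SVD of the standardized concatenation with
    column weights ``a`` (each block's weight repeated over its columns) and
    row masses 1/(n-1).  Eigenvalues are squared singular values; loadings
    are scaled so the block-weighted sum of squared loadings per component
    equals its eigenvalue; partial scores are ``K * a_b * X_b @ Q_b``.
    """
    k = len(blocks)
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    n, j = blocks[0].shape
    if block_labels is None:
        block_labels = weights.block_labels if k == N_BLOCKS else tuple(
            (1, b + 1) for b in range(k)
        )
    if item_names is None:
        item_names = [f"item_{i + 1:02d}" for i in range(j)]
    total_cols = sum(b.shape[1] for b in blocks)
    if not 1 <= n_components <= min(n - 1, total_cols):
        raise InvalidParameterError(
            f"n_components={n_components} must be in [1, min(n_subjects - 1, "
            f"n_columns)] = [1, {min(n - 1, total_cols)}]"
        )

    x = np.hstack(blocks)
    a = np.repeat(weights.block_weight, [b.shape[1] for b in blocks])
    c = 1.0 / np.sqrt(n - 1)
    xw = c * x * np.sqrt(a)
    u, s, vt = np.linalg.svd(xw, full_matrices=False)
    lam = s**2
    total_inertia = lam.sum()

    L = n_components
    q = vt.T / np.sqrt(a)[:, None]  # generalized axes, Q' A Q = I
    loadings = q[:, :L] * s[:L]
    scores = (x * a) @ q[:, :L]
    partial = np.stack(
        [
            k * weights.block_weight[b] * blocks[b] @ q[b * j : (b + 1) * j, :L]
            for b in range(k)
        ]
    )

    if fix_signs:
        for ell in range(L):
            jmax = int(np.argmax(np.abs(loadings[:, ell])))
            if loadings[jmax, ell] < 0:
                loadings[:, ell] *= -1
                q[:, ell] *= -1
                scores[:, ell] *= -1
                partial[:, :, ell] *= -1

    with np.errstate(divide="ignore", invalid="ignore"):
        ctr_cols = a[:, None] * loadings**2 / lam[:L]
    degenerate = lam[:L] <= _RANK_TOL * max(lam[0], 1.0)
    if degenerate.any():
        ctr_cols[:, degenerate] = np.nan
        warnings.warn(
            "contributions undefined for zero-eigenvalue component(s) "
            f"{np.flatnonzero(degenerate) + 1}",
            RuntimeWarning,
            stacklevel=2,
        )
    contributions = ctr_cols.reshape(k, j, L).transpose(1, 0, 2)

    return MFAResult(
        eigenvalues=lam,
        loadings=loadings,
        compromise_scores=scores,
        partial_scores=partial,
        variance_explained=lam[:L] / total_inertia,
        contributions=contributions,
        weights=weights,
        n_components=L,
        item_names=list(item_names),
        block_labels=tuple(block_labels),
        column_means=None if column_means is None else np.concatenate(column_means),
        column_stds=None if column_stds is None else np.concatenate(column_stds),
        axes=q[:, :L],
    )


def compute_contributions(result: MFAResult, weights: MFAWeights | None = None):
    """Contributions ctr[j, b, l] = a_b * loading^2 / eigenvalue.

    Recomputed from the fitted loadings; per component the contributions sum
    to 1.  Raises for components with a zero eigenvalue, where the ratio is
    undefined.
    """
    w = weights if weights is not None else result.weights
    L = result.n_components
    lam = result.eigenvalues[:L]
    if np.any(lam <= _RANK_TOL * max(result.eigenvalues[0], 1.0)):
        bad = int(np.flatnonzero(lam <= _RANK_TOL * max(result.eigenvalues[0], 1.0))[0])
        raise DegenerateInputError(
            f"component {bad + 1} has zero eigenvalue; contributions undefined"
        )
    j = result.n_items
    k = len(result.block_labels)
    a = np.repeat(w.block_weight, j)
    ctr = a[:, None] * result.loadings**2 / lam
    return ctr.reshape(k, j, L).transpose(1, 0, 2)


def bootstrap_contributions(
    contributions: np.ndarray,
    component: int = 1,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    bonferroni: bool = True,
    seed=None,
    item_names=None,
) -> ContributionSummary:
    """Percentile bootstrap CI for each item's summed contribution.

    For every item, its 4 per-block contributions to ``component`` (1-based)
    are resampled with replacement (4 draws) and summed; ``n_boot``
    replicates form a percentile interval at level ``1 - alpha`` (``alpha``
    divided by the number of items under Bonferroni).  An item is flagged
    significant when its interval's lower bound exceeds the equal
    contribution value 1/n_items.
    """
    if n_boot < 2:
        raise InvalidParameterError("n_boot must be at least 2")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is very small for percentile intervals",
            UserWarning,
            stacklevel=2,
        )
    ctr = np.asarray(contributions, dtype=float)
    if ctr.ndim == 3:
        if not 1 <= component <= ctr.shape[2]:
            raise InvalidParameterError(
                f"component {component} not in 1..{ctr.shape[2]}"
            )
        ctr = ctr[:, :, component - 1]
    n_items, n_blocks = ctr.shape
    if item_names is None:
        item_names = [f"item_{i + 1:02d}" for i in range(n_items)]
    expected = 1.0 / n_items
    a_eff = alpha / n_items if bonferroni else alpha

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_blocks, size=(n_boot, n_items, n_blocks))
    boot = np.take_along_axis(ctr[None, :, :], idx, axis=2).sum(axis=2)

    lo, hi = np.quantile(boot, [a_eff / 2, 1 - a_eff / 2], axis=0)
    lo_u, hi_u = np.quantile(boot, [alpha / 2, 1 - alpha / 2], axis=0)
    med = np.median(boot, axis=0)
    observed = ctr.sum(axis=1)
    table = pd.DataFrame(
        {
            "item": item_names,
            "summed_contribution": observed,
            "boot_median": med,
            "ci_lower": lo,
            "ci_upper": hi,
            "ci_lower_uncorrected": lo_u,
            "ci_upper_uncorrected": hi_u,
            "significant": lo > expected,
            "significant_uncorrected": lo_u > expected,
        }
    )
    return ContributionSummary(
        table=table,
        component=component,
        expected_null=expected,
        n_boot=n_boot,
        alpha=alpha,
        bonferroni=bonferroni,
    )


def variance_table(result: MFAResult) -> pd.DataFrame:
    """Scree table: eigenvalue, proportion and cumulative proportion."""
    lam = result.eigenvalues
    prop = lam / lam.sum()
    return pd.DataFrame(
        {
            "component": np.arange(1, lam.size + 1),
            "eigenvalue": lam,
            "proportion": prop,
            "cumulative": np.cumsum(prop),
        }
    )


def partial_scores_frame(result: MFAResult, subject_ids) -> pd.DataFrame:
    """Partial factor scores in long form, keyed by (subject_id, day, run).

    This is the per-scan predictor table consumed by the network statistic.
    """
    rows = []
    for b, (day, run) in enumerate(result.block_labels):
        blk = pd.DataFrame(
            result.partial_scores[b],
            columns=[f"score_{l + 1}" for l in range(result.n_components)],
        )
        blk.insert(0, "run", run)
        blk.insert(0, "day", day)
        blk.insert(0, "subject_id", list(subject_ids))
        rows.append(blk)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subject_id", "day", "run"], ignore_index=True)


# ---------------------------------------------------------------------------
# estimator


class MFA(TransformerMixin, BaseEstimator):
    """Multiple factor analysis transformer (scikit-learn style).

    Parameters
    ----------
    n_components : int, default 3
        Components to retain.  Retention is the caller's choice; the scree
        table (:func:`variance_table`) supports the decision.
    n_blocks : int, default 4
        Number of repeated-measures blocks; columns of ``X`` are split
        evenly, block-major.
    block_labels : sequence of (day, run), optional
        Crossed design labels; defaults to the 2 x 2 day x run layout for
        four blocks.
    scale : bool, default True
        Unit-scale columns within block before weighting (questionnaire
        items on heterogeneous usage ranges).
    nested : bool, default True
        Apply the two-level day/run normalization on top of the standard
        per-block first-eigenvalue weighting.
    fix_signs : bool, default True
        Orient each component so its largest-magnitude loading is positive.

    Attributes
    ----------
    eigenvalues_ : full eigenvalue spectrum (descending)
    loadings_ : (items * blocks, n_components)
    scores_ : compromise factor scores, (subjects, n_components)
    partial_scores_ : (blocks, subjects, n_components)
    variance_explained_ : proportion of total inertia per retained component
    contributions_ : (items, blocks, n_components)
    block_weights_ : :class:`MFAWeights`
    result_ : the full :class:`MFAResult`
    """

    def __init__(
        self,
        n_components: int = 3,
        n_blocks: int = N_BLOCKS,
        block_labels=None,
        scale: bool = True,
        nested: bool = True,
        fix_signs: bool = True,
    ):
        self.n_components = n_components
        self.n_blocks = n_blocks
        self.block_labels = block_labels
        self.scale = scale
        self.nested = nested
        self.fix_signs = fix_signs

    # -- helpers ------------------------------------------------------------

    def _coerce(self, X):
        if isinstance(X, MultiBlockTable):
            return X.values, X.item_names, list(X.subject_ids)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidParameterError("X must be 2-D (subjects x columns)")
        if X.shape[1] % self.n_blocks:
            raise InvalidParameterError(
                f"{X.shape[1]} columns not divisible into {self.n_blocks} blocks"
            )
        return X, None, None

    def _split(self, X):
        j = X.shape[1] // self.n_blocks
        return [X[:, b * j : (b + 1) * j] for b in range(self.n_blocks)]

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        X, item_names, subject_ids = self._coerce(X)
        if np.isnan(X).any():
            raise InvalidParameterError("missing values are not supported")
        labels = self.block_labels
        if labels is None and self.n_blocks == N_BLOCKS:
            labels = DEFAULT_BLOCK_LABELS
        blocks = self._split(X)
        std_blocks, means, stds = preprocess_blocks(blocks, scale=self.scale)
        weights = compute_block_weights(std_blocks, labels, nested=self.nested)
        self.result_ = fit_mfa(
            std_blocks,
            weights,
            self.n_components,
            item_names=item_names,
            block_labels=labels,
            fix_signs=self.fix_signs,
            column_means=means,
            column_stds=stds,
        )
        self.subject_ids_ = subject_ids
        self.n_features_in_ = X.shape[1]
        r = self.result_
        self.eigenvalues_ = r.eigenvalues
        self.loadings_ = r.loadings
        self.scores_ = r.compromise_scores
        self.partial_scores_ = r.partial_scores
        self.variance_explained_ = r.variance_explained
        self.contributions_ = r.contributions
        self.block_weights_ = r.weights
        return self

    def transform(self, X):
        """Compromise factor scores of (new) subjects."""
        if not hasattr(self, "result_"):
            raise InvalidParameterError("MFA instance is not fitted yet")
        X, _, _ = self._coerce(X)
        if X.shape[1] != self.n_features_in_:
            raise InvalidParameterError("column count differs from the fitted data")
        r = self.result_
        x = (X - r.column_means) / r.column_stds
        j = x.shape[1] // self.n_blocks
        a = np.repeat(r.weights.block_weight, j)
        return (x * a) @ r.axes

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_

    # -- convenience --------------------------------------------------------

    def bootstrap(self, component: int = 1, **kwargs) -> ContributionSummary:
        if not hasattr(self, "result_"):
            raise InvalidParameterError("MFA instance is not fitted yet")
        return bootstrap_contributions(
            self.contributions_,
            component=component,
            item_names=self.result_.item_names,
            **kwargs,
        )

    def variance_table(self) -> pd.DataFrame:
        return variance_table(self.result_)
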