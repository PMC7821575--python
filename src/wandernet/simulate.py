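"""Synthetic repeated-measures questionnaire and connectivity data.

Emulates the study design the pipeline targets: 19 subjects scanned in a
2 day x 2 run crossed design (4 scans each), a 12-item post-scan thought
questionnaire driven by 3 latent thought dimensions, and per-scan whole-brain
connectivity in which a planted subnetwork's edge strength varies linearly
with the scan's latent factor score on top of stable subject-level offsets
and edge noise.  Ground truth (latent scores, planted edges, effect size) is
returned alongside the data so recovery can be tested.

All generators are driven by a single integer seed expanded into fixed
per-stage child streams, so identical parameters yield bit-identical data
regardless of which generators are called or in what order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityStack,
    ROITimeSeriesSet,
    edge_count,
    edge_index,
)
from .exceptions import InvalidParameterError
from .mfa import DEFAULT_BLOCK_LABELS, MultiBlockTable, N_BLOCKS, N_ITEMS

# fixed stage ids -> independent child streams of the one global seed
_STAGES = {"scores": 0, "questionnaire": 1, "connectivity": 2, "timeseries": 3,
           "nodes": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


def default_latent_loadings() -> np.ndarray:
    """Well-separated 12 x 3 structure: 6, 4 and 2 items per latent factor.

    Factors of different sizes keep the component eigenvalues separated even
    after items are scaled to unit variance; principal axes are only
    identifiable when the spectrum is separated, mirroring the scree-elbow
    ordering of real thought-content dimensions (a dominant first dimension,
    then progressively smaller ones).
    """
    loadings = np.zeros((N_ITEMS, 3))
    loadings[0:6, 0] = 1.0
    loadings[6:10, 1] = 1.0
    loadings[10:12, 2] = 1.0
    return loadings


def default_planted_edges(n_nodes: int = 60, clique: int = 6) -> tuple:
    """A planted clique among the first ``clique`` nodes."""
    if clique > n_nodes:
        raise InvalidParameterError("clique larger than node count")
    return tuple((i, j) for i in range(clique) for j in range(i + 1, clique))


@dataclass
class SimParams:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 19 subjects x 4 scans (2 days x
    2 runs), 12 items on a 0-100 visual-analog-like scale, 3 latent thought
    factors with unit subject-level spread and half-unit scan-to-scan spread,
    and a 60-node connectome (scaled down from a 470-region parcellation;
    up to 470 supported) with a planted 6-node clique whose edges gain
    ``beta`` correlation units per unit factor score.
    """

    n_subjects: int = 19
    n_nodes: int = 60
    n_volumes: int = 300
    latent_loadings: np.ndarray = field(default_factory=default_latent_loadings)
    subject_score_sd: float = 1.0
    block_score_sd: float = 0.5
    item_noise_sd: float = 0.3
    planted_edges: tuple = None
    beta: float = 0.1
    edge_noise_sd: float = 0.1
    subject_edge_sd: float = 0.1
    base_edge_mean: float = 0.2
    base_edge_sd: float = 0.1
    item_center: float = 50.0
    item_scale: float = 8.0
    round_items: bool = False
    seed: int = 0

    n_blocks: int = field(default=N_BLOCKS, init=False)
    n_items: int = field(default=N_ITEMS, init=False)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be positive")
        if not 2 <= self.n_nodes <= 470:
            raise InvalidParameterError("n_nodes must be between 2 and 470")
        if self.n_volumes < 10:
            raise InvalidParameterError("n_volumes must be at least 10")
        self.latent_loadings = np.asarray(self.latent_loadings, dtype=float)
        if self.latent_loadings.shape != (N_ITEMS, 3):
            raise InvalidParameterError(
                f"latent_loadings must be {N_ITEMS} x 3, got "
                f"{self.latent_loadings.shape}"
            )
        for name in ("subject_score_sd", "block_score_sd", "item_noise_sd",
                     "edge_noise_sd", "subject_edge_sd", "base_edge_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.planted_edges is None:
            self.planted_edges = default_planted_edges(
                self.n_nodes, clique=min(6, self.n_nodes)
            )
        self.planted_edges = tuple(tuple(int(v) for v in e) for e in self.planted_edges)
        for i, j in self.planted_edges:
            if not (0 <= i < j < self.n_nodes):
                raise InvalidParameterError(
                    f"planted edge ({i}, {j}) outside the upper triangle of "
                    f"{self.n_nodes} nodes"
                )


@dataclass
class GroundTruth:
    """Latent state behind one synthetic dataset."""

    true_scores: np.ndarray  # (subjects, blocks, 3)
    planted_edges: tuple
    beta: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_scores": np.asarray(self.true_scores).tolist(),
                "planted_edges": [list(e) for e in self.planted_edges],
                "beta": self.beta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_scores=np.asarray(d["true_scores"], dtype=float),
            planted_edges=tuple(tuple(e) for e in d["planted_edges"]),
            beta=float(d["beta"]),
        )


def generate_factor_scores(params: SimParams) -> GroundTruth:
    """Draw latent per-scan factor scores.

    score[i, b, k] = subject_level[i, k] + block_level[i, b, k] with
    independent zero-mean Gaussian draws, so scores are zero mean in
    population with variance subject_score_sd^2 + block_score_sd^2.
    """
    rng = stage_rng(params.seed, "scores")
    subj = rng.normal(0.0, params.subject_score_sd, size=(params.n_subjects, 1, 3))
    block = rng.normal(
        0.0, params.block_score_sd, size=(params.n_subjects, N_BLOCKS, 3)
    )
    return GroundTruth(
        true_scores=subj + block,
        planted_edges=params.planted_edges,
        beta=params.beta,
    )


def subject_ids(n_subjects: int) -> list:
    return [f"sub-{i + 1:02d}" for i in range(n_subjects)]


def generate_questionnaire(truth: GroundTruth, params: SimParams) -> MultiBlockTable:
    """Item responses from the latent scores.

    raw = latent_loadings @ score + N(0, item_noise_sd); responses are the
    fixed affine map item_center + item_scale * raw, clipped to the 0-100
    response scale (with the default scales the clip is ~5-sigma, so it is
    essentially never active) and optionally rounded to integers.
    """
    if truth.true_scores.shape != (params.n_subjects, N_BLOCKS, 3):
        raise InvalidParameterError("ground truth does not match SimParams")
    rng = stage_rng(params.seed, "questionnaire")
    raw = np.einsum("jk,ibk->ibj", params.latent_loadings, truth.true_scores)
    raw = raw + rng.normal(0.0, params.item_noise_sd, size=raw.shape)
    vals = params.item_center + params.item_scale * raw
    vals = np.clip(vals, 0.0, 100.0)
    if params.round_items:
        vals = np.round(vals)
    # (subjects, blocks, items) -> subjects x (items * blocks), block-major
    values = np.hstack([vals[:, b, :] for b in range(N_BLOCKS)])
    return MultiBlockTable(
        values=values,
        subject_ids=subject_ids(params.n_subjects),
        item_names=[f"item_{i + 1:02d}" for i in range(N_ITEMS)],
        block_labels=DEFAULT_BLOCK_LABELS,
    )


def make_node_table(n_nodes: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic region table: label, hemisphere, MNI-like mm coordinates."""
    rng = stage_rng(seed, "nodes")
    hemi = np.where(np.arange(n_nodes) % 2 == 0, "L", "R")
    x = rng.uniform(8, 65, n_nodes) * np.where(hemi == "L", -1, 1)
    y = rng.uniform(-95, 65, n_nodes)
    z = rng.uniform(-55, 75, n_nodes)
    return pd.DataFrame(
        {
            "label": [f"Region {i + 1:03d}" for i in range(n_nodes)],
            "hemisphere": hemi,
            "x": np.round(x, 2),
            "y": np.round(y, 2),
            "z": np.round(z, 2),
        }
    )


def _planted_mask(params: SimParams) -> np.ndarray:
    ii, jj = edge_index(params.n_nodes)
    lookup = {(int(a), int(b)) for a, b in params.planted_edges}
    return np.fromiter(
        ((int(a), int(b)) in lookup for a, b in zip(ii, jj)),
        dtype=bool,
        count=ii.size,
    )


def _scan_meta(params: SimParams) -> pd.DataFrame:
    subs = subject_ids(params.n_subjects)
    rows = [
        {"subject_id": s, "day": d, "run": r}
        for s in subs
        for d, r in DEFAULT_BLOCK_LABELS
    ]
    return pd.DataFrame(rows)


def generate_connectivity(
    truth: GroundTruth, params: SimParams, score_component: int = 1
) -> ConnectivityStack:
    """Per-scan edge vectors with the planted score-coupled subnetwork.

    edge[scan, e] = base[e] + subject_offset[i, e]
                    + beta * score[i, b, component] * 1[e planted]
                    + N(0, edge_noise_sd),
    clipped to (-1, 1).  Scan rows are ordered subject-major then
    (day, run), matching the questionnaire block layout.
    """
    if score_component not in (1, 2, 3):
        raise InvalidParameterError("score_component must be 1, 2 or 3")
    rng = stage_rng(params.seed, "connectivity")
    n, e = params.n_subjects, edge_count(params.n_nodes)
    base = rng.normal(params.base_edge_mean, params.base_edge_sd, size=e)
    offsets = rng.normal(0.0, params.subject_edge_sd, size=(n, e))
    noise = rng.normal(0.0, params.edge_noise_sd, size=(n, N_BLOCKS, e))
    planted = _planted_mask(params)

    scores = truth.true_scores[:, :, score_component - 1]  # (n, blocks)
    edges = (
        base[None, None, :]
        + offsets[:, None, :]
        + params.beta * scores[:, :, None] * planted[None, None, :]
        + noise
    )
    lim = 1.0 - 1e-6
    edges = np.clip(edges, -lim, lim).reshape(n * N_BLOCKS, e)
    return ConnectivityStack(
        edge_matrix=edges,
        meta=_scan_meta(params),
        node_table=make_node_table(params.n_nodes, params.seed),
        n_nodes=params.n_nodes,
    )


def generate_roi_timeseries(
    truth: GroundTruth,
    params: SimParams,
    score_component: int = 1,
    n_communities: int = 4,
    community_coupling: float = 0.3,
    planted_coupling: float = 0.3,
) -> ROITimeSeriesSet:
    """Regional time series whose correlations carry the planted structure.

    Each region mixes its community's shared signal (weight
    ``community_coupling``) with private noise; for every planted node pair
    an extra pair-specific shared signal is added to both endpoints with
    variance ``max(0, planted_coupling + beta * score)``, so the pair's
    correlation increases monotonically with the scan's factor score.  This
    path yields genuine (positive semi-definite) correlation matrices.
    """
    if score_component not in (1, 2, 3):
        raise InvalidParameterError("score_component must be 1, 2 or 3")
    rng = stage_rng(params.seed, "timeseries")
    n_nodes, t = params.n_nodes, params.n_volumes
    community = np.arange(n_nodes) % n_communities
    meta = _scan_meta(params)
    scores = truth.true_scores[:, :, score_component - 1]

    series = []
    for i in range(params.n_subjects):
        for b in range(N_BLOCKS):
            shared = rng.standard_normal((t, n_communities))
            private = rng.standard_normal((t, n_nodes))
            ts = (
                np.sqrt(community_coupling) * shared[:, community]
                + np.sqrt(1.0 - community_coupling) * private
            )
            strength = max(0.0, planted_coupling + truth.beta * scores[i, b])
            if strength > 0 and truth.planted_edges:
                for a, c in truth.planted_edges:
                    h = rng.standard_normal(t)
                    ts[:, a] = ts[:, a] + np.sqrt(strength) * h
                    ts[:, c] = ts[:, c] + np.sqrt(strength) * h
            series.append(ts)
    return ROITimeSeriesSet(
        series=series,
        meta=meta,
        region_names=list(make_node_table(n_nodes, params.seed)["label"]),
    )


def simulate_study(params: SimParams, score_component: int = 1):
    """One full synthetic study: (truth, questionnaire, connectivity stack)."""
    truth = generate_factor_scores(params)
    table = generate_questionnaire(truth, params)
    stack = generate_connectivity(truth, params, score_component=score_component)
    return truth, table, stack
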