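"""Similarity scores between cell groups of independent datasets.

Two groups are compared through their fold-change frames of reference.
Every pairwise (Hadamard) product of contrast columns is formed — p × q
products per feature for frames with p and q contrasts — and averaged per
feature into the SC score, whose sign records whether expression changes
agree across datasets.  The similarity is

    similarity = (sqrt(|Σ SC|) + ω) · sign(Σ SC)

where ω = ln(|d|)·sign(d), d being the count imbalance of features with
SC above +threshold versus below −threshold (default 0.2); ω = 0 when
d = 0.  Features ranked by SC are the markers driving a match.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .foldchange import FoldChangeFrame

__all__ = [
    "FeatureContribution",
    "SimilarityRecord",
    "feature_products",
    "sc_scores",
    "concordance_weight",
    "similarity_score",
    "compare_datasets",
    "label_transfer",
]

SC_THRESHOLD = 0.2  # |SC| above which a feature counts toward concordance


@dataclass
class FeatureContribution:
    feature_id: str
    sc: float  # mean of Hadamard FC products, log2² units


@dataclass
class SimilarityRecord:
    """One comparison: group ``group_a`` of ``dataset_a`` vs ``group_b`` of ``dataset_b``."""

    dataset_a: str
    group_a: str
    dataset_b: str
    group_b: str
    similarity: float
    omega: float
    sum_sc: float
    n_pos: int
    n_neg: int
    top_features: list[FeatureContribution] = field(default_factory=list)


def feature_products(
    frame_a: FoldChangeFrame, frame_b: FoldChangeFrame
) -> np.ndarray:
    """All pairwise products of contrast columns, features × (p·q).

    Column order is a-major: products of frame_a column s with frame_b
    column t appear at index s·q + t.
    """
    if frame_a.feature_ids != frame_b.feature_ids:
        raise ValueError("frames do not share a feature space")
    fa = frame_a.fc  # features × p
    fb = frame_b.fc  # features × q
    nfeat, p = fa.shape
    q = fb.shape[1]
    return (fa[:, :, None] * fb[:, None, :]).reshape(nfeat, p * q)


def sc_scores(products: np.ndarray) -> np.ndarray:
    """Per-feature SC: mean of the k pairwise products."""
    products = np.asarray(products, dtype=float)
    if products.ndim != 2 or products.shape[1] < 1:
        raise ValueError("products must be features × k with k >= 1")
    return products.mean(axis=1)


def concordance_weight(
    sc: np.ndarray, threshold: float = SC_THRESHOLD
) -> tuple[float, int, int]:
    """Concordance weight ω with the counts it is built from.

    n_pos counts features with SC > threshold, n_neg those with
    SC < −threshold; with d = n_pos − n_neg, ω = ln(|d|)·sign(d), taken
    as 0 when d = 0 (no concordance evidence either way).
    """
    sc = np.asarray(sc, dtype=float)
    n_pos = int(np.sum(sc > threshold))
    n_neg = int(np.sum(sc < -threshold))
    d = n_pos - n_neg
    omega = 0.0 if d == 0 else math.log(abs(d)) * (1 if d > 0 else -1)
    return omega, n_pos, n_neg


def similarity_score(sc: np.ndarray, omega: float) -> float:
    """Signed similarity: (sqrt(|Σ SC|) + ω)·sign(Σ SC); 0 if the sum is 0."""
    s = float(np.sum(sc))
    if s == 0.0:
        return 0.0
    sign = 1.0 if s > 0 else -1.0
    return (math.sqrt(abs(s)) + omega) * sign


def _record(
    frame_a: FoldChangeFrame,
    frame_b: FoldChangeFrame,
    top_n_features: int,
    threshold: float,
) -> SimilarityRecord:
    products = feature_products(frame_a, frame_b)
    sc = sc_scores(products)
    omega, n_pos, n_neg = concordance_weight(sc, threshold)
    sim = similarity_score(sc, omega)
    order = sorted(
        range(len(sc)), key=lambda i: (-sc[i], frame_a.feature_ids[i])
    )[:top_n_features]
    top = [FeatureContribution(frame_a.feature_ids[i], float(sc[i])) for i in order]
    return SimilarityRecord(
        dataset_a=frame_a.dataset,
        group_a=frame_a.focal_group,
        dataset_b=frame_b.dataset,
        group_b=frame_b.focal_group,
        similarity=sim,
        omega=omega,
        sum_sc=float(np.sum(sc)),
        n_pos=n_pos,
        n_neg=n_neg,
        top_features=top,
    )


def compare_datasets(
    frames: Mapping[str, Sequence[FoldChangeFrame]],
    top_n_features: int = 10,
    sc_threshold: float = SC_THRESHOLD,
) -> list[SimilarityRecord]:
    """Similarity records for every group pair of every ordered dataset pair.

    All combinations are reported (the full similarity heatmap); records
    are ordered by (dataset_a, group_a, dataset_b, group_b).
    """
    names = sorted(frames)
    if len(names) < 2:
        raise ValueError("need >= 2 datasets to compare")
    records: list[SimilarityRecord] = []
    for name_a, name_b in itertools.permutations(names, 2):
        for frame_a in sorted(frames[name_a], key=lambda f: f.focal_group):
            for frame_b in sorted(frames[name_b], key=lambda f: f.focal_group):
                records.append(
                    _record(frame_a, frame_b, top_n_features, sc_threshold)
                )
    records.sort(key=lambda r: (r.dataset_a, r.group_a, r.dataset_b, r.group_b))
    return records


def label_transfer(
    records: Sequence[SimilarityRecord],
    reference: str,
    truth: Mapping[str, str],
    group_sizes: Mapping[str, int] | None = None,
) -> float:
    """Cell-weighted accuracy of annotating query groups from a reference.

    Each query group receives the label of its maximal-similarity
    reference group (ties broken by lexicographic target group, with a
    warning).  Accuracy is the fraction of query cells whose assigned
    reference group matches ``truth``; with ``group_sizes`` omitted,
    groups are weighted equally.
    """
    by_query: dict[str, list[SimilarityRecord]] = {}
    for r in records:
        if r.dataset_b == reference and r.dataset_a != reference:
            by_query.setdefault(r.group_a, []).append(r)
    missing = [g for g in truth if g not in by_query]
    if missing:
        raise ValueError(f"no records for query group(s): {', '.join(missing)}")
    correct = 0.0
    total = 0.0
    for g in truth:
        cands = sorted(by_query[g], key=lambda r: (-r.similarity, r.group_b))
        if len(cands) > 1 and cands[0].similarity == cands[1].similarity:
            warnings.warn(
                f"tied top similarity for query group {g!r}; "
                "assigned lexicographically smallest target"
            )
        w = float(group_sizes[g]) if group_sizes is not None else 1.0
        total += w
        if cands[0].group_b == truth[g]:
            correct += w
    return correct / total
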