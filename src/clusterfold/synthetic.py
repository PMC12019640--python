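"""Seeded negative-binomial single-cell count simulations with planted markers.

Counts are drawn per feature and cell from a negative binomial with
variance mean + dispersion·mean², the standard overdispersed model of
scRNA-seq counts.  Each group owns a disjoint block of marker features
whose mean is multiplied by 2^marker_log2fc inside that group; the marker
assignment is shared across datasets (conserved phenotypes) while the
sampling noise and a per-dataset library-size factor (batch effect) are
independent.  Ground truth — which query group corresponds to which
reference group — is therefore known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Dataset

__all__ = ["SimConfig", "simulate_paired_datasets", "simulate_mixture_query", "write_fixture"]


@dataclass
class SimConfig:
    """Study conditions for a paired-dataset simulation.

    marker_log2fc is the planted effect size in log2 units; base_mean the
    negative-binomial mean of background features (counts per cell);
    dispersion d gives variance m + d·m²; batch_scale multiplies every
    mean of each dataset (library-size batch effect).  mixture_spec, when
    given, lists (component group, proportion) pairs defining the mixed
    query group of :func:`simulate_mixture_query`.
    """

    n_datasets: int = 2
    n_groups: int = 10
    cells_per_group: int = 200
    n_features: int = 2000
    n_markers_per_group: int = 10
    marker_log2fc: float = 3.0
    base_mean: float = 2.0
    dispersion: float = 0.5
    batch_scale: tuple[float, ...] | None = None
    mixture_spec: list[tuple[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_datasets, self.n_groups, self.cells_per_group, self.n_features) < 1:
            raise ValueError("counts parameters must be positive")
        if self.cells_per_group < 2:
            raise ValueError("cells_per_group must be >= 2")
        if self.n_markers_per_group * self.n_groups > self.n_features:
            raise ValueError("not enough features for the marker blocks")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ValueError("base_mean and dispersion must be positive")
        if self.batch_scale is not None and len(self.batch_scale) != self.n_datasets:
            raise ValueError("batch_scale needs one factor per dataset")
        if self.mixture_spec is not None:
            total = sum(p for _, p in self.mixture_spec)
            if abs(total - 1.0) > 1e-9 or any(p <= 0 for _, p in self.mixture_spec):
                raise ValueError("mixture proportions must be positive and sum to 1")

    def group_label(self, g: int) -> str:
        return f"G{g:02d}"

    def marker_features(self, g: int) -> np.ndarray:
        """Feature indices planted as markers of group g (disjoint blocks)."""
        start = g * self.n_markers_per_group
        return np.arange(start, start + self.n_markers_per_group)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, var = mean + d·mean²) via the (n, p) parameterization."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def _feature_base_means(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    # log-normal spread around base_mean, shared across datasets so the
    # underlying expression profile is conserved
    return cfg.base_mean * np.exp(rng.normal(0.0, 0.5, size=cfg.n_features))


def _group_mean_matrix(cfg: SimConfig, base: np.ndarray) -> np.ndarray:
    """Expected mean per feature × group, with marker blocks boosted."""
    means = np.tile(base[:, None], (1, cfg.n_groups))
    boost = 2.0**cfg.marker_log2fc
    for g in range(cfg.n_groups):
        means[cfg.marker_features(g), g] *= boost
    return means


def _sample_dataset(
    cfg: SimConfig,
    name: str,
    group_means: np.ndarray,
    scale: float,
    rng: np.random.Generator,
    groups: Sequence[tuple[str, int, np.ndarray]] | None = None,
) -> Dataset:
    """Draw one dataset; ``groups`` = (label, n_cells, column of group_means)."""
    if groups is None:
        groups = [
            (cfg.group_label(g), cfg.cells_per_group, group_means[:, g])
            for g in range(cfg.n_groups)
        ]
    blocks = []
    cell_ids: list[str] = []
    group_of: dict[str, str] = {}
    cell_counter = 0
    for label, n_cells, mean_vec in groups:
        mean = np.tile(scale * mean_vec[:, None], (1, n_cells))
        blocks.append(_nb_draw(rng, mean, cfg.dispersion))
        for _ in range(n_cells):
            cid = f"{name}_c{cell_counter:05d}"
            cell_ids.append(cid)
            group_of[cid] = label
            cell_counter += 1
    counts = np.concatenate(blocks, axis=1)
    feature_ids = [f"gene{i:05d}" for i in range(cfg.n_features)]
    return Dataset(
        name=name, counts=counts, feature_ids=feature_ids, cell_ids=cell_ids, group_of=group_of
    )


def simulate_paired_datasets(cfg: SimConfig) -> tuple[list[Dataset], dict[str, str]]:
    """Independent datasets with conserved marker structure.

    Returns the datasets plus the ground-truth correspondence (group label
    in any query dataset → matching group label in the reference); with
    shared labels across datasets this is the identity map.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    base = _feature_base_means(cfg, rng)
    group_means = _group_mean_matrix(cfg, base)
    scales = cfg.batch_scale or tuple(1.0 for _ in range(cfg.n_datasets))
    datasets = []
    for d in range(cfg.n_datasets):
        ds_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(d,)))
        datasets.append(
            _sample_dataset(cfg, f"dataset{d}", group_means, scales[d], ds_rng)
        )
    truth = {cfg.group_label(g): cfg.group_label(g) for g in range(cfg.n_groups)}
    return datasets, truth


def simulate_mixture_query(
    cfg: SimConfig,
) -> tuple[Dataset, Dataset, dict[str, float]]:
    """Reference dataset plus a query whose extra group is a cell-type mixture.

    The query contains every pure group (independently sampled) and one
    group ``MIX`` whose cells are drawn from the component groups of
    ``cfg.mixture_spec`` at the given proportions (deterministic rounded
    cell counts).  Returns (reference, query, proportions by component).
    """
    if cfg.mixture_spec is None:
        raise ValueError("mixture_spec required")
    labels = {cfg.group_label(g) for g in range(cfg.n_groups)}
    for comp, _ in cfg.mixture_spec:
        if comp not in labels:
            raise ValueError(f"unknown mixture component {comp!r}")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    base = _feature_base_means(cfg, rng)
    group_means = _group_mean_matrix(cfg, base)
    col = {cfg.group_label(g): g for g in range(cfg.n_groups)}

    ref_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    reference = _sample_dataset(cfg, "reference", group_means, 1.0, ref_rng)

    # mixed group: rounded component cell counts, remainder to the largest
    n_mix = cfg.cells_per_group
    comp_counts = [int(round(p * n_mix)) for _, p in cfg.mixture_spec]
    comp_counts[int(np.argmax(comp_counts))] += n_mix - sum(comp_counts)
    groups = [
        (cfg.group_label(g), cfg.cells_per_group, group_means[:, g])
        for g in range(cfg.n_groups)
    ]
    for (comp, _), n_c in zip(cfg.mixture_spec, comp_counts):
        if n_c > 0:
            groups.append(("MIX", n_c, group_means[:, col[comp]]))
    qry_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    query = _sample_dataset(cfg, "query", group_means, 1.0, qry_rng, groups=groups)
    proportions = {comp: p for comp, p in cfg.mixture_spec}
    return reference, query, proportions


def write_fixture(dataset: Dataset, outdir: str | Path) -> None:
    """Write a dataset as MTX + id files + labels TSV (io-module formats)."""
    import scipy.io
    import scipy.sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), scipy.sparse.coo_matrix(dataset.counts)
    )
    (outdir / "features.tsv").write_text("\n".join(dataset.feature_ids) + "\n")
    (outdir / "cells.tsv").write_text("\n".join(dataset.cell_ids) + "\n")
    lines = ["cell_id\tgroup"] + [f"{c}\t{dataset.group_of[c]}" for c in dataset.cell_ids]
    (outdir / "labels.tsv").write_text("\n".join(lines) + "\n")
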