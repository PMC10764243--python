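"""Synthetic RNA-seq count data with known differential-expression truth.

The generator emulates the standard two-group benchmark design for DE
methods: a fraction ``P_DEG`` of genes are differentially expressed, a
fraction ``P1`` of those are up-regulated in group 1 ("DEG1" pattern; the
rest are up in group 2, "DEG2"), and each DEG's fold change ``FC`` is
split symmetrically around its baseline mean (``sqrt(FC)`` up in one
group, ``sqrt(FC)`` down in the other) so that the ideal cluster center of
a pattern is ``(+-ln sqrt(FC), -+ln sqrt(FC))``.

Per gene, a baseline mean is drawn from a log-normal law (meanlog 4.0,
sdlog 1.5, truncated below at 0.5 by resampling) and an NB dispersion from
Gamma(shape 2, scale 0.15); counts are independent negative binomials per
sample with equal nominal library scale, so realized library sizes differ
only through count noise (and through the DE bias itself when ``P1`` is
far from 0.5 — the effect that stresses CPM normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import CountMatrix, GroupDesign

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_counts",
    "replica_sample_dataset",
    "ideal_center",
]

LABEL_DEG1 = "DEG1"
LABEL_DEG2 = "DEG2"
LABEL_NONDEG = "nonDEG"


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``n_deg1 = round(G * P_DEG * P1)`` genes get the DEG1 pattern,
    ``n_deg2 = round(G * P_DEG * (1 - P1))`` the DEG2 pattern, the rest are
    non-DEG.  ``fc1``/``fc2`` are the fold changes of the two patterns.
    """

    n_genes: int = 10_000
    p_deg: float = 0.25
    p1: float = 0.5
    fc1: float = 4.0
    fc2: float = 4.0
    n: tuple = (3, 3)
    mean_meanlog: float = 4.0
    mean_sdlog: float = 1.5
    mean_floor: float = 0.5
    disp_shape: float = 2.0
    disp_scale: float = 0.15
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_deg <= 1.0:
            raise ValueError("p_deg must be in [0, 1]")
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError("p1 must be in [0, 1]")
        if self.fc1 <= 0 or self.fc2 <= 0:
            raise ValueError("fold changes must be positive")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if len(self.n) != 2 or any(r < 1 for r in self.n):
            raise ValueError("n must give two groups with >= 1 replicate each")

    @property
    def n_deg1(self) -> int:
        return int(round(self.n_genes * self.p_deg * self.p1))

    @property
    def n_deg2(self) -> int:
        return int(round(self.n_genes * self.p_deg * (1.0 - self.p1)))

    @property
    def n_nondeg(self) -> int:
        return self.n_genes - self.n_deg1 - self.n_deg2

    def design(self) -> GroupDesign:
        labels = []
        for i, reps in enumerate(self.n):
            labels.extend([f"G{i + 1}"] * reps)
        return GroupDesign.from_labels(labels)


@dataclass
class SimulationTruth:
    """Per-gene ground-truth pattern labels and applied fold changes."""

    label: np.ndarray  # per-gene DEG1 / DEG2 / nonDEG
    true_fc: np.ndarray

    @property
    def is_deg(self) -> np.ndarray:
        return self.label != LABEL_NONDEG


def ideal_center(fc: float, up_group: int) -> np.ndarray:
    """Noise-free two-group effect vector of a pattern with fold change ``fc``.

    The symmetric fold-change split puts the up group at ``ln sqrt(fc)``
    above the gene's log baseline and the down group the same amount below,
    so the ideal center is ``(ln sqrt(fc), -ln sqrt(fc))`` for a gene up in
    group 1, negated for group 2.
    """
    if fc <= 0:
        raise ValueError("fc must be positive")
    if up_group not in (1, 2):
        raise ValueError("up_group must be 1 or 2")
    half = 0.5 * np.log(fc)
    vec = np.array([half, -half])
    return vec if up_group == 1 else -vec


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB draws with Var = mean + phi * mean**2; Poisson below phi = 1e-8."""
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi < 1e-8
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mean[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def simulate_counts(config: SimulationConfig):
    """Draw one count matrix plus truth labels under ``config``.

    Returns
    -------
    (CountMatrix, SimulationTruth)
        Gene IDs are ``gene_1 .. gene_G`` with DEG1 genes first, then DEG2,
        then non-DEG; sample IDs are ``G1_1 .. G1_n1, G2_1 ..``.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    lam = rng.lognormal(config.mean_meanlog, config.mean_sdlog, size=g)
    low = lam < config.mean_floor
    while low.any():  # truncation by resampling
        lam[low] = rng.lognormal(config.mean_meanlog, config.mean_sdlog, size=low.sum())
        low = lam < config.mean_floor
    phi = rng.gamma(config.disp_shape, config.disp_scale, size=g)

    label = np.array(
        [LABEL_DEG1] * config.n_deg1
        + [LABEL_DEG2] * config.n_deg2
        + [LABEL_NONDEG] * config.n_nondeg
    )
    true_fc = np.ones(g)
    true_fc[label == LABEL_DEG1] = config.fc1
    true_fc[label == LABEL_DEG2] = config.fc2

    # symmetric split: sqrt(FC) up in the favoured group, sqrt(FC) down opposite
    fold = np.ones((g, 2))
    d1 = label == LABEL_DEG1
    d2 = label == LABEL_DEG2
    fold[d1, 0] = np.sqrt(config.fc1)
    fold[d1, 1] = 1.0 / np.sqrt(config.fc1)
    fold[d2, 0] = 1.0 / np.sqrt(config.fc2)
    fold[d2, 1] = np.sqrt(config.fc2)

    n_samples = int(sum(config.n))
    counts = np.empty((g, n_samples), dtype=np.int64)
    sample_ids = []
    col = 0
    for i, reps in enumerate(config.n):
        mean_i = lam * fold[:, i]
        for rep in range(reps):
            counts[:, col] = _draw_nb(rng, mean_i, phi)
            sample_ids.append(f"G{i + 1}_{rep + 1}")
            col += 1

    matrix = CountMatrix(
        gene_ids=[f"gene_{k + 1}" for k in range(g)],
        sample_ids=sample_ids,
        counts=counts,
    )
    return matrix, SimulationTruth(label=label, true_fc=true_fc)


def replica_sample_dataset(seed: int = 1):
    """Regenerate the structure of the 2,000-gene x 11-sample worked dataset.

    360 genes 4-fold up in group A (gene_1..gene_360), 40 genes 9-fold up
    in group B (gene_361..gene_400), 1,600 non-DEG genes; five A samples
    (A1..A5) and six B samples (B1..B6).  Hence P_DEG = 400/2000 = 0.2 and
    P1 = 360/400 = 0.9.

    Returns
    -------
    (CountMatrix, GroupDesign, SimulationTruth)
    """
    config = SimulationConfig(
        n_genes=2000, p_deg=0.2, p1=0.9, fc1=4.0, fc2=9.0, n=(5, 6), seed=seed
    )
    matrix, truth = simulate_counts(config)
    matrix.sample_ids = [f"A{j}" for j in range(1, 6)] + [f"B{j}" for j in range(1, 7)]
    design = GroupDesign.from_labels(["A"] * 5 + ["B"] * 6)
    return matrix, design, truth
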