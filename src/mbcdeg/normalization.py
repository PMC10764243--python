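"""Per-sample normalization factors used as model offsets.

Two library-size normalizers are provided.  ``cpm`` (counts per million,
the default) rescales each sample so its total count is one million:
``factor_j = 1e6 / library_size_j``.  ``upper_quartile`` rescales by the
per-sample 75th percentile of counts over genes with nonzero total count,
with the factors rebalanced to geometric mean 1.  The natural logarithm of
the factor is the additive offset entering the mixture model's mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NormalizationFactors", "cpm_factors", "upper_quartile_factors"]

CPM_SCALE = 1_000_000.0


@dataclass
class NormalizationFactors:
    """Per-sample multiplicative factors and their natural logarithms."""

    method: str
    factor: np.ndarray
    log_factor: np.ndarray

    def __post_init__(self) -> None:
        self.factor = np.asarray(self.factor, dtype=float)
        self.log_factor = np.asarray(self.log_factor, dtype=float)
        if self.factor.shape != self.log_factor.shape:
            raise ValueError("factor and log_factor shapes differ")
        if np.any(self.factor <= 0):
            raise ValueError("normalization factors must be positive")

    @classmethod
    def from_factor(cls, method: str, factor: np.ndarray) -> "NormalizationFactors":
        factor = np.asarray(factor, dtype=float)
        return cls(method=method, factor=factor, log_factor=np.log(factor))

    @classmethod
    def from_log_factor(cls, method: str, log_factor) -> "NormalizationFactors":
        log_factor = np.asarray(log_factor, dtype=float)
        return cls(method=method, factor=np.exp(log_factor), log_factor=log_factor)


def cpm_factors(counts) -> NormalizationFactors:
    """Counts-per-million factors: ``1e6 / library_size`` per sample.

    Raises
    ------
    ValueError
        If any sample has a zero library size.
    """
    lib = counts.library_sizes().astype(float)
    if np.any(lib <= 0):
        bad = counts.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero library size")
    return NormalizationFactors.from_factor("cpm", CPM_SCALE / lib)


def upper_quartile_factors(counts) -> NormalizationFactors:
    """Upper-quartile factors, rescaled to geometric mean 1.

    The 75th percentile is taken per sample over genes whose total count
    across all samples is nonzero, using linear interpolation.  Factors are
    proportional to the reciprocal of the percentile.
    """
    x = counts.counts
    expressed = x.sum(axis=1) > 0
    if not expressed.any():
        raise ValueError("all genes have zero total count")
    uq = np.percentile(x[expressed].astype(float), 75, axis=0)
    if np.any(uq <= 0):
        bad = counts.sample_ids[int(np.argmax(uq <= 0))]
        raise ValueError(f"sample {bad!r} has a zero upper quartile")
    raw = 1.0 / uq
    raw /= np.exp(np.mean(np.log(raw)))
    return NormalizationFactors.from_factor("upper_quartile", raw)
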