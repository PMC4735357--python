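"""Per-scaffold features for binning: logit-GC, FPKM, length weights.

Scaffolds are summarized by two numbers: GC content mapped to the real line
by a logit transform (so Gaussian modeling is appropriate for proportion
data) and FPKM (fragments per kilobase per million mapped fragments), a
proxy for the relative abundance of the source genome. Every downstream
computation weights scaffolds by length, because the features describe the
community at the nucleotide level, not the scaffold level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CountTable, ScaffoldRecord

logger = logging.getLogger("contourbin")

_GC_BASES = frozenset("GC")
_UNAMBIG = frozenset("ACGT")

#: epsilon for the optional log10(FPKM + eps) transform
LOG_FPKM_EPS = 1e-6


def gc_counts(sequence: str) -> tuple[int, int]:
    """Return (#G+#C, #unambiguous A/C/G/T) for a sequence, case-insensitive."""
    s = sequence.upper()
    unambig = sum(s.count(b) for b in _UNAMBIG)
    gc = sum(s.count(b) for b in _GC_BASES)
    return gc, unambig


def gc_content(sequence: str) -> float:
    """GC proportion over unambiguous bases; ambiguity codes are excluded."""
    gc, unambig = gc_counts(sequence)
    if unambig == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T base")
    return gc / unambig


def adjusted_logit_gc(gc_count: int, unambiguous_length: int) -> float:
    """Logit of GC with a half-count correction: p = (g + 0.5)/(L + 1).

    The correction keeps p strictly inside (0, 1) so all-AT and all-GC
    scaffolds stay finite; it converges to the plain logit as L grows.
    """
    if not 0 <= gc_count <= unambiguous_length or unambiguous_length < 1:
        raise ValueError("need 0 <= gc_count <= unambiguous_length >= 1")
    p = (gc_count + 0.5) / (unambiguous_length + 1)
    return float(np.log(p / (1.0 - p)))


def compute_fpkm(counts: CountTable, lengths: Mapping[str, int]) -> dict[str, float]:
    """FPKM_i = c_i * 1e9 / (l_i * T), T = total mapped fragments."""
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be positive to compute FPKM")
    out: dict[str, float] = {}
    for sid, c in counts.entries.items():
        if sid not in lengths:
            raise ValueError(f"no length known for counted scaffold {sid!r}")
        out[sid] = c * 1e9 / (lengths[sid] * counts.total_mapped)
    return out


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Weighted quantile with linear interpolation.

    Plotting positions are p_i = C_{i-1} / (S - w_n) on the value-sorted
    sample (C = cumulative weight, w_n = weight of the largest value), which
    reduces exactly to the Hyndman-Fan type-7 convention when all weights
    are equal.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    csum = np.cumsum(w)
    total = csum[-1]
    denom = total - w[-1]
    if denom <= 0:  # single effective observation
        return float(v[-1])
    p = (csum - w) / denom
    return float(np.interp(q, p, v))


@dataclass
class FeatureTable:
    """Per-scaffold feature vectors, lengths, normalized weights, KDE mask.

    ``kde_mask`` is True for scaffolds used in bandwidth selection, density
    estimation and initialization; coverage outliers are masked out but stay
    in the table (and in the EM) — they are only hidden from the KDE because
    extreme coverage values distort bandwidth selection.
    """

    ids: list[str]
    x1: np.ndarray  # logit GC
    x2: np.ndarray  # FPKM (or log10 FPKM when transformed)
    lengths: np.ndarray
    weights: np.ndarray
    kde_mask: np.ndarray
    fpkm: np.ndarray  # untransformed FPKM, kept for reporting
    log_fpkm: bool = False

    def __post_init__(self) -> None:
        n = len(self.ids)
        for arr in (self.x1, self.x2, self.lengths, self.weights, self.kde_mask):
            if len(arr) != n:
                raise ValueError("feature table arrays must share one length")
        if n and abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @property
    def points(self) -> np.ndarray:
        """N x 2 array of (logit GC, FPKM) feature points."""
        return np.column_stack([self.x1, self.x2])

    def __len__(self) -> int:
        return len(self.ids)


def build_feature_table(
    records: Sequence[ScaffoldRecord],
    counts: CountTable,
    min_length: int = 1000,
    coverage_quantile: float = 0.99,
    log_fpkm: bool = False,
) -> FeatureTable:
    """Assemble the feature table: length filter, features, weights, mask.

    Scaffolds shorter than ``min_length`` are dropped and the length weights
    renormalized over the survivors. Scaffolds whose FPKM strictly exceeds
    the length-weighted ``coverage_quantile`` quantile are masked from the
    KDE stage but retained for EM assignment. Scaffolds missing from the
    count table get count 0 (logged).
    """
    kept = [r for r in records if r.length >= min_length]
    if not kept:
        raise ValueError(f"no scaffold passes the min_length={min_length} filter")
    missing = [r.id for r in kept if r.id not in counts.entries]
    if missing:
        logger.warning(
            "%d scaffolds missing from the count table; assuming 0 fragments "
            "(first: %s)", len(missing), missing[0],
        )
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")

    ids = [r.id for r in kept]
    lengths = np.array([r.length for r in kept], dtype=float)
    weights = lengths / lengths.sum()

    x1 = np.empty(len(kept))
    for i, r in enumerate(kept):
        g, u = gc_counts(r.sequence)
        if u == 0:
            raise ValueError(f"scaffold {r.id!r} has no unambiguous base")
        x1[i] = adjusted_logit_gc(g, u)

    fpkm = np.array(
        [counts.entries.get(r.id, 0) * 1e9 / (r.length * counts.total_mapped) for r in kept]
    )
    cutoff = weighted_quantile(fpkm, weights, coverage_quantile)
    kde_mask = fpkm <= cutoff
    n_masked = int((~kde_mask).sum())
    if n_masked:
        logger.info(
            "masking %d coverage outliers above the %.2f quantile (FPKM > %.4g)",
            n_masked, coverage_quantile, cutoff,
        )

    x2 = np.log10(fpkm + LOG_FPKM_EPS) if log_fpkm else fpkm.copy()
    return FeatureTable(
        ids=ids, x1=x1, x2=x2, lengths=lengths, weights=weights,
        kde_mask=kde_mask, fpkm=fpkm, log_fpkm=log_fpkm,
    )
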