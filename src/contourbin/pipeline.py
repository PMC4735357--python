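"""End-to-end orchestration: features -> KDE init -> EM -> bins -> summary.

Given an assembly FASTA and a fragment-count table (or SAM alignments), the
pipeline computes per-scaffold (logit GC, FPKM) features, estimates their
length-weighted density, seeds a Gaussian mixture from the density contours
and assigns every scaffold to a genome bin (or to the noise set), reporting
per-bin statistics: contig count, total length, length-weighted GC and
relative abundance (percentage of mapped fragments in the bin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import density as _density
from . import features as _features
from . import io as _io
from . import mixture as _mixture
from .io import NOISE, CountTable, ScaffoldRecord

logger = logging.getLogger("contourbin")


@dataclass
class BinningConfig:
    """Configuration for one binning run; mirrors the CLI flags."""

    assembly: str
    counts: str | None = None
    sam: str | None = None
    out: str | None = None
    level: float | None = None
    min_length: int = 1000
    quantile: float = 0.99
    log_fpkm: bool = False
    min_posterior: float = 0.5
    tol: float = 1e-8
    max_iter: int = 500
    gridsize: tuple[int, int] = (256, 256)
    seed: int | None = None  # echoed in provenance; the binning path is deterministic


_CONFIG_BOOLS = {"log_fpkm"}
_CONFIG_INTS = {"min_length", "max_iter", "seed"}
_CONFIG_FLOATS = {"level", "quantile", "min_posterior", "tol"}


def read_config(path: str) -> BinningConfig:
    """Parse a flat ``key = value`` text config into a :class:`BinningConfig`."""
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key in _CONFIG_BOOLS:
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key in _CONFIG_INTS:
                kwargs[key] = int(value)
            elif key in _CONFIG_FLOATS:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return BinningConfig(**kwargs)


@dataclass
class BinSummary:
    group: object
    n_contigs: int
    length_bp: int
    gc_percent: float
    relative_abundance_percent: float


@dataclass
class BinSet:
    """Final scaffold -> bin assignment with per-bin summary statistics."""

    assignments: dict[str, object]
    bins: list[BinSummary]
    provenance: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return sum(1 for b in self.bins if b.group != "unbinned" and b.n_contigs > 0)


def relative_abundance(
    counts: CountTable, assignments: Mapping[str, object]
) -> dict[object, float]:
    """Percentage of all mapped fragments carried by each bin (and noise)."""
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    acc: dict[object, int] = {}
    for sid, label in assignments.items():
        acc[label] = acc.get(label, 0) + counts.entries.get(sid, 0)
    return {label: 100.0 * c / counts.total_mapped for label, c in acc.items()}


def bin_statistics(
    records: Sequence[ScaffoldRecord],
    assignments: Mapping[str, object],
    counts: CountTable,
) -> list[BinSummary]:
    """Per-bin Table-1-style statistics, plus a trailing 'unbinned' row.

    GC is the length-weighted mean over member scaffolds, in percent.
    """
    by_id = {r.id: r for r in records}
    members: dict[object, list[ScaffoldRecord]] = {}
    for sid, label in assignments.items():
        members.setdefault(label, []).append(by_id[sid])
    abundance = relative_abundance(counts, assignments)

    def _row(group, recs: list[ScaffoldRecord]) -> BinSummary:
        total_bp = sum(r.length for r in recs)
        if total_bp:
            gc_bp = 0.0
            for r in recs:
                g, u = _features.gc_counts(r.sequence)
                gc_bp += (g / u) * r.length if u else 0.0
            gc_pct = 100.0 * gc_bp / total_bp
        else:
            gc_pct = float("nan")
        return BinSummary(
            group=group,
            n_contigs=len(recs),
            length_bp=total_bp,
            gc_percent=gc_pct,
            relative_abundance_percent=abundance.get(group, 0.0),
        )

    labels = sorted(
        (l for l in members if l != NOISE),
        key=lambda l: (0, l, "") if isinstance(l, int) else (1, 0, str(l)),
    )
    rows = [_row(l, members[l]) for l in labels]
    noise_row = _row("unbinned", members.get(NOISE, []))
    noise_row.relative_abundance_percent = abundance.get(NOISE, 0.0)
    rows.append(noise_row)
    return rows


def run_binning(config: BinningConfig) -> BinSet:
    """Execute the full binning pipeline and (optionally) write outputs.

    Deterministic given the configuration: the binning path draws no random
    numbers. Every stage is logged with its input/output sizes; errors are
    re-raised with the failing stage named.
    """
    stage = "read_assembly"
    try:
        records = _io.read_assembly(config.assembly)
        logger.info("read_assembly: %d scaffolds", len(records))

        stage = "read_counts"
        if config.counts is not None:
            counts = _io.read_counts(config.counts)
        elif config.sam is not None:
            counts = _io.count_fragments_from_alignments(config.sam)
        else:
            raise ValueError("config must name a counts TSV or a SAM file")
        logger.info("read_counts: %d entries, total_mapped=%d",
                    len(counts.entries), counts.total_mapped)

        stage = "build_feature_table"
        table = _features.build_feature_table(
            records, counts,
            min_length=config.min_length,
            coverage_quantile=config.quantile,
            log_fpkm=config.log_fpkm,
        )
        logger.info("build_feature_table: %d scaffolds retained, %d masked",
                    len(table), int((~table.kde_mask).sum()))

        stage = "binned_kde2d"
        grid = _density.binned_kde2d(table, gridsize=config.gridsize)
        logger.info("binned_kde2d: bandwidths h1=%.4g h2=%.4g", *grid.bandwidths)

        stage = "choose_level"
        level = config.level if config.level is not None else _density.default_level(grid)
        logger.info("contour level: %.6g", level)

        stage = "initial_binning"
        init = _density.initial_binning(table, grid, level)
        logger.info("initial_binning: %d groups", init.n_groups)

        stage = "fit_em"
        fitted = _mixture.fit_em(table, init, tol=config.tol, max_iter=config.max_iter)
        logger.info("fit_em: G=%d, %d iterations, converged=%s",
                    fitted.params.G, len(fitted.loglik_trace), fitted.converged)

        stage = "hard_assign"
        assignments = _mixture.hard_assign(fitted, table.ids, config.min_posterior)

        stage = "bin_statistics"
        bins = bin_statistics(
            [r for r in records if r.id in assignments], assignments, counts
        )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    provenance = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "chosen_level": level,
        "n_initial_groups": init.n_groups,
        "bandwidths": grid.bandwidths,
        "loglik_trace_tail": fitted.loglik_trace[-5:],
        "converged": fitted.converged,
        "seed": config.seed,
    }
    binset = BinSet(assignments=assignments, bins=bins, provenance=provenance)

    if config.out is not None:
        outdir = Path(config.out)
        outdir.mkdir(parents=True, exist_ok=True)
        kept = [r for r in records if r.id in assignments]
        _io.write_bins(kept, assignments, outdir)
        _io.write_summary(binset, outdir / "summary.tsv")
        with open(outdir / "provenance.txt", "w") as fh:
            for k, v in provenance.items():
                fh.write(f"{k} = {v}\n")
    return binset
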