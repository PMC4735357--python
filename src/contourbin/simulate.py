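"""Seeded synthetic communities for validating the binner.

Generates multi-species communities with exactly the statistical structure
the binning model assumes: each species' genome is an i.i.d. base sequence
at a target GC, fragmented into scaffolds with lognormal lengths, and each
scaffold receives a Poisson fragment count whose expectation is
proportional to species abundance times scaffold length (so scaffolds of
one species share a common expected FPKM). Ground truth is kept so binning
quality can be scored by length-weighted accuracy.

Two named presets ship with the generator: ``taihu9`` mirrors the GC and
relative-abundance structure of a nine-member Microcystis-colony community,
and ``wu10`` is a ten-species benchmark with an abundance gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import NOISE, CountTable, ScaffoldRecord

logger = logging.getLogger("contourbin")


@dataclass(frozen=True)
class SpeciesSpec:
    """One community member: GC target, genome size, relative abundance."""

    name: str
    gc: float
    genome_length: int
    abundance: float
    scaffold_meanlog: float = math.log(8000.0)
    scaffold_sdlog: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must be in (0,1), got {self.gc}")
        if self.genome_length < 1 or self.abundance <= 0:
            raise ValueError("genome_length >= 1 and abundance > 0 required")


@dataclass
class SyntheticCommunity:
    records: list[ScaffoldRecord]
    counts: CountTable
    truth: dict[str, str]  # scaffold id -> species name
    specs: list[SpeciesSpec]
    seed: int

    def species_length_shares(self, min_length: int = 0) -> dict[str, float]:
        """Fraction of total scaffold bp per species (for comparing with tau)."""
        acc: dict[str, float] = {s.name: 0.0 for s in self.specs}
        total = 0
        for r in self.records:
            if r.length >= min_length:
                acc[self.truth[r.id]] += r.length
                total += r.length
        return {k: v / total for k, v in acc.items()}


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome(gc: float, length: int, rng: np.random.Generator | int) -> str:
    """I.i.d. genome at a GC target: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be strictly inside (0,1), got {gc}")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def fragment_genome(
    sequence: str,
    meanlog: float,
    sdlog: float,
    min_length: int,
    rng: np.random.Generator | int,
    id_prefix: str = "scf",
) -> list[ScaffoldRecord]:
    """Cut a genome into contiguous scaffolds with truncated-lognormal lengths.

    Fragment lengths are lognormal(meanlog, sdlog) clipped to
    [min_length, remaining bp]; a trailing remainder shorter than
    min_length is appended to the previous fragment, so the fragments
    partition the genome exactly.
    """
    L = len(sequence)
    if L < min_length:
        raise ValueError("genome shorter than min_length")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    cuts: list[int] = []
    pos = 0
    while pos < L:
        frag = int(round(rng.lognormal(meanlog, sdlog)))
        frag = max(frag, min_length)
        frag = min(frag, L - pos)
        if L - pos - frag < min_length:
            frag = L - pos  # absorb a too-short remainder
        cuts.append(frag)
        pos += frag
    records = []
    pos = 0
    for j, frag in enumerate(cuts, start=1):
        records.append(ScaffoldRecord(f"{id_prefix}_{j}", sequence[pos : pos + frag]))
        pos += frag
    return records


def simulate_counts(
    records: list[ScaffoldRecord],
    truth: dict[str, str],
    specs: list[SpeciesSpec],
    total_fragments: int,
    rng: np.random.Generator | int,
    overdispersion: float = 0.0,
) -> CountTable:
    """Poisson fragment counts with E[c_i] = T * a_s * l_i / sum_j a_s(j) l_j.

    The expectation makes all scaffolds of one species share one expected
    FPKM. ``overdispersion`` > 0 switches to a gamma-Poisson (negative
    binomial) draw with that squared coefficient of extra variation.
    """
    if total_fragments < 1:
        raise ValueError("total_fragments must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    abund = {s.name: s.abundance for s in specs}
    z = sum(abund.values())
    abund = {k: v / z for k, v in abund.items()}
    al = np.array([abund[truth[r.id]] * r.length for r in records])
    expected = total_fragments * al / al.sum()
    if overdispersion > 0:
        lam = expected * rng.gamma(1.0 / overdispersion, overdispersion, size=len(records))
    else:
        lam = expected
    counts = rng.poisson(lam)
    entries = {r.id: int(c) for r, c in zip(records, counts)}
    return CountTable(entries=entries, total_mapped=int(counts.sum()))


#: nine species mirroring the GC/abundance structure of a Microcystis-colony
#: community (GC percent, relative abundance percent, renormalized)
TAIHU9 = [
    ("Flavobacterium_like", 33.95, 0.5),
    ("Limnobacter_like_a", 53.05, 0.5),
    ("Rhizobium_like", 64.26, 1.8),
    ("Limnobacter_like_b", 52.26, 4.4),
    ("Methylobacterium_like", 68.5, 2.3),
    ("Agrobacterium_like", 61.67, 4.9),
    ("Lacibacter_like", 41.25, 14.8),
    ("Pseudomonas_like", 64.34, 6.4),
    ("Microcystis_like", 43.06, 31.6),
]

#: ten-species benchmark: evenly spread GC with a geometric abundance
#: gradient, interleaved so GC neighbors differ >=2x in expected coverage
_WU10_GC = [30.0, 34.5, 39.0, 43.5, 48.0, 52.5, 57.0, 61.5, 66.0, 70.5]
_WU10_ABUND_RANK = [0, 5, 1, 6, 2, 7, 3, 8, 4, 9]
WU10 = [
    (f"species_{i+1:02d}", gc, 2.0 * 1.32**_WU10_ABUND_RANK[i])
    for i, gc in enumerate(_WU10_GC)
]


def preset_specs(name: str, rng: np.random.Generator | int | None = None) -> list[SpeciesSpec]:
    """Species tables for the named preset ('taihu9' or 'wu10').

    Genome lengths are drawn uniformly in 0.5-1 Mb from ``rng`` (defaults
    to a fixed draw so the preset is stable without a seed).
    """
    tables = {"taihu9": TAIHU9, "wu10": WU10}
    if name not in tables:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(tables)}")
    rng = np.random.default_rng(0 if rng is None else rng) if not isinstance(
        rng, np.random.Generator
    ) else rng
    specs = []
    for sp_name, gc_pct, ab_pct in tables[name]:
        glen = int(rng.integers(500_000, 1_000_001))
        specs.append(SpeciesSpec(sp_name, gc_pct / 100.0, glen, ab_pct))
    return specs


def simulate_community(
    specs: list[SpeciesSpec],
    total_fragments: int,
    seed: int,
    min_scaffold_length: int = 1000,
) -> SyntheticCommunity:
    """Compose genome + fragmentation + count simulation for a community.

    Warns when two species are poorly separated in the feature space
    (|logit GC| difference < 0.3 and expected-FPKM ratio < 2).
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 species")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")

    z = sum(s.abundance for s in specs)
    al_total = sum((s.abundance / z) * s.genome_length for s in specs)
    exp_fpkm = {s.name: 1e9 * (s.abundance / z) / al_total for s in specs}
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            dlogit = abs(math.log(a.gc / (1 - a.gc)) - math.log(b.gc / (1 - b.gc)))
            ratio = max(exp_fpkm[a.name], exp_fpkm[b.name]) / min(
                exp_fpkm[a.name], exp_fpkm[b.name]
            )
            if dlogit < 0.3 and ratio < 2.0:
                logger.warning(
                    "species %s and %s are poorly separated "
                    "(|dlogit GC|=%.3f, FPKM ratio=%.2f)",
                    a.name, b.name, dlogit, ratio,
                )

    root = np.random.default_rng(seed)
    child_seeds = root.spawn(len(specs) + 1)
    records: list[ScaffoldRecord] = []
    truth: dict[str, str] = {}
    for spec, child in zip(specs, child_seeds):
        genome = simulate_genome(spec.gc, spec.genome_length, child)
        frags = fragment_genome(
            genome, spec.scaffold_meanlog, spec.scaffold_sdlog,
            min_scaffold_length, child, id_prefix=spec.name,
        )
        records.extend(frags)
        for r in frags:
            truth[r.id] = spec.name
    counts = simulate_counts(records, truth, specs, total_fragments, child_seeds[-1])
    return SyntheticCommunity(
        records=records, counts=counts, truth=truth, specs=list(specs), seed=seed
    )


def evaluate_assignment(
    truth: dict[str, str],
    predicted: dict[str, object],
    lengths: dict[str, int],
) -> dict:
    """Score a binning against ground truth, weighting scaffolds by length.

    Bins are matched to species greedily by descending overlapping bp
    (unmatched bins score 0 precision). ``weighted_accuracy`` is correctly
    assigned bp over all bp placed in non-noise bins; noise-assigned
    scaffolds are excluded from accuracy but reported as the unbinned
    fraction. All-noise predictions score accuracy 0 with unbinned 1.0.
    """
    ids = sorted(truth)
    binned = [i for i in ids if predicted.get(i, NOISE) != NOISE]
    total_bp = sum(lengths[i] for i in ids)
    unbinned_bp = total_bp - sum(lengths[i] for i in binned)

    overlap: dict[tuple[object, str], int] = {}
    bin_bp: dict[object, int] = {}
    for i in binned:
        b, s = predicted[i], truth[i]
        overlap[(b, s)] = overlap.get((b, s), 0) + lengths[i]
        bin_bp[b] = bin_bp.get(b, 0) + lengths[i]
    species_bp: dict[str, int] = {}
    for i in binned:
        species_bp[truth[i]] = species_bp.get(truth[i], 0) + lengths[i]

    # greedy 1-1 matching by descending overlap
    pairs = sorted(overlap.items(), key=lambda kv: (-kv[1], str(kv[0])))
    bin_to_species: dict[object, str] = {}
    used_species: set[str] = set()
    for (b, s), _ in pairs:
        if b in bin_to_species or s in used_species:
            continue
        bin_to_species[b] = s
        used_species.add(s)

    correct_bp = sum(overlap.get((b, s), 0) for b, s in bin_to_species.items())
    precision = {
        b: overlap.get((b, bin_to_species[b]), 0) / bin_bp[b]
        if b in bin_to_species else 0.0
        for b in bin_bp
    }
    recall = {
        s: overlap.get((b, s), 0) / species_bp[s]
        for b, s in bin_to_species.items() if s in species_bp
    }
    assigned_bp = sum(bin_bp.values())
    return {
        "weighted_accuracy": correct_bp / assigned_bp if assigned_bp else 0.0,
        "precision": precision,
        "recall": recall,
        "n_bins": len(bin_bp),
        "unbinned_fraction": unbinned_bp / total_bp if total_bp else 0.0,
        "bin_to_species": bin_to_species,
    }


def write_community(community: SyntheticCommunity, outdir) -> None:
    """Write assembly FASTA, counts TSV, truth TSV and a spec echo."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "assembly.fasta", "w") as fh:
        for r in community.records:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, 80):
                fh.write(r.sequence[i : i + 80] + "\n")
    with open(outdir / "counts.tsv", "w") as fh:
        fh.write(f"#total_mapped={community.counts.total_mapped}\n")
        fh.write("scaffold_id\tfragments\n")
        for r in community.records:
            fh.write(f"{r.id}\t{community.counts.entries.get(r.id, 0)}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("scaffold_id\tspecies\n")
        for r in community.records:
            fh.write(f"{r.id}\t{community.truth[r.id]}\n")
    with open(outdir / "spec.tsv", "w") as fh:
        fh.write("name\tgc\tgenome_length\tabundance\n")
        for s in community.specs:
            fh.write(f"{s.name}\t{s.gc}\t{s.genome_length}\t{s.abundance}\n")
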