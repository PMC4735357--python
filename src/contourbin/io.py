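"""Reading and writing the formats the binner touches.

Assemblies come in as FASTA, per-scaffold fragment counts as a two-column
TSV (or are counted from SAM-format alignments), and results go out as one
FASTA per bin plus a per-bin summary TSV.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("contourbin")

#: sentinel bin label for scaffolds the model could not assign
NOISE = "noise"

FASTA_LINE_WIDTH = 80


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembled scaffold: unique id, upper-case sequence, length in bp."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid scaffold id {self.id!r}")
        if not self.sequence:
            raise ValueError(f"scaffold {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CountTable:
    """Mapped-fragment counts per scaffold.

    ``total_mapped`` may exceed the sum of the entries: fragments mapped to
    sequences outside the assembly still count toward the normalizing total.
    """

    entries: dict[str, int] = field(default_factory=dict)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        for sid, c in self.entries.items():
            if c < 0:
                raise ValueError(f"negative count for {sid!r}")
        if self.total_mapped < sum(self.entries.values()):
            raise ValueError("total_mapped smaller than the sum of counts")


def read_assembly(path: str | os.PathLike) -> list[ScaffoldRecord]:
    """Read an assembly FASTA into :class:`ScaffoldRecord` objects.

    Ids are the first whitespace-delimited token of the header, sequences
    are upper-cased and wrapped lines concatenated. Duplicate ids and empty
    sequences are errors.
    """
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"scaffold {rec.id!r} has an empty sequence")
        records.append(ScaffoldRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_counts(path: str | os.PathLike) -> CountTable:
    """Read a fragment-count TSV (``scaffold_id<TAB>fragments``).

    An optional comment line ``#total_mapped=<int>`` overrides the default
    total (the sum of the counts). Extra columns are ignored with a warning.
    """
    entries: dict[str, int] = {}
    total_override: int | None = None
    warned_extra = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("total_mapped="):
                    total_override = int(body.split("=", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0] == "scaffold_id":  # header row
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if len(fields) > 2 and not warned_extra:
                logger.warning("%s:%d: ignoring extra columns", path, lineno)
                warned_extra = True
            sid = fields[0]
            try:
                count = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer count {fields[1]!r}"
                ) from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            entries[sid] = entries.get(sid, 0) + count
    total = sum(entries.values()) if total_override is None else total_override
    return CountTable(entries=entries, total_mapped=total)


def count_fragments_from_alignments(path: str | os.PathLike) -> CountTable:
    """Count mapped fragments per reference from a SAM-format text file.

    Only primary, mapped records are counted (unmapped, secondary and
    supplementary records are skipped). Paired libraries are counted in
    fragments, not reads: only the first-in-pair record of a pair
    contributes. Reference names must appear in the ``@SQ`` header.
    """
    entries: dict[str, int] = {}
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
            refs = set(sam.references)
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.is_paired and not aln.is_read1:
                    continue
                ref = aln.reference_name
                if ref not in refs:
                    raise ValueError(
                        f"{path}: reference {ref!r} not declared in @SQ header"
                    )
                entries[ref] = entries.get(ref, 0) + 1
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed SAM file {path}: {exc}") from exc
    total = sum(entries.values())
    return CountTable(entries=entries, total_mapped=total)


def _wrap(seq: str, width: int = FASTA_LINE_WIDTH) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_bins(
    records: Sequence[ScaffoldRecord],
    assignment: Mapping[str, object],
    outdir: str | os.PathLike,
) -> list[dict]:
    """Write one FASTA per bin (``bin_<k>.fasta``) plus ``unbinned.fasta``.

    Returns a manifest: one dict per file with its scaffold count and bp.
    Scaffolds absent from ``assignment`` go to the unbinned file.
    """
    by_id = {r.id: r for r in records}
    unknown = [sid for sid in assignment if sid not in by_id]
    if unknown:
        raise ValueError(f"assignment references unknown scaffold id {unknown[0]!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    bins: dict[object, list[ScaffoldRecord]] = {}
    unbinned: list[ScaffoldRecord] = []
    for rec in records:
        label = assignment.get(rec.id, NOISE)
        if label == NOISE or label is None or label == 0:
            unbinned.append(rec)
        else:
            bins.setdefault(label, []).append(rec)

    manifest: list[dict] = []

    def _emit(fname: str, recs: list[ScaffoldRecord]) -> None:
        fpath = outdir / fname
        with open(fpath, "w") as fh:
            for r in recs:
                fh.write(f">{r.id}\n{_wrap(r.sequence)}\n")
        manifest.append(
            {"file": str(fpath), "n_scaffolds": len(recs), "total_bp": sum(r.length for r in recs)}
        )

    for label in sorted(
        bins, key=lambda l: (0, l, "") if isinstance(l, int) else (1, 0, str(l))
    ):
        _emit(f"bin_{label}.fasta", bins[label])
    _emit("unbinned.fasta", unbinned)
    return manifest


def write_summary(binset, path: str | os.PathLike) -> None:
    """Write the per-bin summary TSV (Table-1-style statistics).

    Columns: group, n_contigs, length_bp, gc_percent (length-weighted, 2
    decimals; blank for an empty bin), relative_abundance_percent.
    """
    with open(path, "w") as fh:
        fh.write("group\tn_contigs\tlength_bp\tgc_percent\trelative_abundance_percent\n")
        for b in binset.bins:
            gc = "" if b.n_contigs == 0 else f"{b.gc_percent:.2f}"
            fh.write(
                f"{b.group}\t{b.n_contigs}\t{b.length_bp}\t{gc}\t"
                f"{b.relative_abundance_percent:.2f}\n"
            )
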