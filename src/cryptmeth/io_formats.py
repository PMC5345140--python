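"""Readers and writers for every external representation the pipeline touches.

All internal coordinates are 0-based half-open. Conversions to 1-based
conventions (GFF3) happen only at the I/O boundary, so that converting in and
out of GFF3 twice is the identity.

Formats
-------
* Probe table: TSV with header ``probe_id promoter_id chrom start end <sample...>``,
  one row per tiling probe, one column of log2(MeDIP/Input) per sample.
* Gene models: BED12 or GFF3 (auto-detected from the file extension).
* ChIP peaks / DMEPs: BED6 with an optional 7th column giving the summit as an
  offset from the interval start.
* Promoter sequences: FASTA, upper-cased on read; only A/C/G/T/N accepted.
* Group assignment and parameters: YAML.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProbeTable",
    "GeneModel",
    "ChIPPeak",
    "FormatError",
    "ValidationError",
    "read_probe_table",
    "write_probe_table",
    "read_gene_models",
    "write_gene_models",
    "read_peaks_bed",
    "write_peaks_bed",
    "write_dmeps_bed",
    "read_fasta",
    "write_fasta",
    "read_group_assignment",
    "write_group_assignment",
]

PROBE_META_COLUMNS = ["probe_id", "promoter_id", "chrom", "start", "end"]

GROUPS = ("control", "case")

_ALLOWED_BASES = set("ACGTN")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------


@dataclass
class ProbeTable:
    """Probe-level two-channel enrichment values for a two-group design.

    ``frame`` holds one row per probe: the five metadata columns of
    :data:`PROBE_META_COLUMNS` plus one float column of log2(MeDIP/Input) per
    sample.  ``groups`` maps ``"control"`` and ``"case"`` to the sample
    columns belonging to each group.
    """

    frame: pd.DataFrame
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def samples(self) -> list[str]:
        return list(self.groups["control"]) + list(self.groups["case"])

    @property
    def n_probes(self) -> int:
        return len(self.frame)

    def group_columns(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
        return list(self.groups[group])

    def values(self, samples: Sequence[str] | None = None) -> np.ndarray:
        cols = list(samples) if samples is not None else self.samples
        return self.frame[cols].to_numpy(dtype=float)

    def swap_groups(self) -> "ProbeTable":
        """Return a view of the table with the two group labels exchanged."""
        return ProbeTable(
            self.frame,
            {"control": list(self.groups["case"]), "case": list(self.groups["control"])},
        )

    def validate(self) -> None:
        if sorted(self.groups) != sorted(GROUPS):
            raise ValidationError(
                f"groups must be exactly {GROUPS}, got {sorted(self.groups)}"
            )
        for g in GROUPS:
            if not self.groups[g]:
                raise ValidationError(f"group {g!r} has no samples")
        overlap = set(self.groups["control"]) & set(self.groups["case"])
        if overlap:
            raise ValidationError(f"samples assigned to both groups: {sorted(overlap)}")
        missing = [s for s in self.samples if s not in self.frame.columns]
        if missing:
            raise FormatError(f"probe table is missing sample column(s): {missing}")
        for col in PROBE_META_COLUMNS:
            if col not in self.frame.columns:
                raise FormatError(f"probe table is missing column {col!r}")
        if self.frame[self.samples].isna().any().any():
            raise ValidationError("probe table has missing log2 values")
        starts = self.frame["start"].to_numpy()
        ends = self.frame["end"].to_numpy()
        if not (starts < ends).all():
            raise ValidationError("probe intervals must satisfy start < end")
        # promoters: contiguous runs, one chromosome, sorted non-overlapping probes
        promoter = self.frame["promoter_id"].to_numpy()
        if len(promoter):
            change = np.flatnonzero(promoter[1:] != promoter[:-1]) + 1
            seen_ids = promoter[np.concatenate(([0], change))]
            if len(set(seen_ids)) != len(seen_ids):
                raise ValidationError("probe rows of one promoter must be contiguous")
            same = promoter[1:] == promoter[:-1]
            chroms = self.frame["chrom"].to_numpy()
            if (same & (chroms[1:] != chroms[:-1])).any():
                raise ValidationError("all probes of one promoter must share a chromosome")
            if (same & (starts[1:] < ends[:-1])).any():
                raise ValidationError(
                    "probes within a promoter must be sorted and non-overlapping"
                )


def read_probe_table(path: str | os.PathLike, group_assignment: Mapping[str, str]) -> ProbeTable:
    """Read a probe-level TSV, assigning samples to groups.

    ``group_assignment`` maps each sample name to ``"control"`` or ``"case"``.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sample, group in group_assignment.items():
        if group not in GROUPS:
            raise FormatError(
                f"sample {sample!r} assigned to unknown group {group!r}"
            )
        if sample not in frame.columns:
            raise FormatError(f"probe table is missing sample column(s): ['{sample}']")
        groups[group].append(sample)
    frame = frame.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return ProbeTable(frame, groups)


def write_probe_table(table: ProbeTable, path: str | os.PathLike) -> None:
    out = table.frame[PROBE_META_COLUMNS + table.samples]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_group_assignment(path: str | os.PathLike) -> dict[str, str]:
    """Read a YAML mapping sample -> group (or group -> [samples])."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError("group assignment YAML must be a mapping")
    if set(raw) <= set(GROUPS):
        flat: dict[str, str] = {}
        for group, samples in raw.items():
            for s in samples:
                flat[str(s)] = group
        return flat
    return {str(k): str(v) for k, v in raw.items()}


def write_group_assignment(assignment: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(assignment), fh)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand-aware TSS and exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.gene_start <= self.tss < self.gene_end:
            raise ValidationError(
                f"{self.gene_id}: TSS {self.tss} outside gene body "
                f"[{self.gene_start},{self.gene_end})"
            )
        prev_end = None
        for start, end in self.exons:
            if start < self.gene_start or end > self.gene_end:
                raise ValidationError(f"{self.gene_id}: exon ({start},{end}) outside gene body")
            if start >= end:
                raise ValidationError(f"{self.gene_id}: empty exon ({start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"{self.gene_id}: exons must be sorted, non-overlapping")
            prev_end = end


def _tss_for(strand: str, start: int, end: int) -> int:
    return start if strand == "+" else end - 1


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"BED12 line has {len(f)} fields: {line[:80]!r}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"BED12 block count mismatch for {name!r}")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tss=_tss_for(strand, start, end),
                    gene_start=start,
                    gene_end=end,
                    exons=exons,
                )
            )
    return models


def _read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        start = gene.start - 1  # GFF3 is 1-based inclusive
        end = gene.end
        exons = tuple(
            sorted((ex.start - 1, ex.end) for ex in db.children(gene, featuretype="exon"))
        )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=_tss_for(gene.strand, start, end),
                gene_start=start,
                gene_end=end,
                exons=exons,
            )
        )
    return models


def read_gene_models(path: str | os.PathLike, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3, auto-detecting from the extension."""
    if dialect is None:
        ext = os.path.splitext(str(path))[1].lower()
        if ext in (".bed", ".bed12"):
            dialect = "bed12"
        elif ext in (".gff", ".gff3"):
            dialect = "gff3"
        else:
            raise FormatError(f"cannot infer gene-model dialect from extension {ext!r}")
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise FormatError(f"unknown gene-model dialect {dialect!r}")


def write_gene_models(models: Iterable[GeneModel], path: str | os.PathLike,
                      dialect: str = "bed12") -> None:
    models = list(models)
    with open(path, "w") as fh:
        if dialect == "bed12":
            for m in models:
                exons = m.exons or ((m.gene_start, m.gene_end),)
                sizes = ",".join(str(e - s) for s, e in exons) + ","
                offsets = ",".join(str(s - m.gene_start) for s, e in exons) + ","
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            m.chrom, m.gene_start, m.gene_end, m.gene_id, 0, m.strand,
                            m.gene_start, m.gene_end, "0,0,0", len(exons), sizes, offsets,
                        )
                    )
                    + "\n"
                )
        elif dialect == "gff3":
            fh.write("##gff-version 3\n")
            for m in models:
                fh.write(
                    f"{m.chrom}\tcryptmeth\tgene\t{m.gene_start + 1}\t{m.gene_end}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}\n"
                )
                for i, (s, e) in enumerate(m.exons, start=1):
                    fh.write(
                        f"{m.chrom}\tcryptmeth\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                    )
        else:
            raise FormatError(f"unknown gene-model dialect {dialect!r}")


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChIPPeak:
    """A called binding-site interval with its summit (absolute bp)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    group_label: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValidationError(
                f"summit {self.summit} outside interval [{self.start},{self.end})"
            )


def read_peaks_bed(path: str | os.PathLike, group_label: str = "") -> list[ChIPPeak]:
    """Read peaks from BED6(+summit).

    Column 7, when present, is the summit offset from the interval start
    (the MACS ``.xls``/narrowPeak convention); otherwise the summit defaults
    to the interval midpoint.
    """
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            if len(f) > 6 and f[6] not in (".", ""):
                summit = start + int(f[6])
            else:
                summit = (start + end) // 2
            peaks.append(
                ChIPPeak(chrom=chrom, start=start, end=end, summit=summit,
                         score=score, group_label=group_label or name)
            )
    return peaks


def write_peaks_bed(peaks: Iterable[ChIPPeak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.group_label or f'peak{i + 1}'}\t"
                f"{p.score:g}\t.\t{p.summit - p.start}\n"
            )


def write_dmeps_bed(peaks, path: str | os.PathLike) -> None:
    """Write called differential peaks as BED6; score = |M'| x 1000 capped at 1000."""
    with open(path, "w") as fh:
        for p in peaks:
            chrom, start, end = p.span
            score = min(1000, int(round(abs(p.m_prime) * 1000)))
            fh.write(f"{chrom}\t{start}\t{end}\t{p.promoter_id}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read sequences into a dict id -> upper-cased string (A/C/G/T/N only)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED_BASES
        if bad:
            raise ValidationError(
                f"sequence {rec.id!r} contains disallowed characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
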