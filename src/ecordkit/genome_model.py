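"""Core genomic record types, coordinate conventions, and format I/O.

All coordinates are held internally as 0-based, half-open intervals (the BED
convention).  Conversion to/from 1-based inclusive coordinates happens only at
the GTF boundary.  Binned signal is held in :class:`BinnedTrack`, where a
missing bin is ``NaN`` and is distinct from an observed value of zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line."""


class ValidationError(ValueError):
    """Records parsed but violate a contract (coordinates, uniqueness...)."""


# --------------------------------------------------------------------------
# record types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A gene's genomic interval, 0-based half-open.

    ``tss`` is the strand-aware transcription start: ``start`` on the plus
    (or unknown) strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) <= start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.end - 1 if self.strand == "-" else self.start


class GeneClass:
    """Expression classes derived from a differential-expression test."""

    DEG_UP = "DEG_UP"
    DEG_DOWN = "DEG_DOWN"
    BREAKER_UP = "BREAKER_UP"
    BREAKER_DOWN = "BREAKER_DOWN"
    STATIC = "STATIC"
    UNEXPRESSED = "UNEXPRESSED"

    ALL = (DEG_UP, DEG_DOWN, BREAKER_UP, BREAKER_DOWN, STATIC, UNEXPRESSED)


def classify_gene(log2fc: float, padj: float | None,
                  alpha: float = 0.05, lfc_threshold: float = 1.0) -> str:
    """Classify a gene from its effect size and adjusted p-value.

    A differential gene (DEG) is significant (padj < alpha) with
    ``|log2fc| >= lfc_threshold``; a "breaker" is significant but below the
    fold-change cutoff; a static gene is expressed but not significant; a
    gene with a missing padj (removed by independent filtering upstream) is
    unexpressed.  The classes partition all inputs.
    """
    if padj is None or (isinstance(padj, float) and np.isnan(padj)):
        return GeneClass.UNEXPRESSED
    if padj < alpha:
        if abs(log2fc) >= lfc_threshold:
            return GeneClass.DEG_UP if log2fc > 0 else GeneClass.DEG_DOWN
        return GeneClass.BREAKER_UP if log2fc > 0 else GeneClass.BREAKER_DOWN
    return GeneClass.STATIC


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression result with its derived class."""

    gene_id: str
    log2fc: float
    padj: float | None
    klass: str

    @classmethod
    def from_stats(cls, gene_id: str, log2fc: float, padj: float | None,
                   alpha: float = 0.05, lfc_threshold: float = 1.0) -> "DEGRecord":
        return cls(gene_id, log2fc, padj,
                   classify_gene(log2fc, padj, alpha, lfc_threshold))


@dataclass(frozen=True)
class TadInterval:
    """A topologically associating domain; non-overlapping within a chromosome."""

    chrom: str
    start: int
    end: int
    tad_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"TAD {self.tad_id}: end <= start")


@dataclass(frozen=True)
class GenomicInterval:
    """A generic 0-based half-open interval (peak, repeat, domain...).

    ``summit`` is an absolute coordinate and must lie inside the interval.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"interval {self.name}: end <= start")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"interval {self.name}: summit {self.summit} outside "
                f"[{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit if present, midpoint otherwise."""
        return self.summit if self.summit is not None else self.midpoint


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome signal bins.

    Bin *i* of a chromosome covers ``[i*w, (i+1)*w)``.  Missing bins are NaN;
    missing is distinct from zero.
    """

    bin_width: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            self.values[chrom] = np.asarray(arr, dtype=float)
            if chrom not in self.chrom_lengths:
                self.chrom_lengths[chrom] = len(self.values[chrom]) * self.bin_width

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def all_values(self) -> np.ndarray:
        """Concatenated non-missing values genome-wide, in chromosome order."""
        parts = [self.values[c] for c in self.chroms]
        flat = np.concatenate(parts) if parts else np.array([])
        return flat[np.isfinite(flat)]

    def same_binning(self, other: "BinnedTrack") -> bool:
        return (self.bin_width == other.bin_width
                and set(self.values) == set(other.values)
                and all(len(self.values[c]) == len(other.values[c])
                        for c in self.values))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.bin_width,
                           {c: v.copy() for c, v in self.values.items()},
                           dict(self.chrom_lengths))


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_genes(path: str | Path, dialect: str | None = None) -> list[GeneRecord]:
    """Read gene annotation from GTF (1-based inclusive) or BED (0-based).

    The dialect is inferred from the extension unless given explicitly
    (``"gtf"`` or ``"bed"``).  Output is normalized to 0-based half-open,
    sorted by (chrom, start, gene_id); duplicate gene ids are rejected.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".gtf", ".gff"):
            dialect = "gtf"
        elif suffix.startswith(".bed"):
            dialect = "bed"
        else:
            raise ValueError(f"cannot infer dialect from {path.name!r}")

    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gtf":
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 columns")
                    if fields[2] != "gene":
                        continue
                    attrs = _parse_gtf_attributes(fields[8])
                    gene_id = attrs.get("gene_id")
                    if gene_id is None:
                        raise ValueError("no gene_id attribute")
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in ("+", "-") else "."
                    records.append(GeneRecord(gene_id, fields[0], start, end, strand))
                else:
                    if len(fields) < 4:
                        raise ValueError("BED gene line needs >= 4 columns")
                    start, end = int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
                    records.append(GeneRecord(fields[3], fields[0], start, end, strand))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc

    seen: dict[str, int] = {}
    for rec in records:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
        seen[rec.gene_id] = 1
    records.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return records


def write_genes_gtf(genes: Iterable[GeneRecord], path: str | Path,
                    source: str = "ecordkit") -> None:
    """Write genes as GTF gene features (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda r: (r.chrom, r.start, r.gene_id)):
            strand = g.strand if g.strand in ("+", "-") else "."
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{strand}\t.\tgene_id \"{g.gene_id}\";\n")


def read_deg_table(path: str | Path, alpha: float = 0.05,
                   lfc_threshold: float = 1.0) -> dict[str, DEGRecord]:
    """Read a differential-expression TSV (columns gene_id, log2fc, padj).

    A missing/NA padj marks an unexpressed gene (removed by independent
    filtering upstream).  Returns a mapping gene_id -> DEGRecord.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise ParseError(f"DEG table missing columns {sorted(required - set(df.columns))}")
    out: dict[str, DEGRecord] = {}
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in out:
            raise ValidationError(f"duplicate gene_id {gid!r} in DEG table")
        padj = None if pd.isna(row.padj) else float(row.padj)
        out[gid] = DEGRecord.from_stats(gid, float(row.log2fc), padj,
                                        alpha, lfc_threshold)
    return out


def write_deg_table(records: Mapping[str, DEGRecord] | Iterable[DEGRecord],
                    path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    rows = [(r.gene_id, r.log2fc, "" if r.padj is None else r.padj)
            for r in records]
    pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"]).to_csv(
        path, sep="\t", index=False)


def read_tads(path: str | Path) -> list[TadInterval]:
    """Read TADs from BED; overlapping TADs on one chromosome are rejected."""
    tads: list[TadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                name = fields[3] if len(fields) >= 4 else f"tad_{lineno}"
                tads.append(TadInterval(fields[0], int(fields[1]), int(fields[2]), name))
            except (ValueError, ValidationError, IndexError) as exc:
                raise ParseError(f"{Path(path).name}:{lineno}: {exc}") from exc
    tads.sort(key=lambda t: (t.chrom, t.start))
    for a, b in zip(tads, tads[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValidationError(f"TADs {a.tad_id} and {b.tad_id} overlap")
    return tads


def read_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (or narrowPeak-like with a summit-offset column 10)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                start, end = int(f[1]), int(f[2])
                name = f[3] if len(f) >= 4 and f[3] != "." else None
                score = float(f[4]) if len(f) >= 5 and f[4] != "." else None
                summit = None
                if len(f) >= 10 and f[9] not in (".", "-1"):
                    summit = start + int(f[9])
                out.append(GenomicInterval(f[0], start, end, name, score, summit))
            except (ValueError, ValidationError, IndexError) as exc:
                raise ParseError(f"{Path(path).name}:{lineno}: {exc}") from exc
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def write_intervals(items: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, sorted; round-trips with :func:`read_intervals`."""
    items = sorted(items, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for iv in items:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.summit is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.summit is not None:
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            if iv.summit is not None:
                cols += [".", ".", ".", ".", str(iv.summit - iv.start)]
            fh.write("\t".join(cols) + "\n")


def read_track(path: str | Path, bin_width: int,
               chrom_lengths: Mapping[str, int] | None = None,
               zero_fill: bool = False) -> BinnedTrack:
    """Read a bedGraph (or BigWig, if pyBigWig is available) into fixed bins.

    Intervals need not be bin-aligned: each bin receives the overlap-weighted
    mean of the intervals covering it.  Uncovered bins are missing (NaN)
    unless ``zero_fill`` is set.  Overlapping bedGraph intervals are an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        return _read_bigwig(path, bin_width, zero_fill)

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    df = df.sort_values(["chrom", "start"], kind="mergesort")

    lengths: dict[str, int] = dict(chrom_lengths or {})
    for chrom, grp in df.groupby("chrom", sort=False):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValidationError(f"overlapping bedGraph intervals on {chrom}")
        lengths.setdefault(chrom, int(ends.max()))

    values: dict[str, np.ndarray] = {}
    for chrom, length in lengths.items():
        n = -(-length // bin_width)
        acc = np.zeros(n)
        cov = np.zeros(n)
        grp = df[df["chrom"] == chrom]
        for start, end, value in zip(grp["start"], grp["end"], grp["value"]):
            first, last = start // bin_width, (end - 1) // bin_width
            for b in range(first, min(last, n - 1) + 1):
                lo, hi = max(start, b * bin_width), min(end, (b + 1) * bin_width)
                acc[b] += value * (hi - lo)
                cov[b] += hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = acc / cov
        vals[cov == 0] = 0.0 if zero_fill else np.nan
        values[chrom] = vals
    return BinnedTrack(bin_width, values, lengths)


def _read_bigwig(path: Path, bin_width: int, zero_fill: bool) -> BinnedTrack:
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    values: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for chrom, length in bw.chroms().items():
        n = -(-length // bin_width)
        arr = np.array(bw.stats(chrom, 0, length, nBins=n, type="mean"),
                       dtype=float)
        if zero_fill:
            arr[~np.isfinite(arr)] = 0.0
        values[chrom] = arr
        lengths[chrom] = length
    bw.close()
    return BinnedTrack(bin_width, values, lengths)


def write_track(track: BinnedTrack, path: str | Path) -> None:
    """Write a BinnedTrack as bedGraph; missing bins are omitted."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals = track.values[chrom]
            length = track.chrom_lengths.get(chrom, len(vals) * w)
            for i, v in enumerate(vals):
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, length)}\t{v:g}\n")
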