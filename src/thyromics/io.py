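"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is **0-based, half-open**.  Conversions happen only
in this module, exactly at the I/O boundary:

* BED: 0-based half-open on disk -- passed through unchanged.
* SEG: 1-based closed on disk -- ``start`` is decremented on read (a 1-based
  inclusive end already equals the half-open end).
* VCF: positions are 1-based points and are kept 1-based on
  :class:`VariantRecord` (a substitution is a point, not an interval).
* SAM-like TSV: 1-based leftmost position on disk, converted to a 0-based
  half-open ``[start, end)`` row in memory.

Unknown chromosome labels are kept verbatim; no "chr" aliasing is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "VariantRecord",
    "Segment",
    "PeakInterval",
    "AlignedReadTable",
    "EFFECTS",
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_expression",
    "write_expression",
    "read_peaks",
    "write_peaks",
    "read_alignments",
    "write_alignments",
]

EFFECTS = {
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "synonymous",
    "promoter",
    "other",
}
_CALLS = {"deleterious", "benign", "missing"}
_SOMATIC = {"somatic", "unknown"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class VariantRecord:
    """A single alternate allele with the annotations the retention filter uses.

    ``pos`` is 1-based.  ``popmax_af`` is the highest population allele
    frequency seen in a reference database (ExAC-style popmax), ``None`` when
    the variant is absent from the database.  ``polyphen_call`` / ``sift_call``
    are consumed as pre-computed annotations and never recomputed here.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    popmax_af: Optional[float] = None
    polyphen_call: str = "missing"
    sift_call: str = "missing"
    somatic_status: str = "unknown"
    sample: Optional[str] = None
    platform: Optional[str] = None  # e.g. WGS / WES / targeted

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.popmax_af is not None and not 0.0 <= self.popmax_af <= 1.0:
            raise FormatError(f"popmax_af outside [0,1]: {self.popmax_af}")
        if self.effect not in EFFECTS:
            raise FormatError(f"unknown effect {self.effect!r}")
        if self.polyphen_call not in _CALLS or self.sift_call not in _CALLS:
            raise FormatError("predictor calls must be deleterious/benign/missing")
        if self.somatic_status not in _SOMATIC:
            raise FormatError(f"somatic_status must be somatic/unknown")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != self.alt


@dataclass(frozen=True)
class Segment:
    """Copy-number segment; ``start``/``end`` are 0-based half-open in memory."""

    sample: str
    chrom: str
    start: int
    end: int
    log2ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"segment start >= end ({self.start} >= {self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class PeakInterval:
    """H3K27ac enrichment peak; 0-based half-open, signal = area under coverage."""

    chrom: str
    start: int
    end: int
    signal: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak start >= end ({self.start} >= {self.end})")
        if self.signal < 0:
            raise FormatError(f"negative peak signal {self.signal}")


class AlignedReadTable:
    """Table of aligned reads with mate linkage.

    Backed by a DataFrame with columns ``qname, chrom, start, end, mapq,
    mate_qname`` (0-based half-open).  :meth:`fragments` joins mate pairs into
    sequenced-fragment intervals, the unit the methylation classifier consumes.
    """

    COLUMNS = ["qname", "chrom", "start", "end", "mapq", "mate_qname"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"alignment table missing columns: {missing}")
        mapq = frame["mapq"].to_numpy()
        bad = (mapq < 0) | (mapq > 255)
        if bad.any():
            raise FormatError(
                f"MAPQ outside [0,255] for reads: {frame['qname'][bad].tolist()[:5]}"
            )
        if (frame["start"] >= frame["end"]).any():
            raise FormatError("read with start >= end")
        self.frame = frame.reset_index(drop=True)[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlignedReadTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def fragments(self) -> pd.DataFrame:
        """Join paired records by query name into fragment intervals.

        Paired reads (mutual mate linkage on the same chromosome) become one
        fragment spanning the outermost coordinates, with ``mapq`` = min of
        the pair.  Unpaired reads are retained as single-read fragments and
        flagged ``paired=False``.
        """
        df = self.frame
        by_name = {q: i for i, q in enumerate(df["qname"])}
        used: set[int] = set()
        rows = []
        for i in range(len(df)):
            if i in used:
                continue
            r = df.iloc[i]
            mate = r["mate_qname"]
            j = by_name.get(mate) if isinstance(mate, str) and mate else None
            if (
                j is not None
                and j != i
                and j not in used
                and df.iloc[j]["mate_qname"] == r["qname"]
                and df.iloc[j]["chrom"] == r["chrom"]
            ):
                m = df.iloc[j]
                rows.append(
                    (
                        r["qname"],
                        r["chrom"],
                        int(min(r["start"], m["start"])),
                        int(max(r["end"], m["end"])),
                        int(min(r["mapq"], m["mapq"])),
                        True,
                    )
                )
                used.update((i, j))
            else:
                rows.append(
                    (r["qname"], r["chrom"], int(r["start"]), int(r["end"]),
                     int(r["mapq"]), False)
                )
                used.add(i)
        return pd.DataFrame(
            rows, columns=["qname", "chrom", "start", "end", "mapq", "paired"]
        )


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "gene", "effect",
    "popmax_af", "polyphen_call", "sift_call", "somatic_status", "platform",
]


def _coerce_effect(value: str, line_no: int) -> str:
    v = str(value).strip().lower()
    if v in EFFECTS:
        return v
    warnings.warn(
        f"line {line_no}: unknown effect {value!r} mapped to 'other'", stacklevel=3
    )
    return "other"


def read_variants(path: str | Path, dialect: str = "annotated_tsv") -> list[VariantRecord]:
    """Read variants from a VCF 4.2 file or an ANNOVAR-style annotated TSV.

    One record is emitted per alternate allele; multi-allelic rows are split.
    """
    path = Path(path)
    if dialect == "annotated_tsv":
        return _read_variants_tsv(path)
    if dialect == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            af = row.popmax_af
            out.append(
                VariantRecord(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene,
                    effect=_coerce_effect(row.effect, idx),
                    popmax_af=None if af in ("", ".", "NA") else float(af),
                    polyphen_call=row.polyphen_call or "missing",
                    sift_call=row.sift_call or "missing",
                    somatic_status=row.somatic_status or "unknown",
                    sample=row.sample or None,
                    platform=row.platform or None,
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path} line {idx}: {exc}") from exc
    return out


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    out = []
    vcf = VCF(str(path))
    try:
        for n, v in enumerate(vcf, start=1):
            info = dict(v.INFO)
            af = info.get("POPMAX_AF")
            if af is not None:
                af = float(f"{float(af):.7g}")  # htslib stores INFO floats as float32
            for alt in v.ALT:  # split multi-allelic rows
                out.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        gene=str(info.get("GENE", "")),
                        effect=_coerce_effect(info.get("EFFECT", "other"), n),
                        popmax_af=float(af) if af is not None else None,
                        polyphen_call=str(info.get("POLYPHEN", "missing")),
                        sift_call=str(info.get("SIFT", "missing")),
                        somatic_status=str(info.get("SOMATIC_STATUS", "unknown")),
                        sample=str(info["SAMPLE"]) if "SAMPLE" in info else None,
                        platform=str(info["PLATFORM"]) if "PLATFORM" in info else None,
                    )
                )
    finally:
        vcf.close()
    return out


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">
##INFO=<ID=POPMAX_AF,Number=1,Type=Float,Description="Population max allele frequency">
##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen2 call">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=SOMATIC_STATUS,Number=1,Type=String,Description="somatic or unknown">
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">
##INFO=<ID=PLATFORM,Number=1,Type=String,Description="Sequencing platform">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants(
    records: Iterable[VariantRecord], path: str | Path, dialect: str = "annotated_tsv"
) -> None:
    path = Path(path)
    records = list(records)
    if dialect == "annotated_tsv":
        rows = [
            {
                "sample": r.sample or "",
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "effect": r.effect,
                "popmax_af": "" if r.popmax_af is None else repr(r.popmax_af),
                "polyphen_call": r.polyphen_call,
                "sift_call": r.sift_call,
                "somatic_status": r.somatic_status,
                "platform": r.platform or "",
            }
            for r in records
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for r in records:
                info = [f"GENE={r.gene}", f"EFFECT={r.effect}"]
                if r.popmax_af is not None:
                    info.append(f"POPMAX_AF={r.popmax_af:g}")
                info += [f"POLYPHEN={r.polyphen_call}", f"SIFT={r.sift_call}",
                         f"SOMATIC_STATUS={r.somatic_status}"]
                if r.sample:
                    info.append(f"SAMPLE={r.sample}")
                if r.platform:
                    info.append(f"PLATFORM={r.platform}")
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{';'.join(info)}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Segments (SEG), expression TSV, peaks (BED5)
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[Segment]:
    """Read a SEG file (tab: sample, chrom, start, end, [num_mark,] log2ratio).

    On-disk coordinates are 1-based closed; returned segments are 0-based
    half-open.
    """
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        if ncol not in (5, 6):
            raise FormatError(f"{path}: SEG must have 5 or 6 columns, got {ncol}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise FormatError(f"{path} line {line_no}: expected {ncol} fields")
            try:
                out.append(
                    Segment(
                        sample=parts[0],
                        chrom=parts[1],
                        start=int(parts[2]) - 1,
                        end=int(parts[3]),
                        log2ratio=float(parts[-1]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return out


def write_segments(segments: Iterable[Segment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tlog2ratio\n")
        for s in segments:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t{s.log2ratio!r}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (header = sample ids).

    Duplicate gene rows or duplicate sample columns are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene rows {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample columns {dups[:5]}")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise FormatError(f"{path}: non-numeric expression values")
    df.index.name = "gene"
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_peaks(path: str | Path) -> list[PeakInterval]:
    """Read BED5 (chrom, start, end, name, signal); 0-based half-open."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path} line {line_no}: BED5 needs 5 fields")
            try:
                out.append(
                    PeakInterval(
                        chrom=parts[0],
                        start=int(parts[1]),
                        end=int(parts[2]),
                        signal=float(parts[4]),
                    )
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return out


def write_peaks(peaks: Iterable[PeakInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t{p.signal!r}\n")


# ---------------------------------------------------------------------------
# Alignments (SAM-like TSV or BAM)
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path, dialect: str = "sam_like_tsv") -> AlignedReadTable:
    """Read alignments.  TSV columns: qname, chrom, pos (1-based), end, mapq,
    mate_qname.  BAM is read through pysam when requested."""
    if dialect == "sam_like_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"qname": str, "mate_qname": str},
                         keep_default_na=False)
        need = ["qname", "chrom", "pos", "end", "mapq", "mate_qname"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        frame = pd.DataFrame(
            {
                "qname": df["qname"],
                "chrom": df["chrom"].astype(str),
                "start": df["pos"].astype(int) - 1,
                "end": df["end"].astype(int),
                "mapq": df["mapq"].astype(int),
                "mate_qname": df["mate_qname"],
            }
        )
        return AlignedReadTable(frame)
    if dialect == "bam":
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), "rb") as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                rows.append(
                    (
                        rec.query_name + ("/2" if rec.is_read2 else "/1"),
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end,
                        rec.mapping_quality,
                        rec.query_name + ("/1" if rec.is_read2 else "/2"),
                    )
                )
        return AlignedReadTable(
            pd.DataFrame(rows, columns=AlignedReadTable.COLUMNS)
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_alignments(table: AlignedReadTable, path: str | Path) -> None:
    df = table.frame
    out = pd.DataFrame(
        {
            "qname": df["qname"],
            "chrom": df["chrom"],
            "pos": df["start"] + 1,
            "end": df["end"],
            "mapq": df["mapq"],
            "mate_qname": df["mate_qname"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
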