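"""Readers/writers for every flat format the pipeline touches.

BED3/6, RepeatMasker ``.out``, genome FASTA, the tab-delimited
methylation table (chrom, pos, strand, context, kind, level_pct) and the
tab-delimited gene table (id, chrom, start, end, class, ka_ks).  All
writers emit tab-delimited UTF-8 with a single commented header line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "RepeatAnnotation",
    "read_repeatmasker",
    "MethylCall",
    "read_methylation",
    "write_methylation",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
]


class BedParseError(ValueError):
    pass


def read_bed(
    path: str,
    one_based: bool = False,
    genome_size: Optional[Dict[str, int]] = None,
) -> IntervalSet:
    """Read a BED3/6 file into an :class:`IntervalSet`.

    With ``one_based=True`` the start column is interpreted as 1-based
    inclusive and shifted to the internal 0-based half-open convention.
    Duplicate intervals are retained.
    """
    out = IntervalSet(genome_size=genome_size, name=path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom = fields[0]
                start = int(fields[1]) - (1 if one_based else 0)
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            if end <= start:
                raise BedParseError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.add(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(path: str, intervals: Iterable[GenomicInterval], six_col: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if six_col:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                         f"{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# RepeatMasker

@dataclass
class RepeatAnnotation:
    """One repeat copy: its span, family identity, and divergence."""

    interval: GenomicInterval
    repeat_name: str
    repeat_class: str
    divergence_pct: Optional[float] = None
    consensus_span: Optional[Tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.divergence_pct is not None and self.divergence_pct < 0:
            raise ValueError("negative divergence")

    def length(self) -> int:
        return self.interval.length()


_CLASS_PREFIXES = (
    ("L1", "LINE"), ("L2", "LINE"), ("LTR", "LTR"), ("HERV", "LTR"),
    ("Alu", "SINE"), ("MIR", "SINE"), ("MER", "DNA"),
)


def _infer_class(name: str) -> str:
    for prefix, cls in _CLASS_PREFIXES:
        if name.startswith(prefix):
            return cls
    return "Unknown"


def read_repeatmasker(path: str, dialect: str = "out") -> List[RepeatAnnotation]:
    """Read repeat annotations from a RepeatMasker ``.out`` file or BED.

    ``.out`` bodies are 1-based inclusive and converted to 0-based
    half-open.  The BED dialect carries name (column 4) and optionally
    class (column 7); divergence is absent.
    """
    annotations: List[RepeatAnnotation] = []
    if dialect == "out":
        with open(path) as fh:
            lines = fh.readlines()
        for raw in lines[3:]:  # 3 header lines precede the body
            fields = raw.split()
            if not fields:
                continue
            chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
            strand = "-" if fields[8] in ("C", "-") else "+"
            name, cls = fields[9], fields[10].split("/")[0]
            if fields[8] in ("C", "-"):
                c_left, c_begin, c_end = fields[11], int(fields[12]), int(fields[13])
                span = (c_begin, c_end, int(c_left.strip("()")))
            else:
                c_begin, c_end, c_left = int(fields[11]), int(fields[12]), fields[13]
                span = (c_begin, c_end, int(c_left.strip("()")))
            annotations.append(RepeatAnnotation(
                interval=GenomicInterval(chrom, begin - 1, end, strand, name),
                repeat_name=name, repeat_class=cls,
                divergence_pct=float(fields[1]), consensus_span=span))
    elif dialect == "bed":
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise BedParseError(f"{path}:{lineno}: repeat BED needs a name column")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
                cls = fields[6] if len(fields) > 6 else _infer_class(name)
                annotations.append(RepeatAnnotation(
                    interval=GenomicInterval(chrom, start, end, strand, name),
                    repeat_name=name, repeat_class=cls))
    else:
        raise ValueError(f"unknown RepeatMasker dialect: {dialect!r}")
    return annotations


def write_repeat_bed(path: str, annotations: Iterable[RepeatAnnotation]) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            iv = ann.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.repeat_name}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '+'}\t{ann.repeat_class}\n")


# ---------------------------------------------------------------------------
# Methylation table

@dataclass(frozen=True)
class MethylCall:
    """A base-resolution methylation/5hmC call on one strand."""

    chrom: str
    position: int  # 0-based offset of the cytosine
    strand: str
    context: str  # CG / CHG / CHH
    kind: str     # mC / hmC
    level_pct: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")
        if self.kind not in ("mC", "hmC"):
            raise ValueError(f"bad kind: {self.kind!r}")
        if not 0 <= self.level_pct <= 100:
            raise ValueError(f"level out of range: {self.level_pct}")

    @property
    def signed_level(self) -> float:
        """Display level: positive on +, negative on - strand."""
        return self.level_pct if self.strand == "+" else -self.level_pct


_METHYL_COLUMNS = ["chrom", "position", "strand", "context", "kind", "level_pct"]


def read_methylation(path: str) -> List[MethylCall]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_METHYL_COLUMNS)
    return [MethylCall(r.chrom, int(r.position), r.strand, r.context, r.kind,
                       float(r.level_pct))
            for r in df.itertuples(index=False)]


def write_methylation(path: str, calls: Iterable[MethylCall]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_METHYL_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.position}\t{c.strand}\t{c.context}\t"
                     f"{c.kind}\t{c.level_pct:g}\n")


# ---------------------------------------------------------------------------
# Gene table

_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "gene_class", "ka_ks"]


def read_gene_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_GENE_COLUMNS)
    return df


def write_gene_table(path: str, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_GENE_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Binding-site BED (peak coordinates; name column carries "tf|site_id")

def write_sites_bed(path: str, sites: Iterable["BindingSite"]) -> None:
    with open(path, "w") as fh:
        for s in sites:
            p = s.peak
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{s.tf}|{s.site_id}\t0\t"
                     f"{p.strand if p.strand != '.' else '+'}\n")


def read_sites_bed(path: str, window_width: int = 200) -> List["BindingSite"]:
    from .intervals import BindingSite  # local import avoids a cycle at module load

    sites: List[BindingSite] = []
    for iv in read_bed(path):
        if iv.name and "|" in iv.name:
            tf, site_id = iv.name.split("|", 1)
        else:
            tf, site_id = iv.name or "TF", None
        sites.append(BindingSite(tf=tf, peak=iv, window_width=window_width,
                                 site_id=site_id))
    return sites


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
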