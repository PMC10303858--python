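"""Domain types and readers/writers for the tabular and interval formats the pipeline touches.

Every coordinate held in memory is 0-based, half-open (BED-native).  GTF is
the only 1-based inclusive format; it is converted on read and write so that
no other module ever sees a 1-based coordinate.  Tab is the only field
separator — no whitespace splitting — so that read/write round-trips are
byte-exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Raised on malformed input, with the offending line number when known."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥ 1 bp shared, strand-blind."""
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )


@dataclass(frozen=True)
class L1Locus:
    """A genomic L1 copy: interval plus RepeatMasker-style metadata.

    ``milli_div`` is the number of base mismatches per thousand between the
    copy and its subfamily consensus — a proxy for evolutionary age (lower =
    younger).
    """

    interval: GenomicInterval
    subfamily: str
    milli_div: float

    def __post_init__(self) -> None:
        if self.milli_div < 0:
            raise ValueError("milli_div must be >= 0")

    @property
    def id(self) -> str:
        return self.interval.id

    @property
    def length(self) -> int:
        return self.interval.length


def subfamily_from_id(name: str) -> str:
    """First colon-separated token of a RepeatMasker-style id.

    ``"L1PA7:L1:LINE" -> "L1PA7"``; a bare subfamily passes through.
    """
    return name.split(":", 1)[0]


@dataclass
class GeneModel:
    """A gene body with its (merged, sorted) exon structure."""

    gene_id: str
    gene_name: str
    body: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "protein_coding"
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.exons = merge_exons(self.exons)
        for ex in self.exons:
            if ex.chrom != self.body.chrom or ex.start < self.body.start or ex.end > self.body.end:
                raise ValueError(
                    f"exon {ex.chrom}:{ex.start}-{ex.end} outside body of {self.gene_id}"
                )

    def introns(self) -> list[GenomicInterval]:
        """Body minus exons, in order."""
        out = []
        cursor = self.body.start
        for ex in self.exons:
            if ex.start > cursor:
                out.append(
                    GenomicInterval(self.body.chrom, cursor, ex.start, self.body.strand)
                )
            cursor = max(cursor, ex.end)
        if cursor < self.body.end:
            out.append(
                GenomicInterval(self.body.chrom, cursor, self.body.end, self.body.strand)
            )
        return out


def merge_exons(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping/adjacent intervals on one chromosome."""
    if not exons:
        return []
    exons = sorted(exons, key=lambda e: (e.chrom, e.start, e.end))
    merged = [exons[0]]
    for ex in exons[1:]:
        last = merged[-1]
        if ex.chrom == last.chrom and ex.start <= last.end:
            if ex.end > last.end:
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, ex.end, last.strand, last.id
                )
        else:
            merged.append(ex)
    return merged


# ---------------------------------------------------------------------------
# BED (0-based half-open; BED6 + optional subfamily/milliDiv/length columns)
# ---------------------------------------------------------------------------


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"line {lineno}: non-integer {what}: {token!r}") from None


def read_bed(path) -> list:
    """Read BED6(+3).

    With the three extra columns (subfamily, milliDiv, length) records come
    back as :class:`L1Locus`, otherwise as :class:`GenomicInterval`.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 tab-separated fields")
            start = _parse_int(f[1], "start", lineno)
            end = _parse_int(f[2], "end", lineno)
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 and f[5] in VALID_STRANDS else "."
            iv = GenomicInterval(f[0], start, end, strand, name)
            if len(f) >= 9:
                length = _parse_int(f[8], "length", lineno)
                if length != iv.length:
                    raise FormatError(
                        f"line {lineno}: length column {length} != end - start {iv.length}"
                    )
                out.append(L1Locus(iv, subfamily=f[6], milli_div=float(f[7])))
            else:
                out.append(iv)
    return out


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, L1Locus):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}"
                    f"\t{rec.subfamily}\t{rec.milli_div:g}\t{rec.length}\n"
                )
            else:
                fh.write(
                    f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.id}\t0\t{rec.strand}\n"
                )


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk; converted to 0-based half-open in memory)
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path) -> list[GeneModel]:
    """Read exon features of a GTF and assemble one :class:`GeneModel` per gene.

    Gene body is the min/max exon span unless an explicit ``gene`` feature is
    present; overlapping exon records of one gene are merged.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    bodies: dict[str, GenomicInterval] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF fields, got {len(f)}")
            feature = f[2]
            if feature not in ("exon", "gene"):
                continue
            start = _parse_int(f[3], "start", lineno) - 1  # 1-based -> 0-based
            end = _parse_int(f[4], "end", lineno)
            strand = f[6] if f[6] in VALID_STRANDS else "."
            attrs = _parse_gtf_attributes(f[8])
            gid = attrs.get("gene_id")
            if not gid:
                raise FormatError(f"line {lineno}: {feature} without gene_id attribute")
            if gid not in meta:
                meta[gid] = {
                    "gene_name": attrs.get("gene_name", gid),
                    "biotype": attrs.get("biotype", attrs.get("gene_type", "protein_coding")),
                    "labels": frozenset(
                        x for x in attrs.get("labels", "").split(",") if x
                    ),
                }
                order.append(gid)
            else:
                if "labels" in attrs:
                    meta[gid]["labels"] = meta[gid]["labels"] | frozenset(
                        x for x in attrs["labels"].split(",") if x
                    )
            iv = GenomicInterval(f[0], start, end, strand)
            if feature == "gene":
                bodies[gid] = iv
            else:
                exons.setdefault(gid, []).append(iv)
    models = []
    for gid in order:
        ex = merge_exons(exons.get(gid, []))
        if not ex and gid not in bodies:
            continue
        if gid in bodies:
            body = bodies[gid]
        else:
            body = GenomicInterval(
                ex[0].chrom, ex[0].start, max(e.end for e in ex), ex[0].strand
            )
        m = meta[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                gene_name=m["gene_name"],
                body=GenomicInterval(body.chrom, body.start, body.end, body.strand, gid),
                exons=ex,
                biotype=m["biotype"],
                labels=m["labels"],
            )
        )
    return models


def write_gtf_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            labels = ",".join(sorted(g.labels))
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'biotype "{g.biotype}";'
            )
            if labels:
                attrs += f' labels "{labels}";'
            b = g.body
            fh.write(
                f"{b.chrom}\tl1locus\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\tl1locus\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Count matrices, sample sheets
# ---------------------------------------------------------------------------


def read_counts_tsv(path, raw: bool = True) -> pd.DataFrame:
    """Feature × sample count matrix; first column = feature id, header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicated feature id: {dup!r}")
    if df.isna().any().any():
        raise FormatError("ragged or missing values in count matrix")
    if raw:
        values = df.to_numpy()
        if (values < 0).any():
            raise FormatError("negative raw count")
        if not np.allclose(values, np.round(values)):
            raise FormatError("non-integral raw count")
        df = df.astype(np.int64)
    return df


def write_counts_tsv(counts: pd.DataFrame, path, index_label: str = "feature") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column {col!r}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BEDPE fragment tables
# ---------------------------------------------------------------------------

BEDPE_COLUMNS = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "read_id",
    "mapq",
    "strand1",
    "strand2",
    "proper_pair",
]


def fragment_table(records) -> pd.DataFrame:
    """Build a validated fragment table from an iterable of dict-like records."""
    df = pd.DataFrame(list(records), columns=BEDPE_COLUMNS)
    return _validate_fragments(df)


def _validate_fragments(df: pd.DataFrame) -> pd.DataFrame:
    for c in ("start1", "end1", "start2", "end2", "mapq"):
        df[c] = df[c].astype(np.int64)
    if (df["mapq"] < 0).any():
        raise FormatError("negative mapq")
    if ((df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])).any():
        raise FormatError("empty mate interval in fragment table")
    df["proper_pair"] = df["proper_pair"].astype(bool)
    return df


def read_bedpe(path) -> pd.DataFrame:
    """BEDPE with name = read id, score = mapq; both mates 0-based half-open.

    Column 11 (flag ``1``/``0``) carries the proper-pair status; absent, all
    records are taken as properly paired.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"line {lineno}: expected >= 10 BEDPE fields")
            rows.append(
                {
                    "chrom1": f[0],
                    "start1": _parse_int(f[1], "start1", lineno),
                    "end1": _parse_int(f[2], "end1", lineno),
                    "chrom2": f[3],
                    "start2": _parse_int(f[4], "start2", lineno),
                    "end2": _parse_int(f[5], "end2", lineno),
                    "read_id": f[6],
                    "mapq": _parse_int(f[7], "mapq", lineno),
                    "strand1": f[8],
                    "strand2": f[9],
                    "proper_pair": f[10] == "1" if len(f) > 10 else True,
                }
            )
    return _validate_fragments(pd.DataFrame(rows, columns=BEDPE_COLUMNS))


def write_bedpe(fragments: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in fragments.itertuples(index=False):
            fh.write(
                f"{r.chrom1}\t{r.start1}\t{r.end1}\t{r.chrom2}\t{r.start2}\t{r.end2}"
                f"\t{r.read_id}\t{r.mapq}\t{r.strand1}\t{r.strand2}"
                f"\t{1 if r.proper_pair else 0}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph signal tracks
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> pd.DataFrame:
    """Signal track as a DataFrame (chrom, start, end, value), sorted runs."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise FormatError(f"line {lineno}: expected 4 bedGraph fields")
            start = _parse_int(f[1], "start", lineno)
            end = _parse_int(f[2], "end", lineno)
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end")
            value = float(f[3])
            if not np.isfinite(value):
                raise FormatError(f"line {lineno}: non-finite value")
            rows.append((f[0], start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    # runs must not overlap
    same = df["chrom"].shift() == df["chrom"]
    if (same & (df["start"] < df["end"].shift())).any():
        raise FormatError("overlapping bedGraph runs")
    return df


def write_bedgraph(track: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in track.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.value:g}\n")


# ---------------------------------------------------------------------------
# Retained-intron tables (IRFinder-style)
# ---------------------------------------------------------------------------

IR_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "IRratio",
    "IntronDepth",
    "Warnings",
    "overlaps_known_feature",
]


def read_ir_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"Warnings": str})
    missing = [c for c in IR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"retained-intron table missing columns: {missing}")
    if ((df["IRratio"] < 0) | (df["IRratio"] > 1)).any():
        raise FormatError("IRratio outside [0, 1]")
    df["overlaps_known_feature"] = df["overlaps_known_feature"].astype(bool)
    return df


def write_ir_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["overlaps_known_feature"] = out["overlaps_known_feature"].astype(int).astype(bool)
    out.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def intervals_of(loci) -> list[GenomicInterval]:
    """Project a mixed list of L1Locus/GeneModel/GenomicInterval onto intervals."""
    out = []
    for x in loci:
        if isinstance(x, L1Locus):
            out.append(x.interval)
        elif isinstance(x, GeneModel):
            out.append(x.body)
        else:
            out.append(x)
    return out
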