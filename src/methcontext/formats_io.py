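"""Readers and writers for the formats the pipeline touches.

Conventions, fixed package-wide:

* genome sequences are uppercase over ``{A, C, G, T, N}``;
* cytosine reports are 1-based, per-strand (Bismark-style columns:
  contig, position, strand, methylated count, unmethylated count);
* all interval files are 0-based half-open (BED standard);
* TSV outputs carry a single ``#``-prefixed header line, tab separators,
  ``.`` for missing values, LF line endings.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ``{A,C,G,T,N}`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """An ordered collection of named contigs.

    Sequences are normalized to uppercase ``{A,C,G,T,N}``; any other
    letter (IUPAC ambiguity codes, gaps) becomes ``N`` and ``U`` becomes
    ``T``.
    """

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise FormatError("genome contains no contigs")
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains unnormalized characters {sorted(bad)}"
                )

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])


_NORMALIZE = str.maketrans(
    {c: ("T" if c in "Uu" else c.upper() if c.upper() in "ACGTN" else "N")
     for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"}
)


def normalize_sequence(seq: str) -> str:
    """Uppercase; U -> T; anything outside {A,C,G,T} -> N."""
    return str(seq).translate(_NORMALIZE)


def read_fasta(path) -> GenomeSequence:
    """Read a (multi-)FASTA file into a :class:`GenomeSequence`.

    Raises :class:`FormatError` (with a line number where identifiable)
    on an empty file, a duplicate contig name, or content before the
    first header.
    """
    # Pre-scan for structural problems SeqIO silently tolerates.
    with open(path) as fh:
        first_header_seen = False
        names: dict[str, int] = {}
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                first_header_seen = True
                name = stripped[1:].split()[0] if len(stripped) > 1 else ""
                if not name:
                    raise FormatError("FASTA header with empty contig name", lineno)
                if name in names:
                    raise FormatError(
                        f"duplicate contig name {name!r} (first seen on line {names[name]})",
                        lineno,
                    )
                names[name] = lineno
            elif not first_header_seen:
                raise FormatError("sequence data before first FASTA header", lineno)
        if not first_header_seen:
            raise FormatError("empty FASTA file (no headers found)")

    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        contigs[record.id] = normalize_sequence(str(record.seq))
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Cytosine reports


REPORT_COLUMNS = ["contig", "pos", "strand", "n_meth", "n_unmeth"]


@dataclass
class MethylomeTable:
    """Per-cytosine methylation counts for one sample/timepoint.

    ``records`` is a DataFrame with columns contig (str), pos (1-based
    int, plus-strand coordinate of the cytosine's own base), strand
    (``+``/``-``), n_meth, n_unmeth (non-negative ints), sorted by
    (contig, pos, strand) with no duplicates.
    """

    sample_id: str
    records: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REPORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"methylome table missing columns {missing}")
        self.records = _canonicalize_report(df)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coverage(self) -> pd.Series:
        return self.records["n_meth"] + self.records["n_unmeth"]

    @property
    def levels(self) -> pd.Series:
        """Per-cytosine methylation level n_meth / coverage."""
        cov = self.coverage
        return self.records["n_meth"] / cov.where(cov > 0)

    def filter_coverage(self, min_coverage: int) -> "MethylomeTable":
        """Drop cytosines covered by fewer than ``min_coverage`` reads."""
        keep = self.coverage >= min_coverage
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "%s: dropped %d/%d cytosines below coverage %d",
                self.sample_id, dropped, len(self.records), min_coverage,
            )
        return MethylomeTable(self.sample_id, self.records.loc[keep])


def _canonicalize_report(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, REPORT_COLUMNS].copy()
    df["contig"] = df["contig"].astype(str)
    df["strand"] = df["strand"].astype(str)
    for col in ("pos", "n_meth", "n_unmeth"):
        df[col] = df[col].astype(np.int64)
    if (df["pos"] < 1).any():
        raise FormatError("cytosine position < 1 (positions are 1-based)")
    if ((df["n_meth"] < 0) | (df["n_unmeth"] < 0)).any():
        raise FormatError("negative read count")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"strand not in {{+,-}}: {df.loc[bad_strand, 'strand'].iloc[0]!r}")
    df = df.sort_values(["contig", "pos", "strand"], kind="mergesort")
    df = df.drop_duplicates(["contig", "pos", "strand"], keep="first")
    return df.reset_index(drop=True)


def read_cytosine_report(path, min_coverage: int = 10, sample_id: str | None = None) -> MethylomeTable:
    """Read a Bismark-style cytosine report TSV.

    Expected columns (tab-separated, optional ``#``-prefixed header,
    extra columns ignored): contig, 1-based position, strand (+/-),
    methylated count, unmethylated count.  Records with coverage below
    ``min_coverage`` are dropped; the output is sorted and de-duplicated.
    """
    if min_coverage < 0:
        raise ConfigurationError("min_coverage must be >= 0")
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=REPORT_COLUMNS, usecols=range(5),
            dtype={0: str, 2: str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed cytosine report: {exc}") from exc
    if df.empty:
        raise FormatError("empty cytosine report")
    for col in ("pos", "n_meth", "n_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            raise FormatError(
                f"non-integer value in column {col!r}", _report_lineno(path, int(bad.idxmax()))
            )
        df[col] = numeric.astype(np.int64)
    for check, message in (
        (df["pos"] < 1, "position < 1 (positions are 1-based)"),
        ((df["n_meth"] < 0) | (df["n_unmeth"] < 0), "negative read count"),
        (~df["strand"].isin(["+", "-"]), "strand not in {+,-}"),
    ):
        if check.any():
            raise FormatError(message, _report_lineno(path, int(check.idxmax())))
    name = sample_id if sample_id is not None else _stem(path)
    return MethylomeTable(name, df).filter_coverage(min_coverage)


def _report_lineno(path, row_index: int) -> int:
    """Map a pandas row index back to a 1-based file line number, counting
    comment lines."""
    with open(path) as fh:
        data_rows = -1
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            data_rows += 1
            if data_rows == row_index:
                return lineno
    return row_index + 1


def _stem(path) -> str:
    import os
    return os.path.splitext(os.path.basename(str(path)))[0]


def write_cytosine_report(methylome: MethylomeTable, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(REPORT_COLUMNS) + "\n")
        methylome.records.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Intervals (BED, 0-based half-open)


@dataclass
class IntervalSet:
    """Genomic intervals in 0-based half-open coordinates.

    ``intervals`` columns: contig, start, end, name and optionally
    strand.  Names are unique within a set; unnamed intervals are
    auto-named ``contig:start-end``.
    """

    intervals: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        for col in ("contig", "start", "end"):
            if col not in df.columns:
                raise FormatError(f"interval table missing column {col!r}")
        df["contig"] = df["contig"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise FormatError("interval start < 0")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise FormatError(
                f"interval start >= end: {bad['contig']}:{bad['start']}-{bad['end']}"
            )
        if "name" not in df.columns:
            df["name"] = ""
        df["name"] = df["name"].fillna("").astype(str)
        unnamed = (df["name"] == "") | (df["name"] == ".")
        df.loc[unnamed, "name"] = (
            df.loc[unnamed, "contig"]
            + ":" + df.loc[unnamed, "start"].astype(str)
            + "-" + df.loc[unnamed, "end"].astype(str)
        )
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise FormatError(f"duplicate interval name {dup!r}")
        keep = ["contig", "start", "end", "name"]
        if "strand" in df.columns:
            df["strand"] = df["strand"].astype(str)
            keep.append("strand")
        self.intervals = df.loc[:, keep].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def names(self) -> pd.Series:
        return self.intervals["name"]

    def lengths(self) -> pd.Series:
        return self.intervals["end"] - self.intervals["start"]

    def to_pyranges(self):
        import pyranges as pr

        df = self.intervals.rename(
            columns={"contig": "Chromosome", "start": "Start", "end": "End", "name": "Name"}
        )
        if "strand" in df.columns:
            df = df.rename(columns={"strand": "Strand"})
        return pr.PyRanges(df)


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open).

    Columns beyond the fourth are ignored except a sixth-column strand,
    which is kept when present.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith(("#", "track", "browser")):
                continue
            parts = stripped.split("\t")
            if len(parts) < 3:
                raise FormatError("BED line with fewer than 3 columns", lineno)
            contig = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError("non-integer BED coordinate", lineno) from None
            if start < 0:
                raise FormatError("negative BED start", lineno)
            if start >= end:
                raise FormatError(f"empty or inverted interval {contig}:{start}-{end}", lineno)
            row = {"contig": contig, "start": start, "end": end,
                   "name": parts[3] if len(parts) > 3 else ""}
            if len(parts) > 5 and parts[5] in ("+", "-"):
                row["strand"] = parts[5]
            rows.append(row)
    if not rows:
        raise FormatError("empty BED file")
    return IntervalSet(pd.DataFrame(rows))


def write_bed(intervals: IntervalSet, path) -> None:
    df = intervals.intervals
    cols = ["contig", "start", "end", "name"]
    out = df.loc[:, cols].copy()
    if "strand" in df.columns:
        out["score"] = 0
        out["strand"] = df["strand"]
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Generic TSV


def write_tsv(table: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV: '#'-prefixed header, '.' for missing,
    LF line endings, deterministic row order (as given)."""
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False, na_rep=".", lineterminator="\n")
    text = buf.getvalue()
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + text)


def read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    df.columns = [c.lstrip("#") for c in df.columns]
    return df
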