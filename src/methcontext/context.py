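"""Flanking-context (NNCGNN) methylation preference analysis.

Every CpG sits in a 6-base context -- two flanking bases on each side of
the central CG, read 5'->3' on the cytosine's own strand -- giving 256
possible hexamers.  DNA methyltransferases and TET oxidases have
measurable in-vitro rate preferences over these contexts.  This module
extracts contexts strand-awarely from a genome, averages observed
per-cytosine methylation within each context, and correlates the
resulting 256-vector against enzyme preference profiles: a high Pearson
r means the enzyme's favourite sites are among the most methylated, so
the enzyme is an active contributor to the methylome; a drop after
depleting a factor means the factor sustained activity at those sites.

The user-facing entry point is :class:`ContextPreferenceModel`, whose
``fit()`` returns a :class:`ContextPreferenceResults` carrying one
correlation per (sample, enzyme) pair.  The module-level functions
implement the individual steps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    FormatError,
    InsufficientDataError,
    PatternError,
    UndefinedStatisticError,
)
from .formats_io import GenomeSequence, MethylomeTable, revcomp

logger = logging.getLogger(__name__)

#: All 256 NNCGNN hexamers in lexicographic order.
ALL_HEXAMERS: tuple[str, ...] = tuple(
    a + b + "CG" + c + d
    for a, b, c, d in itertools.product("ACGT", repeat=4)
)

_HEX_INDEX = {h: i for i, h in enumerate(ALL_HEXAMERS)}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def is_valid_hexamer(hexamer: str) -> bool:
    return (
        len(hexamer) == 6
        and hexamer[2:4] == "CG"
        and all(b in _BASE_CODE for b in hexamer)
    )


def revcomp_hexamer(hexamer: str) -> str:
    """Reverse complement of an NNCGNN hexamer (an involution; the
    central CG maps to itself)."""
    if not is_valid_hexamer(hexamer):
        raise PatternError(f"not an NNCGNN hexamer: {hexamer!r}")
    return revcomp(hexamer)


def hexamer_pairs() -> tuple[list[tuple[str, str]], list[str]]:
    """Partition the 256 contexts into complementary pairs and palindromes.

    Returns (pairs, palindromes); each non-palindromic hexamer appears in
    exactly one pair, listed with the lexicographically smaller first.
    """
    pairs, palindromes = [], []
    for h in ALL_HEXAMERS:
        rc = revcomp(h)
        if rc == h:
            palindromes.append(h)
        elif h < rc:
            pairs.append((h, rc))
    return pairs, palindromes


@dataclass
class HexamerProfile:
    """A value per NNCGNN context: an in-vitro enzyme preference, or the
    mean observed methylation of the sites carrying that context.

    ``values`` is indexed by all 256 hexamers; NaN marks contexts with no
    data (observation profiles over small genomes).  ``n_sites`` records
    how many cytosines contributed per context for observation profiles.
    """

    name: str
    values: pd.Series = field(repr=False)
    n_sites: pd.Series | None = field(default=None, repr=False)
    symmetrized: bool = False

    def __post_init__(self) -> None:
        vals = pd.Series(self.values, dtype=float)
        if set(vals.index) != set(ALL_HEXAMERS):
            missing = sorted(set(ALL_HEXAMERS) - set(vals.index))
            extra = sorted(set(vals.index) - set(ALL_HEXAMERS))
            if missing:
                raise FormatError(
                    f"profile {self.name!r} missing {len(missing)} hexamers "
                    f"(first: {missing[:3]})"
                )
            raise FormatError(f"profile {self.name!r} has invalid hexamers {extra[:3]}")
        if len(vals) != 256:
            dup = vals.index[vals.index.duplicated()][0]
            raise FormatError(f"profile {self.name!r} has duplicate hexamer {dup!r}")
        if np.isinf(vals.to_numpy()).any():
            raise FormatError(f"profile {self.name!r} contains non-finite values")
        self.values = vals.reindex(ALL_HEXAMERS)
        if self.n_sites is not None:
            self.n_sites = pd.Series(self.n_sites).reindex(ALL_HEXAMERS).fillna(0).astype(int)

    @property
    def n_observed(self) -> int:
        return int(self.values.notna().sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"hexamer": ALL_HEXAMERS, "value": self.values.to_numpy()})
        if self.n_sites is not None:
            df["n_sites"] = self.n_sites.to_numpy()
        return df


def read_preference_table(path, name: str | None = None) -> HexamerProfile:
    """Read an enzyme flanking-preference TSV (columns hexamer, value).

    The table must contain each of the 256 NNCGNN hexamers exactly once
    with a finite value.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["hexamer", "value"])
    if df.empty:
        raise FormatError("empty preference table")
    df["hexamer"] = df["hexamer"].astype(str).str.strip().str.upper()
    bad = [h for h in df["hexamer"] if not is_valid_hexamer(h)]
    if bad:
        raise FormatError(f"hexamers not matching NNCGNN: {bad[:5]}")
    dup = df.loc[df["hexamer"].duplicated(), "hexamer"].tolist()
    if dup:
        raise FormatError(f"duplicate hexamers: {sorted(set(dup))[:5]}")
    missing = sorted(set(ALL_HEXAMERS) - set(df["hexamer"]))
    if missing:
        raise FormatError(
            f"{len(missing)} hexamers missing from preference table (first: {missing[:5]})"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any() or np.isinf(values.to_numpy()).any():
        raise FormatError("non-finite preference value")
    from .formats_io import _stem

    series = pd.Series(values.to_numpy(), index=df["hexamer"].to_numpy())
    return HexamerProfile(name or _stem(path), series)


def write_preference_table(profile: HexamerProfile, path) -> None:
    from .formats_io import write_tsv

    write_tsv(profile.to_frame(), path)


# ---------------------------------------------------------------------------
# Context extraction


def extract_context(
    genome: GenomeSequence, contig: str, pos: int, strand: str
) -> str | None:
    """NNCGNN context of the cytosine at 1-based ``pos`` on ``strand``.

    Plus strand: the plus-strand window [pos-2, pos+3] (1-based,
    inclusive).  Minus strand (cytosine opposite the plus-strand G at
    coordinate ``pos``): reverse complement of the plus-strand window
    [pos-3, pos+2].  Returns None when the window runs off the contig,
    contains N, or is not centred on a CpG.
    """
    seq = genome[contig]
    if not 1 <= pos <= len(seq):
        raise FormatError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
    if strand == "+":
        lo, hi = pos - 3, pos + 3  # 0-based slice bounds
    elif strand == "-":
        lo, hi = pos - 4, pos + 2
    else:
        raise FormatError(f"strand must be + or -, got {strand!r}")
    if lo < 0 or hi > len(seq):
        return None
    window = seq[lo:hi]
    context = window if strand == "+" else revcomp(window)
    if "N" in context or context[2:4] != "CG":
        return None
    return context


def _encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence: A,C,G,T -> 0..3, N -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    return lut[arr]


def contexts_for_records(genome: GenomeSequence, records: pd.DataFrame) -> np.ndarray:
    """Vectorized context lookup for a cytosine-report DataFrame.

    Returns an int array of hexamer indices into :data:`ALL_HEXAMERS`,
    with -1 for sites whose context is invalid (out of bounds, contains
    N, or not a CpG).
    """
    out = np.full(len(records), -1, dtype=np.int64)
    for contig, group in records.groupby("contig", sort=False):
        if contig not in genome:
            raise FormatError(f"contig {contig!r} not in genome")
        code = _encode(genome[contig])
        n = len(code)
        pos0 = group["pos"].to_numpy() - 1  # 0-based coordinate of the base
        minus = (group["strand"] == "-").to_numpy()
        # 0-based start of the plus-strand 6-mer window; a minus-strand
        # cytosine sits opposite the plus-strand G, one base downstream
        # of the plus-strand C
        w = np.where(minus, pos0 - 3, pos0 - 2)
        valid = (w >= 0) & (w + 6 <= n)
        b = np.zeros((6, len(group)), dtype=np.int64)
        wi = np.clip(w, 0, max(n - 6, 0))
        for k in range(6):
            b[k] = code[wi + k]
        valid &= (b < 4).all(axis=0)
        # plus-strand window must read N N C G N N
        valid &= (b[2] == 1) & (b[3] == 2)
        plus_idx = b[0] * 64 + b[1] * 16 + b[4] * 4 + b[5]
        minus_idx = (3 - b[5]) * 64 + (3 - b[4]) * 16 + (3 - b[1]) * 4 + (3 - b[0])
        idx = np.where(minus, minus_idx, plus_idx)
        out[records.index.get_indexer(group.index)] = np.where(valid, idx, -1)
    return out


def build_observed_profile(
    methylome: MethylomeTable,
    genome: GenomeSequence,
    min_coverage: int = 10,
) -> HexamerProfile:
    """Mean observed methylation per NNCGNN context.

    Cytosines below ``min_coverage`` or without a valid context are
    excluded; each retained cytosine contributes its level
    n_meth/(n_meth+n_unmeth) to an unweighted mean over the sites
    sharing its context.  Contexts with no sites carry NaN.
    """
    filtered = methylome.filter_coverage(min_coverage)
    if len(filtered) == 0:
        logger.warning("%s: no cytosines pass coverage %d; profile is all-missing",
                       methylome.sample_id, min_coverage)
        empty = pd.Series(np.nan, index=list(ALL_HEXAMERS))
        return HexamerProfile(methylome.sample_id, empty,
                              n_sites=pd.Series(0, index=list(ALL_HEXAMERS)))
    records = filtered.records
    ctx = contexts_for_records(genome, records)
    valid = ctx >= 0
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info("%s: excluded %d sites with invalid context",
                    methylome.sample_id, n_invalid)
    levels = (records["n_meth"] / (records["n_meth"] + records["n_unmeth"])).to_numpy()
    counts = np.bincount(ctx[valid], minlength=256)
    sums = np.bincount(ctx[valid], weights=levels[valid], minlength=256)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HexamerProfile(
        methylome.sample_id,
        pd.Series(means, index=list(ALL_HEXAMERS)),
        n_sites=pd.Series(counts, index=list(ALL_HEXAMERS)),
    )


# ---------------------------------------------------------------------------
# Profile transforms


def symmetrize_profile(profile: HexamerProfile) -> HexamerProfile:
    """Average each hexamer with its reverse complement.

    Reflects the two-fold symmetry of the CpG site; idempotent.  Requires
    a complete (no-NaN) profile.
    """
    if profile.values.isna().any():
        n = int(profile.values.isna().sum())
        raise FormatError(
            f"cannot symmetrize profile {profile.name!r}: {n} missing entries"
        )
    vals = profile.values
    rc_vals = pd.Series(
        vals.loc[[revcomp(h) for h in ALL_HEXAMERS]].to_numpy(), index=list(ALL_HEXAMERS)
    )
    out = (vals + rc_vals) / 2.0
    return HexamerProfile(profile.name, out, n_sites=profile.n_sites, symmetrized=True)


def rank_profile(profile: HexamerProfile, order: str = "descending") -> pd.Series:
    """Rank contexts by value; rank 1 is the highest value (most
    preferred), ties get the average of their covered ranks, missing
    entries stay NaN."""
    if order != "descending":
        raise ValueError("only descending ranking is defined")
    vals = profile.values
    mask = vals.notna()
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"profile {profile.name!r} has {int(mask.sum())} non-missing entries (< 3)"
        )
    ranks = pd.Series(np.nan, index=vals.index)
    ranks[mask] = stats.rankdata(-vals[mask].to_numpy(), method="average")
    return ranks


# ---------------------------------------------------------------------------
# Correlation


@dataclass
class CorrelationResult:
    sample_id: str
    enzyme: str
    r: float
    method: str
    n: int

    def __post_init__(self) -> None:
        assert self.n >= 3 and abs(self.r) <= 1 + 1e-12


def preference_correlation(
    observed: HexamerProfile,
    preference: HexamerProfile,
    method: str = "pearson_values",
) -> CorrelationResult:
    """Correlation between observed per-context methylation and an
    enzyme preference profile, over the contexts non-missing in both.

    ``pearson_values`` is Pearson r on the raw paired values;
    ``pearson_ranks`` is Pearson r on average-tie rank vectors, i.e.
    Spearman rho.
    """
    if method not in ("pearson_values", "pearson_ranks"):
        raise ValueError(f"unknown correlation method {method!r}")
    mask = observed.values.notna() & preference.values.notna()
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"only {n} hexamers shared between {observed.name!r} and {preference.name!r}"
        )
    x = observed.values[mask].to_numpy(dtype=float)
    y = preference.values[mask].to_numpy(dtype=float)
    if method == "pearson_ranks":
        x = stats.rankdata(x, method="average")
        y = stats.rankdata(y, method="average")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"zero variance in correlation operands ({observed.name!r} vs "
            f"{preference.name!r}); r is undefined"
        )
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(observed.name, preference.name, r, method, n)


def correlation_matrix(
    samples: list[MethylomeTable],
    genome: GenomeSequence,
    enzymes: list[HexamerProfile],
    method: str = "pearson_values",
    min_coverage: int = 10,
) -> pd.DataFrame:
    """One correlation per (sample, enzyme), in sample-major order.

    Returns a DataFrame with columns sample_id, enzyme, method, n, r.
    """
    rows = []
    for methylome in samples:
        observed = build_observed_profile(methylome, genome, min_coverage=min_coverage)
        for enzyme in enzymes:
            res = preference_correlation(observed, enzyme, method=method)
            rows.append(
                {"sample_id": res.sample_id, "enzyme": res.enzyme,
                 "method": res.method, "n": res.n, "r": res.r}
            )
    return pd.DataFrame(rows, columns=["sample_id", "enzyme", "method", "n", "r"])


# ---------------------------------------------------------------------------
# Model / Results


class ContextPreferenceModel:
    """Correlates observed WGBS methylation with enzyme flanking
    preferences, per sample.

    Parameters
    ----------
    samples
        Methylome tables (one per sample/timepoint).
    genome
        The reference the samples were called against.
    enzymes
        In-vitro preference profiles, one per enzyme.
    symmetrize
        Enzyme names whose profiles are averaged with their reverse
        complements before correlating (the de-novo methyltransferases
        act on a two-fold-symmetric site; their published preference
        tables are conventionally symmetrized).
    min_coverage
        Per-cytosine read-coverage floor.
    """

    def __init__(
        self,
        samples: list[MethylomeTable],
        genome: GenomeSequence,
        enzymes: list[HexamerProfile],
        symmetrize: tuple[str, ...] = ("DNMT3A", "DNMT3B"),
        min_coverage: int = 10,
    ):
        self.samples = samples
        self.genome = genome
        sym = {s.upper() for s in symmetrize}
        self.enzymes = [
            symmetrize_profile(e) if e.name.upper() in sym and not e.symmetrized else e
            for e in enzymes
        ]
        self.min_coverage = min_coverage

    def fit(self, method: str = "pearson_values") -> "ContextPreferenceResults":
        profiles = {
            m.sample_id: build_observed_profile(m, self.genome, self.min_coverage)
            for m in self.samples
        }
        rows = []
        for observed in profiles.values():
            for enzyme in self.enzymes:
                res = preference_correlation(observed, enzyme, method=method)
                rows.append(
                    {"sample_id": res.sample_id, "enzyme": res.enzyme,
                     "method": res.method, "n": res.n, "r": res.r}
                )
        table = pd.DataFrame(rows, columns=["sample_id", "enzyme", "method", "n", "r"])
        return ContextPreferenceResults(self, table, profiles, method)


class ContextPreferenceResults:
    """Correlation table plus the per-sample observed profiles."""

    def __init__(self, model, table: pd.DataFrame, observed_profiles, method: str):
        self.model = model
        self.table = table
        self.observed_profiles = observed_profiles
        self.method = method

    def r(self, sample_id: str, enzyme: str) -> float:
        sel = self.table[(self.table.sample_id == sample_id) & (self.table.enzyme == enzyme)]
        if sel.empty:
            raise KeyError((sample_id, enzyme))
        return float(sel["r"].iloc[0])

    def pivot(self) -> pd.DataFrame:
        """Samples x enzymes matrix of correlation coefficients."""
        return self.table.pivot(index="sample_id", columns="enzyme", values="r")

    def summary(self) -> str:
        lines = [
            "Flanking-context preference correlation",
            f"  method: {self.method}; min coverage: {self.model.min_coverage}",
            f"  {len(self.model.samples)} sample(s) x {len(self.model.enzymes)} enzyme profile(s)",
            "",
            self.pivot().round(3).to_string(),
        ]
        return "\n".join(lines)
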