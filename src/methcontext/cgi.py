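"""CpG-island histone-mark binning and methylation-loss coupling.

The question this analysis answers: do CpG islands carrying more of a
gene-body histone mark (H3K36me3, which recruits the de-novo DNA
methyltransferases) lose disproportionately more methylation when the
maintenance cofactor is depleted than when the maintenance enzyme
itself is depleted?  The statistic per CGI is

    dd = delta_u - delta_d

where delta_u / delta_d are the percentage-point methylation changes
after each depletion.  CGIs are ranked by input-normalized ChIP signal,
split into deciles for display, and the trend is tested with a Spearman
rank correlation across CGIs.

ChIP normalization follows standard read-count practice: CGIs with
fewer than 4 raw ChIP reads are dropped, counts get an offset of 0.5
(keeps ratios finite at zero input), are scaled to counts per 10
million mapped reads, and divided by the equally scaled input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, UndefinedStatisticError
from .formats_io import IntervalSet, MethylomeTable

logger = logging.getLogger(__name__)


def interval_read_count(reads: IntervalSet, targets: IntervalSet) -> pd.Series:
    """Reads overlapping each target by >= 1 bp (0-based half-open).

    A read may count toward several targets.  Returns counts indexed by
    target name, in target order.
    """
    import pyranges as pr

    t = targets.intervals
    r = reads.intervals
    gt = pr.PyRanges(t.rename(columns={"contig": "Chromosome", "start": "Start", "end": "End"})
                      [["Chromosome", "Start", "End"]].assign(Name=t["name"].to_numpy()))
    gr = pr.PyRanges(r.rename(columns={"contig": "Chromosome", "start": "Start", "end": "End"})
                      [["Chromosome", "Start", "End"]])
    counted = gt.count_overlaps(gr).df
    lookup = dict(zip(counted["Name"], counted["NumberOverlaps"]))
    return pd.Series([int(lookup.get(n, 0)) for n in t["name"]],
                     index=t["name"].to_numpy(), name="count")


def scaled_count(count, total: float) -> np.ndarray:
    """(count + 0.5) adjusted to counts per 10 million mapped reads."""
    return (np.asarray(count, dtype=float) + 0.5) * 1e7 / total


def normalize_cgi_signal(
    chip_counts: pd.Series,
    input_counts: pd.Series,
    chip_total: float,
    input_total: float,
    min_reads: int = 4,
) -> pd.DataFrame:
    """Input-normalized ChIP score per CGI.

    CGIs with fewer than ``min_reads`` raw ChIP reads are excluded (they
    are dominated by randomly mapped reads); CGIs with zero coverage in
    both ChIP and input are removed.  The +0.5 offset precedes scaling
    and normalization so the ratio stays finite and positive at zero
    input.
    """
    if chip_total <= 0 or input_total <= 0:
        raise ConfigurationError("mapped-read totals must be positive")
    df = pd.DataFrame({"raw_count": chip_counts, "input_count": input_counts})
    df = df.dropna()
    df["raw_count"] = df["raw_count"].astype(int)
    df["input_count"] = df["input_count"].astype(int)
    n0 = len(df)
    df = df[df["raw_count"] >= min_reads]
    df = df[(df["raw_count"] > 0) | (df["input_count"] > 0)]
    if len(df) < n0:
        logger.info("excluded %d/%d CGIs (min %d ChIP reads / zero coverage)",
                    n0 - len(df), n0, min_reads)
    df["norm_score"] = scaled_count(df["raw_count"], chip_total) / scaled_count(
        df["input_count"], input_total
    )
    return df


def cgi_methylation_delta(
    methylomes_t0: list[MethylomeTable],
    methylomes_tn: list[MethylomeTable],
    cgis: IntervalSet,
    min_coverage: int = 10,
) -> pd.Series:
    """Per-CGI methylation change (percentage points, later - baseline).

    Replicates are pooled per timepoint by summing counts; the CGI-level
    percentage uses all covered cytosines inside the interval.  CGIs
    without a covered cytosine at either timepoint get NaN.
    """
    from .dmr import pool_replicates, _assign_tiles

    pct = {}
    for label, group in (("t0", methylomes_t0), ("tn", methylomes_tn)):
        pooled = pool_replicates([m.filter_coverage(min_coverage) for m in group], label)
        assigned = _assign_tiles(pooled.records, cgis.intervals)
        agg = assigned.groupby("tile_idx")[["n_meth", "n_unmeth"]].sum()
        cov = agg["n_meth"] + agg["n_unmeth"]
        pct[label] = (100.0 * agg["n_meth"] / cov.where(cov > 0)).reindex(cgis.intervals.index)
    delta = pct["tn"] - pct["t0"]
    delta.index = cgis.intervals["name"].to_numpy()
    return delta.rename("delta")


def decile_bins(scores: pd.Series, keys: pd.DataFrame | None = None, n_bins: int = 10) -> pd.Series:
    """Rank-based equal-size bins (1 = lowest signal .. n_bins = highest).

    Sizes differ by at most one; any remainder goes to the lowest-index
    bins.  Ties are broken by (contig, start) via ``keys`` when given,
    else by index order, for determinism.
    """
    scores = scores.dropna()
    n = len(scores)
    if n < n_bins:
        raise InsufficientDataError(f"{n} scored CGIs < {n_bins} bins")
    order_df = pd.DataFrame({"score": scores})
    if keys is not None:
        order_df = order_df.join(keys.loc[scores.index, ["contig", "start"]])
        order_df = order_df.sort_values(["score", "contig", "start"], kind="mergesort")
    else:
        order_df = order_df.sort_values("score", kind="mergesort")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    return pd.Series(labels, index=order_df.index, name="bin").reindex(scores.index)


def bin_summary(dd: pd.Series, bins: pd.Series) -> pd.DataFrame:
    """Boxplot-style statistics of dd per bin.

    Quartiles use linear interpolation; whiskers sit at quartile -/+
    1.5 IQR, clipped to the observed data range.
    """
    rows = []
    for b in sorted(bins.dropna().unique()):
        vals = dd[bins == b].dropna().to_numpy()
        if len(vals) == 0:
            rows.append({"bin": int(b), "n": 0, "median": np.nan, "q25": np.nan,
                         "q75": np.nan, "whisker_lo": np.nan, "whisker_hi": np.nan})
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        iqr = q75 - q25
        rows.append({
            "bin": int(b), "n": len(vals), "median": med, "q25": q25, "q75": q75,
            "whisker_lo": max(q25 - 1.5 * iqr, vals.min()),
            "whisker_hi": min(q75 + 1.5 * iqr, vals.max()),
        })
    return pd.DataFrame(rows)


def spearman_trend_test(
    scores: pd.Series,
    dd: pd.Series,
    method: str = "t_approx",
    n_permutations: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between histone score and dd across CGIs.

    rho is Pearson r on average-tie ranks.  The two-sided p-value uses
    the t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of
    freedom, or a seeded permutation null when ``method='permutation'``
    (intended for n <= 30).
    """
    paired = pd.DataFrame({"x": scores, "y": dd}).dropna()
    n = len(paired)
    if n < 10:
        raise InsufficientDataError(f"{n} paired observations < 10")
    x = stats.rankdata(paired["x"].to_numpy(), method="average")
    y = stats.rankdata(paired["y"].to_numpy(), method="average")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant vector; Spearman rho undefined")
    rho = float(stats.pearsonr(x, y).statistic)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = stats.pearsonr(x, rng.permutation(y)).statistic
        p = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1))
    elif method == "t_approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, p


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class CgiHistoneModel:
    """Couples per-CGI histone-mark levels to depletion-specific
    methylation loss.

    ``u0/u4`` are the cofactor-depletion methylomes at baseline and
    after depletion, ``d0/d4`` the enzyme-depletion pair.  ChIP and
    input read sets (or precomputed counts) quantify the histone mark.
    """

    cgis: IntervalSet
    chip_counts: pd.Series
    input_counts: pd.Series
    chip_total: float
    input_total: float
    u0: list[MethylomeTable]
    u4: list[MethylomeTable]
    d0: list[MethylomeTable]
    d4: list[MethylomeTable]
    min_reads: int = 4
    min_coverage: int = 10
    n_bins: int = 10

    def fit(self, trend_method: str = "t_approx", seed: int = 0) -> "CgiHistoneResults":
        table = normalize_cgi_signal(
            self.chip_counts, self.input_counts,
            self.chip_total, self.input_total, self.min_reads,
        )
        delta_u = cgi_methylation_delta(self.u0, self.u4, self.cgis, self.min_coverage)
        delta_d = cgi_methylation_delta(self.d0, self.d4, self.cgis, self.min_coverage)
        table["delta_u"] = delta_u.reindex(table.index)
        table["delta_d"] = delta_d.reindex(table.index)
        table["dd"] = table["delta_u"] - table["delta_d"]
        keys = self.cgis.intervals.set_index("name")[["contig", "start"]]
        usable = table.dropna(subset=["norm_score", "dd"])
        bins = decile_bins(usable["norm_score"], keys=keys, n_bins=self.n_bins)
        table["bin"] = bins.reindex(table.index)
        rho, p = spearman_trend_test(usable["norm_score"], usable["dd"],
                                     method=trend_method, seed=seed)
        summary = bin_summary(table["dd"], table["bin"])
        return CgiHistoneResults(self, table, summary, rho, p, int(len(usable)))


class CgiHistoneResults:
    def __init__(self, model, table: pd.DataFrame, bin_table: pd.DataFrame,
                 rho: float, p_value: float, n: int):
        self.model = model
        self.table = table
        self.bin_table = bin_table
        self.rho = rho
        self.p_value = p_value
        self.n = n

    def summary(self) -> str:
        return "\n".join([
            "CGI histone-mark / methylation-loss coupling",
            f"  CGIs analysed: {self.n} (min {self.model.min_reads} ChIP reads)",
            f"  Spearman rho (score vs delta_u - delta_d): {self.rho:+.3f}"
            f"  (p = {self.p_value:.3g})",
            "",
            self.bin_table.round(2).to_string(index=False),
        ])
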