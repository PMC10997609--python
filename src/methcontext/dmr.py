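"""1-kb tile differential methylation analysis.

The genome is segmented into fixed-width non-overlapping tiles (1 kb by
default).  Within each condition, replicate cytosine reports are pooled
by summing read counts, each tile's methylation percentage is computed
from the pooled counts, and the two conditions are compared with a
two-sided Fisher exact test on the pooled 2x2 count table.  Tiles with a
methylation difference beyond +/-25 percentage points and a
Benjamini-Hochberg q-value below 0.01 are called hyper-/hypomethylated
(DMRs).

:class:`TileDMRModel` is the user-facing entry point; its ``fit()``
returns :class:`TileDMRResults` with the per-tile table, DMR calls and
summary counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, UndefinedStatisticError
from .formats_io import GenomeSequence, IntervalSet, MethylomeTable

logger = logging.getLogger(__name__)


def tile_genome(genome: GenomeSequence, width: int = 1000) -> IntervalSet:
    """Adjacent non-overlapping tiles covering every contig.

    Tiles are [k*width, (k+1)*width) per contig with the terminal tile
    truncated at the contig end; named ``contig:start-end``.
    """
    if width < 1:
        raise ConfigurationError("tile width must be >= 1")
    frames = []
    for name in genome.names:
        length = genome.length(name)
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        frames.append(pd.DataFrame({"contig": name, "start": starts, "end": ends}))
    return IntervalSet(pd.concat(frames, ignore_index=True))


def pool_replicates(methylomes: list[MethylomeTable], sample_id: str) -> MethylomeTable:
    """Sum read counts across replicates at each (contig, pos, strand)."""
    if not methylomes:
        raise ConfigurationError("cannot pool an empty replicate list")
    df = pd.concat([m.records for m in methylomes], ignore_index=True)
    pooled = (
        df.groupby(["contig", "pos", "strand"], as_index=False, sort=True)[["n_meth", "n_unmeth"]]
        .sum()
    )
    return MethylomeTable(sample_id, pooled)


def aggregate_tile_counts(
    methylomes_a: list[MethylomeTable],
    methylomes_b: list[MethylomeTable],
    tiles: IntervalSet,
    min_coverage: int = 10,
    min_cpg: int = 3,
) -> pd.DataFrame:
    """Pooled per-tile counts for two conditions.

    Replicates within a condition are pooled by summing counts.  A
    cytosine at 1-based position p belongs to the tile containing p-1 in
    0-based space.  Tiles with fewer than ``min_cpg`` covered cytosines
    in either condition are dropped.  ``diff`` is the methylation
    percentage of condition B minus condition A, from pooled counts.

    Reports are usually coverage-filtered on load
    (:func:`methcontext.formats_io.read_cytosine_report` applies the
    >= 10-read rule); the per-cytosine filter is re-applied here at
    ``min_coverage`` before pooling, which is a no-op on pre-filtered
    input.
    """
    if not methylomes_a or not methylomes_b:
        raise ConfigurationError("both conditions need at least one methylome")
    pooled_a = pool_replicates([m.filter_coverage(min_coverage) for m in methylomes_a], "a")
    pooled_b = pool_replicates([m.filter_coverage(min_coverage) for m in methylomes_b], "b")

    tile_df = tiles.intervals
    per_cond = {}
    for label, pooled in (("a", pooled_a), ("b", pooled_b)):
        rec = pooled.records
        assigned = _assign_tiles(rec, tile_df)
        grouped = assigned.groupby("tile_idx")
        agg = grouped.agg(
            n_cpg=("pos", "size"), meth=("n_meth", "sum"), unmeth=("n_unmeth", "sum")
        )
        per_cond[label] = agg

    table = tile_df.copy()
    for label, agg in per_cond.items():
        table[f"n_cpg_{label}"] = agg["n_cpg"].reindex(table.index).fillna(0).astype(int)
        table[f"meth_{label}"] = agg["meth"].reindex(table.index).fillna(0).astype(int)
        table[f"unmeth_{label}"] = agg["unmeth"].reindex(table.index).fillna(0).astype(int)

    eligible = (table["n_cpg_a"] >= min_cpg) & (table["n_cpg_b"] >= min_cpg)
    dropped = int((~eligible).sum())
    if dropped:
        logger.info("dropped %d/%d tiles with < %d covered CpGs in a condition",
                    dropped, len(table), min_cpg)
    table = table.loc[eligible].reset_index(drop=True)

    cov_a = table["meth_a"] + table["unmeth_a"]
    cov_b = table["meth_b"] + table["unmeth_b"]
    table["diff"] = (
        100.0 * table["meth_b"] / cov_b.where(cov_b > 0)
        - 100.0 * table["meth_a"] / cov_a.where(cov_a > 0)
    )
    return table


def _assign_tiles(records: pd.DataFrame, tile_df: pd.DataFrame) -> pd.DataFrame:
    """Attach the index of the containing tile to each cytosine record."""
    out = []
    for contig, group in records.groupby("contig", sort=False):
        tiles_c = tile_df[tile_df["contig"] == contig]
        if tiles_c.empty:
            continue
        starts = tiles_c["start"].to_numpy()
        ends = tiles_c["end"].to_numpy()
        pos0 = group["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        g = group.loc[inside].copy()
        g["tile_idx"] = tiles_c.index.to_numpy()[idx[inside]]
        out.append(g)
    if not out:
        return records.iloc[0:0].assign(tile_idx=pd.Series(dtype=np.int64))
    return pd.concat(out)


def test_tile(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one tile's pooled 2x2 count table.

    Defined as the sum of hypergeometric probabilities, over all tables
    with the observed margins, of tables no more probable than the
    observed one.
    """
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        raise UndefinedStatisticError("zero pooled coverage in a condition")
    _, p = stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]],
                              alternative="two-sided")
    return float(min(p, 1.0))


def _fisher_vector(table: pd.DataFrame) -> np.ndarray:
    p = np.empty(len(table), dtype=float)
    cols = ["meth_a", "unmeth_a", "meth_b", "unmeth_b"]
    for i, (ma, ua, mb, ub) in enumerate(table[cols].itertuples(index=False)):
        p[i] = test_tile(ma, ua, mb, ub)
    return p


def call_dmrs(
    tiles: pd.DataFrame,
    diff_threshold: float = 25.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Classify tiles as hypo / hyper / ns.

    Fisher p-values are corrected with Benjamini-Hochberg over all
    tested tiles; ``hypo`` requires diff <= -diff_threshold and
    q < q_threshold, ``hyper`` the mirror image.
    """
    out = tiles.copy()
    if out.empty:
        out["p_value"] = out["q_value"] = np.nan
        out["class"] = pd.Series(dtype=str)
        return out
    out["p_value"] = _fisher_vector(out)
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    significant = out["q_value"] < q_threshold
    out["class"] = "ns"
    out.loc[significant & (out["diff"] <= -diff_threshold), "class"] = "hypo"
    out.loc[significant & (out["diff"] >= diff_threshold), "class"] = "hyper"
    out = out.sort_values(["contig", "start"], kind="mergesort").reset_index(drop=True)
    counts = out["class"].value_counts()
    logger.info("DMR calls: %d hypo, %d hyper, %d ns",
                counts.get("hypo", 0), counts.get("hyper", 0), counts.get("ns", 0))
    return out


def overlap_dmr_sets(sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn-style membership counts over named DMR sets.

    Each input DataFrame needs a ``name`` column identifying tiles (the
    same tiling across sets).  Returns one row per non-empty membership
    combination with its tile count.
    """
    members = {label: set(df["name"]) for label, df in sets.items()}
    labels = list(members)
    universe = set().union(*members.values()) if members else set()
    rows = []
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = set(universe)
            for lab in combo:
                inside &= members[lab]
            for lab in labels:
                if lab not in combo:
                    inside -= members[lab]
            rows.append({"sets": "&".join(combo), "n_tiles": len(inside)})
    return pd.DataFrame(rows)


def annotate_tiles(
    dmrs: pd.DataFrame,
    genes: IntervalSet,
    promoter_flank: int = 1000,
) -> pd.DataFrame:
    """Label each tile promoter / gene_body / intergenic.

    The promoter is TSS +/- ``promoter_flank`` (TSS = gene start on the
    plus strand, gene end on the minus strand; genes without strand are
    treated as plus).  Priority on any overlap: promoter > gene_body >
    intergenic.
    """
    gene_df = genes.intervals
    strand = gene_df["strand"] if "strand" in gene_df.columns else pd.Series("+", index=gene_df.index)
    tss = np.where(strand == "-", gene_df["end"] - 1, gene_df["start"])
    prom_start = np.maximum(tss - promoter_flank, 0)
    prom_end = tss + promoter_flank + 1

    out = dmrs.copy()
    out["feature"] = "intergenic"
    for contig, group in out.groupby("contig", sort=False):
        on_contig = gene_df["contig"] == contig
        t_start = group["start"].to_numpy()[:, None]
        t_end = group["end"].to_numpy()[:, None]
        g_start = gene_df.loc[on_contig, "start"].to_numpy()[None, :]
        g_end = gene_df.loc[on_contig, "end"].to_numpy()[None, :]
        p_start = prom_start[on_contig.to_numpy()][None, :]
        p_end = prom_end[on_contig.to_numpy()][None, :]
        in_gene = ((t_start < g_end) & (t_end > g_start)).any(axis=1)
        in_prom = ((t_start < p_end) & (t_end > p_start)).any(axis=1)
        labels = np.where(in_prom, "promoter", np.where(in_gene, "gene_body", "intergenic"))
        out.loc[group.index, "feature"] = labels
    return out


# ---------------------------------------------------------------------------
# Model / Results


@dataclass
class TileDMRModel:
    """Two-condition differential methylation on fixed-width tiles.

    Parameters mirror the analysis defaults: 1-kb tiles, >= 3 covered
    CpGs per condition per tile, DMRs at |diff| >= 25 percentage points
    and q < 0.01.
    """

    methylomes_a: list[MethylomeTable]
    methylomes_b: list[MethylomeTable]
    genome: GenomeSequence
    width: int = 1000
    min_coverage: int = 10
    min_cpg: int = 3

    def fit(self, diff_threshold: float = 25.0, q_threshold: float = 0.01) -> "TileDMRResults":
        tiles = tile_genome(self.genome, self.width)
        table = aggregate_tile_counts(
            self.methylomes_a, self.methylomes_b, tiles,
            min_coverage=self.min_coverage, min_cpg=self.min_cpg,
        )
        calls = call_dmrs(table, diff_threshold=diff_threshold, q_threshold=q_threshold)
        return TileDMRResults(self, calls, diff_threshold, q_threshold)


class TileDMRResults:
    def __init__(self, model: TileDMRModel, table: pd.DataFrame,
                 diff_threshold: float, q_threshold: float):
        self.model = model
        self.table = table
        self.diff_threshold = diff_threshold
        self.q_threshold = q_threshold

    @property
    def n_hypo(self) -> int:
        return int((self.table["class"] == "hypo").sum())

    @property
    def n_hyper(self) -> int:
        return int((self.table["class"] == "hyper").sum())

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["class"] != "ns"].reset_index(drop=True)

    def annotate(self, genes: IntervalSet, promoter_flank: int = 1000) -> pd.DataFrame:
        return annotate_tiles(self.table, genes, promoter_flank)

    def summary(self) -> str:
        n = len(self.table)
        return "\n".join([
            "Tile differential methylation",
            f"  width: {self.model.width} bp; min CpGs/tile/condition: {self.model.min_cpg}",
            f"  thresholds: |diff| >= {self.diff_threshold} pp, q < {self.q_threshold}",
            f"  tiles tested: {n}",
            f"  hypomethylated: {self.n_hypo}  hypermethylated: {self.n_hyper}  "
            f"ns: {n - self.n_hypo - self.n_hyper}",
        ])
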