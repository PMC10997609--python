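"""Synthetic genome / methylome / ChIP generator.

The generative model is built so that the pipeline's statistics are its
natural estimands:

* a random genome at a stated GC content, with CpG-dense island blocks;
* per strand-cytosine true methylation on the logit scale,

      m = logistic(alpha0 + sum_e delta_e * w_e * z_e(context) + eps),

  where z_e is the enzyme-e preference profile standardized over the
  256 contexts, w_e the enzyme's weight in shaping the methylome,
  delta_e in [0,1] its residual activity at a depletion timepoint, and
  eps ~ N(0, sigma^2) i.i.d. per site;
* at coupled depletion timepoints, sites inside CGI j additionally lose
  methylation in proportion to the island's histone level:
  m <- m * (1 - beta * h~_j) with h~ the min-max normalized latent
  histone score;
* reads: coverage ~ Poisson(lambda) (zero-coverage sites omitted),
  n_meth ~ Binomial(coverage, m*(1-0) + (1-m)*conversion_failure) --
  bisulfite conversion failure inflates apparent methylation of
  unmethylated molecules only;
* ChIP: latent h_j ~ LogNormal(0,1) per CGI, chip reads ~
  Poisson(depth * len/1kb * h_j), input ~ Poisson(depth * len/1kb).

Identical :class:`SimConfig` (including seed) gives byte-identical
outputs; every draw goes through one documented-order generator chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .context import ALL_HEXAMERS, HexamerProfile, contexts_for_records, symmetrize_profile
from .errors import ConfigurationError
from .formats_io import GenomeSequence, IntervalSet, MethylomeTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Full parameterization of the synthetic data generators.

    Defaults emulate a deeply sequenced human-like degron experiment:
    GC content 0.41, ~80% genome-wide methylation (alpha0 = 1.39 in
    logit units), 30x mean coverage, a methylome shaped mostly by the
    maintenance enzyme and one de-novo enzyme, and cofactor depletion
    reducing all enzymatic activities at once while enzyme depletion
    removes only the maintenance activity.
    """

    seed: int = 0
    genome_length: int = 500_000
    n_contigs: int = 2
    gc_content: float = 0.41
    cgi_count: int = 100
    cgi_length: int = 1000
    cgi_cpg_density: float = 0.10
    enzyme_weights: dict[str, float] = field(
        default_factory=lambda: {"DNMT1": 1.0, "DNMT3A": 0.8, "DNMT3B": 0.1}
    )
    baseline: float = 1.39
    site_noise_sd: float = 0.5
    coverage_mean: float = 30.0
    depletion_factors: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "day0": {},
            "day4_enzyme": {"DNMT1": 0.0},
            "day4_cofactor": {"DNMT1": 0.05, "DNMT3A": 0.05, "DNMT3B": 0.05},
        }
    )
    coupled_timepoints: tuple[str, ...] = ("day4_cofactor",)
    histone_coupling: float = 0.4
    chip_depth: float = 50.0
    conversion_failure: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (("gc_content", self.gc_content),
                            ("cgi_cpg_density", self.cgi_cpg_density),
                            ("conversion_failure", self.conversion_failure)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be > 0")
        if self.site_noise_sd < 0 or self.histone_coupling < 0:
            raise ConfigurationError("site_noise_sd and histone_coupling must be >= 0")
        if self.genome_length < 1 or self.n_contigs < 1:
            raise ConfigurationError("genome_length and n_contigs must be >= 1")
        for tp, factors in self.depletion_factors.items():
            for enzyme, delta in factors.items():
                if enzyme not in self.enzyme_weights:
                    raise ConfigurationError(
                        f"depletion timepoint {tp!r} names unknown enzyme {enzyme!r}"
                    )
                if not 0.0 <= delta <= 1.0:
                    raise ConfigurationError("depletion factors must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupled_timepoints"] = list(self.coupled_timepoints)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "coupled_timepoints" in data:
            data = {**data, "coupled_timepoints": tuple(data["coupled_timepoints"])}
        return cls(**data)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Named independent stream derived from the config seed.

    Keyed by a stable CRC of the stream name so runs are reproducible
    across processes.
    """
    import zlib

    key = zlib.crc32(stream.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((config.seed, key)))


def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, IntervalSet]:
    """Random genome plus non-overlapping CpG-island intervals.

    Background bases are i.i.d. at the stated GC content; island blocks
    get explicit CpG dinucleotides planted at ``cgi_cpg_density`` (per
    bp, i.e. density * length CpGs per island).
    """
    rng = np.random.default_rng(config.seed)
    per_contig = config.genome_length // config.n_contigs
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: dict[str, str] = {}
    cgi_rows = []
    cgi_per_contig = np.diff(np.linspace(0, config.cgi_count, config.n_contigs + 1).astype(int))
    for ci in range(config.n_contigs):
        name = f"chr{ci + 1}"
        seq = rng.choice(4, size=per_contig, p=probs).astype(np.int8)
        n_cgi = int(cgi_per_contig[ci])
        if n_cgi:
            # evenly spaced, non-overlapping island anchors
            lo, hi = config.cgi_length, per_contig - 2 * config.cgi_length
            if hi < lo or (n_cgi > 1 and (hi - lo) / (n_cgi - 1) < config.cgi_length):
                raise ConfigurationError(
                    "CGI total length exceeds genome capacity "
                    f"({n_cgi} x {config.cgi_length} bp on a {per_contig} bp contig)"
                )
            slots = np.linspace(lo, hi, n_cgi).astype(np.int64)
            for start in slots:
                end = start + config.cgi_length
                n_cpg = max(int(round(config.cgi_cpg_density * config.cgi_length)), 1)
                offsets = rng.choice(np.arange(0, config.cgi_length - 1, 2),
                                     size=min(n_cpg, (config.cgi_length - 1) // 2),
                                     replace=False)
                seq[start + offsets] = 1      # C
                seq[start + offsets + 1] = 2  # G
                cgi_rows.append({"contig": name, "start": int(start), "end": int(end),
                                 "name": f"CGI_{len(cgi_rows) + 1}"})
        contigs[name] = "".join(_BASES[seq])
    cgis = IntervalSet(pd.DataFrame(cgi_rows)) if cgi_rows else EmptyIntervalSet()
    return GenomeSequence(contigs), cgis


class EmptyIntervalSet(IntervalSet):
    """An interval set with no intervals (IntervalSet forbids building
    one from an empty frame via the public constructor)."""

    def __init__(self):
        df = pd.DataFrame({"contig": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64),
                           "name": pd.Series(dtype=str)})
        object.__setattr__(self, "intervals", df)

    def __post_init__(self):  # pragma: no cover
        pass


def simulate_preference_profile(seed: int, symmetric: bool = False,
                                name: str | None = None) -> HexamerProfile:
    """Synthetic stand-in for a published in-vitro preference table.

    256 i.i.d. standard-normal draws, min-max rescaled to [0, 1];
    optionally symmetrized over reverse-complement pairs.
    """
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal(256)
    vals = (vals - vals.min()) / (vals.max() - vals.min())
    profile = HexamerProfile(name or f"pref_seed{seed}",
                             pd.Series(vals, index=list(ALL_HEXAMERS)))
    if symmetric:
        profile = symmetrize_profile(profile)
    return profile


def _cpg_sites(genome: GenomeSequence) -> pd.DataFrame:
    """All strand-cytosines of every CpG, as cytosine-report coordinates."""
    rows = []
    for name in genome.names:
        seq = np.frombuffer(genome[name].encode("ascii"), dtype=np.uint8)
        cpg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        plus = pd.DataFrame({"contig": name, "pos": cpg + 1, "strand": "+"})
        minus = pd.DataFrame({"contig": name, "pos": cpg + 2, "strand": "-"})
        rows.append(pd.concat([plus, minus], ignore_index=True))
    df = pd.concat(rows, ignore_index=True)
    return df.sort_values(["contig", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def true_methylation_levels(
    genome: GenomeSequence,
    cgis: IntervalSet,
    profiles: dict[str, HexamerProfile],
    config: SimConfig,
    timepoint: str,
    histone_norm: pd.Series | None = None,
    noise: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per strand-cytosine true methylation level for one timepoint.

    Returns the site table (contig, pos, strand) with columns ``ctx``
    (hexamer index, -1 invalid) and ``m`` (true level; NaN at invalid
    contexts).  ``noise`` allows sharing per-site logit noise across
    timepoints (persistent-noise mode).
    """
    if timepoint not in config.depletion_factors:
        raise ConfigurationError(f"unknown timepoint {timepoint!r}")
    for enzyme in config.enzyme_weights:
        if enzyme not in profiles:
            raise ConfigurationError(f"no preference profile for enzyme {enzyme!r}")
    sites = _cpg_sites(genome)
    ctx = contexts_for_records(genome, sites)
    sites["ctx"] = ctx
    deltas = config.depletion_factors[timepoint]
    logit = np.full(len(sites), config.baseline, dtype=float)
    valid = ctx >= 0
    for enzyme, weight in config.enzyme_weights.items():
        vals = profiles[enzyme].values.to_numpy(dtype=float)
        z = (vals - vals.mean()) / vals.std()
        delta = deltas.get(enzyme, 1.0)
        logit[valid] += delta * weight * z[ctx[valid]]
    if noise is None and config.site_noise_sd > 0:
        noise_rng = _rng(config, f"noise:{timepoint}")
        noise = noise_rng.normal(0.0, config.site_noise_sd, size=len(sites))
    if noise is not None and config.site_noise_sd > 0:
        logit = logit + noise
    m = 1.0 / (1.0 + np.exp(-logit))
    if timepoint in config.coupled_timepoints and config.histone_coupling > 0 and histone_norm is not None:
        m = _apply_histone_coupling(sites, m, cgis, histone_norm, config.histone_coupling)
    m = np.where(valid, m, np.nan)
    sites["m"] = m
    return sites


def _apply_histone_coupling(sites: pd.DataFrame, m: np.ndarray, cgis: IntervalSet,
                            histone_norm: pd.Series, beta: float) -> np.ndarray:
    from .dmr import _assign_tiles

    assigned = _assign_tiles(sites, cgis.intervals)
    m = m.copy()
    if assigned.empty:
        return m
    names = cgis.intervals.loc[assigned["tile_idx"], "name"].to_numpy()
    h = histone_norm.reindex(names).to_numpy(dtype=float)
    h = np.nan_to_num(h, nan=0.0)
    rows = sites.index.get_indexer(assigned.index)
    m[rows] = m[rows] * (1.0 - beta * h)
    return m


def simulate_methylome(
    genome: GenomeSequence,
    cgis: IntervalSet,
    profiles: dict[str, HexamerProfile],
    config: SimConfig,
    timepoint: str,
    histone_norm: pd.Series | None = None,
    sample_id: str | None = None,
) -> MethylomeTable:
    """Cytosine report for one sample/timepoint under the logit-linear
    mixture model (see module docstring)."""
    sites = true_methylation_levels(genome, cgis, profiles, config, timepoint, histone_norm)
    valid = sites["m"].notna().to_numpy()
    sites = sites.loc[valid].reset_index(drop=True)
    m = sites["m"].to_numpy()
    read_rng = _rng(config, f"reads:{timepoint}")
    coverage = read_rng.poisson(config.coverage_mean, size=len(sites))
    covered = coverage > 0
    f = config.conversion_failure
    p_obs = m * 1.0 + (1.0 - m) * f
    n_meth = read_rng.binomial(np.where(covered, coverage, 1), np.clip(p_obs, 0, 1))
    df = pd.DataFrame({
        "contig": sites["contig"], "pos": sites["pos"], "strand": sites["strand"],
        "n_meth": np.where(covered, n_meth, 0),
        "n_unmeth": np.where(covered, coverage - n_meth, 0),
    }).loc[covered]
    return MethylomeTable(sample_id or timepoint, df)


def simulate_chip(
    cgis: IntervalSet,
    config: SimConfig,
    coupled: bool = True,
) -> dict:
    """Latent histone scores and ChIP/input read counts per CGI.

    Returns a dict with keys ``histone`` (latent h), ``histone_norm``
    (min-max normalized; drives the methylome coupling when coupled),
    ``chip_counts``, ``input_counts``, ``chip_total``, ``input_total``.
    """
    rng = _rng(config, "chip")
    n = len(cgis)
    names = cgis.intervals["name"].to_numpy()
    h = rng.lognormal(0.0, 1.0, size=n)
    lengths = cgis.lengths().to_numpy(dtype=float)
    lam = config.chip_depth * lengths / 1000.0
    chip = rng.poisson(lam * h)
    inp = rng.poisson(lam)
    if n and h.max() > h.min():
        h_norm = (h - h.min()) / (h.max() - h.min())
    else:
        h_norm = np.zeros(n)
    background = int(10 * config.chip_depth)  # reads mapped outside CGIs
    return {
        "histone": pd.Series(h, index=names, name="histone"),
        "histone_norm": pd.Series(h_norm if coupled else np.zeros(n), index=names,
                                  name="histone_norm"),
        "chip_counts": pd.Series(chip, index=names, name="chip"),
        "input_counts": pd.Series(inp, index=names, name="input"),
        "chip_total": float(chip.sum() + background),
        "input_total": float(inp.sum() + background),
    }
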