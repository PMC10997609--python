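"""End-to-end orchestration: simulate -> context -> dmr -> cgi.

A single YAML config drives every stage; each run writes its TSV
outputs plus a manifest recording the tool version, a config hash, the
seed and checksums of every file written, so two runs from the same
config can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cgi import CgiHistoneModel, interval_read_count
from .context import ContextPreferenceModel
from .dmr import TileDMRModel
from .errors import ConfigurationError
from .formats_io import (
    IntervalSet,
    write_bed,
    write_cytosine_report,
    write_fasta,
    write_tsv,
)
from .simulate import SimConfig, simulate_chip, simulate_genome, simulate_methylome, simulate_preference_profile

logger = logging.getLogger(__name__)

STAGES = ("simulate", "context", "dmr", "cgi")

DEFAULT_ANALYSIS = {
    "min_coverage": 10,
    "correlation_method": "pearson_values",
    "symmetrize": ["DNMT3A", "DNMT3B"],
    "tile_width": 1000,
    "diff_threshold": 25.0,
    "q_threshold": 0.01,
    "min_cpg": 3,
    "min_reads": 4,
    "n_bins": 10,
}


def demo_config(seed: int = 0) -> dict:
    """The shipped demo parameterization: a small two-contig genome, the
    three-enzyme methylome, one enzyme-depletion and one
    cofactor-depletion timepoint, and a coupled ChIP track."""
    return {
        "simulate": SimConfig(
            seed=seed,
            genome_length=400_000,
            n_contigs=2,
            cgi_count=120,
            cgi_length=800,
        ).to_dict(),
        "analysis": dict(DEFAULT_ANALYSIS),
    }


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_config(data)


def validate_config(data: dict) -> dict:
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(data) - {"simulate", "analysis"}
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    if "simulate" not in data:
        raise ConfigurationError("config missing required section 'simulate'")
    SimConfig.from_dict(data["simulate"])  # raises naming the offending key
    analysis = dict(DEFAULT_ANALYSIS)
    extra = set(data.get("analysis", {})) - set(DEFAULT_ANALYSIS)
    if extra:
        raise ConfigurationError(f"unknown analysis key(s): {sorted(extra)}")
    analysis.update(data.get("analysis", {}))
    data = {"simulate": data["simulate"], "analysis": analysis}
    return data


def config_hash(data: dict) -> str:
    """Stable under key reordering."""
    return hashlib.sha256(json.dumps(data, sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def record(self, path: str) -> None:
        self.outputs[os.path.basename(path)] = _sha256(path)

    def write(self, path: str) -> None:
        rows = [{"key": "version", "value": self.version},
                {"key": "config_hash", "value": self.config_hash},
                {"key": "seed", "value": str(self.seed)}]
        rows += [{"key": f"sha256:{name}", "value": digest}
                 for name, digest in sorted(self.outputs.items())]
        write_tsv(pd.DataFrame(rows), path)


def run_pipeline(config: dict, out_dir: str, stages: tuple[str, ...] = STAGES) -> RunManifest:
    """Execute the requested stages in dependency order.

    Only the fully synthetic path is orchestrated here (the analysis
    stages need the simulate stage's outputs); library users can feed
    their own files to the Model classes directly.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ConfigurationError(f"unknown stage {stage!r} (choose from {STAGES})")
    stages = tuple(s for s in STAGES if s in stages)
    if stages != (("simulate",) + tuple(s for s in stages if s != "simulate")):
        raise ConfigurationError("analysis stages require the simulate stage")

    os.makedirs(out_dir, exist_ok=True)
    config = validate_config(config)
    sim = SimConfig.from_dict(config["simulate"])
    opts = config["analysis"]
    manifest = RunManifest(__version__, config_hash(config), sim.seed)

    def emit(name: str, writer, *args) -> str:
        path = os.path.join(out_dir, name)
        writer(*args, path)
        manifest.record(path)
        return path

    logger.info("simulate: genome %d bp, %d CGIs, seed %d",
                sim.genome_length, sim.cgi_count, sim.seed)
    genome, cgis = simulate_genome(sim)
    profiles = {
        enzyme: simulate_preference_profile(
            sim.seed + 1000 + i,
            symmetric=enzyme.upper() in {s.upper() for s in opts["symmetrize"]},
            name=enzyme,
        )
        for i, enzyme in enumerate(sorted(sim.enzyme_weights))
    }
    chip = simulate_chip(cgis, sim, coupled=True)
    methylomes = {}
    for timepoint in sim.depletion_factors:
        methylomes[timepoint] = simulate_methylome(
            genome, cgis, profiles, sim, timepoint,
            histone_norm=chip["histone_norm"],
        )
    emit("genome.fa", write_fasta, genome)
    emit("cgis.bed", write_bed, cgis)
    for enzyme, profile in profiles.items():
        emit(f"pref_{enzyme}.tsv", write_tsv, profile.to_frame())
    for timepoint, methylome in methylomes.items():
        emit(f"report_{timepoint}.tsv", write_cytosine_report, methylome)
    chip_table = pd.DataFrame({
        "cgi": chip["chip_counts"].index,
        "chip_count": chip["chip_counts"].to_numpy(),
        "input_count": chip["input_counts"].to_numpy(),
    })
    emit("chip_counts.tsv", write_tsv, chip_table)

    timepoints = list(sim.depletion_factors)
    baseline_tp = timepoints[0]
    depleted = [tp for tp in timepoints[1:]]

    if "context" in stages:
        model = ContextPreferenceModel(
            list(methylomes.values()), genome, list(profiles.values()),
            symmetrize=tuple(opts["symmetrize"]), min_coverage=opts["min_coverage"],
        )
        results = model.fit(method=opts["correlation_method"])
        emit("context_correlations.tsv", write_tsv, results.table)
        logger.info("context:\n%s", results.summary())

    if "dmr" in stages and depleted:
        model = TileDMRModel(
            [methylomes[baseline_tp]], [methylomes[depleted[-1]]], genome,
            width=opts["tile_width"], min_coverage=opts["min_coverage"],
            min_cpg=opts["min_cpg"],
        )
        results = model.fit(diff_threshold=opts["diff_threshold"],
                            q_threshold=opts["q_threshold"])
        out = results.table.copy()
        emit("dmr_tiles.tsv", write_tsv, out)
        logger.info("dmr:\n%s", results.summary())

    if "cgi" in stages and len(depleted) >= 2 and len(cgis) >= opts["n_bins"]:
        # convention: last timepoint is the cofactor depletion, the one
        # before it the enzyme depletion
        model = CgiHistoneModel(
            cgis, chip["chip_counts"], chip["input_counts"],
            chip["chip_total"], chip["input_total"],
            u0=[methylomes[baseline_tp]], u4=[methylomes[depleted[-1]]],
            d0=[methylomes[baseline_tp]], d4=[methylomes[depleted[-2]]],
            min_reads=opts["min_reads"], min_coverage=opts["min_coverage"],
            n_bins=opts["n_bins"],
        )
        results = model.fit()
        table = results.table.reset_index(names="cgi")
        emit("cgi_scores.tsv", write_tsv, table)
        emit("cgi_bin_summary.tsv", write_tsv, results.bin_table)
        logger.info("cgi:\n%s", results.summary())

    manifest_path = os.path.join(out_dir, "manifest.tsv")
    manifest.write(manifest_path)
    return manifest
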