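"""End-to-end pipeline: simulate -> quantify -> profile -> digest -> summarize.

A PipelineConfig (YAML-serializable) is validated against every stage's
preconditions before anything runs; each stage writes TSV/JSON outputs and
updates counters collected in a RunManifest.  Given fixed seeds all stage
outputs are byte-identical across reruns; the manifest differs only in
timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from telospect.assoc_stats import correlation_frame, correlation_table
from telospect.digest_sim import ENZYMES, digest
from telospect.io import read_fastq, write_fasta, write_fastq
from telospect.synthetic_data import (
    ArraySpec,
    GenomeSpec,
    ReadSimParams,
    build_genome,
    simulate_reads,
)
from telospect.telomere_quant import (
    ClassifierParams,
    build_reference,
    classify_read,
    estimate_abundance,
    quality_filter,
)
from telospect.variant_profile import (
    SNVCallParams,
    call_snvs,
    count_motifs,
    enumerate_variants,
    phase_read,
)

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20221011


@dataclass
class PipelineConfig:
    """Validated configuration for a full run on synthetic data."""

    motif: str = "TTTAGGG"
    reference_copies: int = 14
    genome_length_bp: int = 1_000_000
    arrays: tuple[tuple[int, ArraySpec], ...] = ()
    background_gc: float = 0.40
    n_reads: int = 100_000
    read_length: int = 150
    error_rate: float = 0.0
    paired: bool = False
    quality_model: str = "constant"
    genome_size_Mb_1C: float = 2000.0
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    snv: SNVCallParams = field(default_factory=SNVCallParams)
    extras: tuple[str, ...] = ("TTCAAGG",)
    enzymes: tuple[str, ...] = ("Tru1I", "TaqI", "HaeIII")
    high_mw_threshold: int = 10_000
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        """Run every stage's precondition checks before execution."""
        build_reference(self.motif, self.reference_copies)
        GenomeSpec(
            genome_length_bp=self.genome_length_bp,
            array_placements=self.arrays,
            background_gc=self.background_gc,
            seed=self.seed,
        )
        ReadSimParams(
            n_reads=self.n_reads,
            read_length=self.read_length,
            error_rate=self.error_rate,
            paired=self.paired,
            quality_model=self.quality_model,
            seed=self.seed,
        )
        if self.genome_size_Mb_1C <= 0:
            raise ValueError("genome_size_Mb_1C must be > 0")
        enumerate_variants(self.motif, self.extras)
        for e in self.enzymes:
            if e not in ENZYMES:
                raise ValueError(f"unknown enzyme {e}; known: {sorted(ENZYMES)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        arrays = tuple(
            (
                int(a["position"]),
                ArraySpec(
                    length_units=int(a["length_units"]),
                    variant_props={str(k): float(v) for k, v in a["variant_props"].items()},
                    interspersion=a.get("interspersion", "iid"),
                    mean_block_units=float(a.get("mean_block_units", 100.0)),
                ),
            )
            for a in raw.get("arrays", [])
        )
        kwargs = {
            k: raw[k]
            for k in (
                "motif",
                "reference_copies",
                "genome_length_bp",
                "background_gc",
                "n_reads",
                "read_length",
                "error_rate",
                "paired",
                "quality_model",
                "genome_size_Mb_1C",
                "high_mw_threshold",
                "seed",
            )
            if k in raw
        }
        if "extras" in raw:
            kwargs["extras"] = tuple(raw["extras"])
        if "enzymes" in raw:
            kwargs["enzymes"] = tuple(raw["enzymes"])
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierParams(**raw["classifier"])
        if "snv" in raw:
            kwargs["snv"] = SNVCallParams(**raw["snv"])
        return cls(arrays=arrays, **kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["arrays"] = [
            {"position": p, **dataclasses.asdict(a)} for p, a in self.arrays
        ]
        return d


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, versions, counters, outputs."""

    config: dict
    version: str
    counters: dict[str, int | float]
    outputs: list[str]
    started: float
    finished: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def quantify_fastq(
    records,
    motif: str = "TTTAGGG",
    copies: int = 14,
    params: ClassifierParams | None = None,
    genome_size_Mb_1C: float = 1.0,
):
    """Quality-filter and classify a FASTQ record stream; return (estimate, hits, counters).

    Counters conserve: total = passing + failed_quality.
    """
    params = params or ClassifierParams()
    ref = build_reference(motif, copies)
    total = passing = mapped = 0
    hits = []
    for rec in records:
        total += 1
        if not quality_filter(rec.quality, params):
            continue
        passing += 1
        hit = classify_read(rec.sequence, ref, params, read_id=rec.id)
        if hit is not None:
            mapped += 1
            hits.append((hit, rec.sequence))
    if passing == 0:
        raise ValueError("no reads passed the quality filter")
    est = estimate_abundance(mapped, passing, genome_size_Mb_1C, total_reads=total)
    counters = {
        "total_reads": total,
        "failed_quality": total - passing,
        "passing_reads": passing,
        "mapped_reads": mapped,
    }
    return est, hits, counters


def _log_binned_histogram(lengths, n_bins: int = 30) -> pd.DataFrame:
    """Fragment-length histogram on a log scale (gel-lane analogue)."""
    import numpy as np

    arr = np.asarray(lengths)
    lo, hi = max(1, arr.min()), arr.max()
    edges = np.logspace(np.log10(lo), np.log10(hi + 1), n_bins + 1)
    counts, edges = np.histogram(arr, bins=edges)
    mass, _ = np.histogram(arr, bins=edges, weights=arr)
    return pd.DataFrame(
        {"bin_low_bp": edges[:-1], "bin_high_bp": edges[1:], "n_fragments": counts, "bp_mass": mass}
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute simulation, quantification, profiling and digestion; write all outputs."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    counters: dict[str, int | float] = {}
    outputs: list[str] = []

    def emit(name: str):
        outputs.append(name)
        return outdir / name

    # 1. genome
    gspec = GenomeSpec(
        genome_length_bp=config.genome_length_bp,
        array_placements=config.arrays,
        background_gc=config.background_gc,
        seed=config.seed,
    )
    genome = build_genome(gspec)
    write_fasta([(genome.record_id, genome.sequence)], emit("genome.fa"))
    genome.truth_table().to_csv(emit("genome_truth.tsv"), sep="\t", index=False)
    counters["genome_bp"] = len(genome.sequence)
    counters["true_telomeric_bp"] = genome.telomeric_bp
    counters["true_gp_percent"] = genome.true_gp_percent
    logger.info("genome: %d bp, true GP %.4f%%", len(genome.sequence), genome.true_gp_percent)

    # 2. reads
    rparams = ReadSimParams(
        n_reads=config.n_reads,
        read_length=config.read_length,
        error_rate=config.error_rate,
        paired=config.paired,
        quality_model=config.quality_model,
        seed=config.seed + 1,
    )
    reads, truths = simulate_reads(genome, rparams)
    write_fastq(reads, emit("reads.fq"))
    pd.DataFrame(truths).to_csv(emit("read_truth.tsv"), sep="\t", index=False)
    counters["simulated_reads"] = len(reads)
    counters["true_telomeric_reads"] = sum(t.is_telomeric_majority for t in truths)

    # 3. quantify
    est, hits, qc = quantify_fastq(
        read_fastq(outdir / "reads.fq"),
        motif=config.motif,
        copies=config.reference_copies,
        params=config.classifier,
        genome_size_Mb_1C=config.genome_size_Mb_1C,
    )
    counters.update(qc)
    pd.DataFrame(
        [
            {
                "sample": "synthetic",
                "total_reads": est.total_reads,
                "passing_reads": est.passing_reads,
                "mapped_reads": est.mapped_reads,
                "GP_percent": est.GP,
                "genome_size_Mb": est.genome_size_Mb_1C,
                "abundance_Mb": est.abundance_Mb_1C,
            }
        ]
    ).to_csv(emit("abundance.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "orientation": h.orientation,
                "frame": h.frame,
                "run_units": h.run_units,
                "telomeric_fraction": round(h.telomeric_fraction, 4),
                "identity": round(h.identity, 4),
            }
            for h, _ in hits
        ]
    ).to_csv(emit("hits.tsv"), sep="\t", index=False)
    logger.info("quantify: GP %.4f%% (%d/%d reads)", est.GP, est.mapped_reads, est.passing_reads)

    # 4. variant profile + SNVs
    ref = build_reference(config.motif, config.reference_copies)
    variants = enumerate_variants(config.motif, config.extras)
    phased = [phase_read(seq, config.motif, hit=h, read_id=h.read_id) for h, seq in hits]
    if phased:
        spectrum = count_motifs(phased, variants)
        pd.DataFrame(
            [
                {
                    "motif": m,
                    "count": spectrum.counts[m],
                    "frequency_percent": round(spectrum.frequencies[m], 4),
                    "abundant": spectrum.abundant[m],
                }
                for m in variants.full_list
            ]
        ).to_csv(emit("spectrum.tsv"), sep="\t", index=False)
        report = call_snvs(phased, ref, config.snv)
        pd.DataFrame(
            [
                {
                    "position": c.position,
                    "ref_base": c.ref_base,
                    "alt_base": c.alt_base,
                    "coverage": c.coverage,
                    "count": c.variant_count,
                    "frequency": round(c.frequency, 4),
                }
                for c in report.calls
            ],
            columns=["position", "ref_base", "alt_base", "coverage", "count", "frequency"],
        ).to_csv(emit("snv.tsv"), sep="\t", index=False)
        with open(emit("profile_summary.json"), "w") as fh:
            json.dump(
                {
                    "snv_count": report.snv_count,
                    "assigned_windows": spectrum.assigned_windows,
                    "unassigned_windows": spectrum.unassigned_windows,
                    "mean_coverage": report.mean_coverage,
                    "coverage_cv": report.coverage_cv,
                },
                fh,
                indent=2,
            )
        counters["assigned_windows"] = spectrum.assigned_windows
        counters["unassigned_windows"] = spectrum.unassigned_windows
        counters["snv_count"] = report.snv_count
    else:
        logger.warning("no telomeric hits; variant profiling skipped")

    # 5. digestion of the realized arrays
    frag_rows = []
    for i, (start, end) in enumerate(genome.array_intervals):
        arr_seq = genome.sequence[start:end]
        for ename in config.enzymes:
            res = digest(arr_seq, ENZYMES[ename], high_MW_threshold=config.high_mw_threshold)
            frag_rows.append(
                {
                    "array_index": i,
                    "enzyme": ename,
                    "n_sites": len(res.site_positions),
                    "n_fragments": res.n_fragments,
                    "mean_fragment_bp": round(res.mean_fragment_length, 2),
                    "fraction_high_MW": round(res.fraction_high_MW, 4),
                }
            )
    if frag_rows:
        pd.DataFrame(frag_rows).to_csv(emit("digest.tsv"), sep="\t", index=False)

    from telospect import __version__ as pkg_version

    manifest = RunManifest(
        config=config.snapshot(),
        version=pkg_version,
        counters=counters,
        outputs=outputs,
        started=started,
        finished=time.time(),
    )
    manifest.to_json(outdir / "manifest.json")
    for name, value in counters.items():
        logger.info("counter %s = %s", name, value)
    return manifest


def correlate_table(table_path: str | Path, out_path: str | Path | None = None) -> pd.DataFrame:
    """Correlation table for a species TSV; optionally written as TSV."""
    df = pd.read_csv(table_path, sep="\t")
    frame = correlation_frame(correlation_table(df))
    if out_path is not None:
        frame.to_csv(out_path, sep="\t", index=False)
    return frame
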