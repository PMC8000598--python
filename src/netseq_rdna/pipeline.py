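"""End-to-end orchestration: simulate → preprocess → occupancy → compare → logos.

`run_pipeline` executes every stage on synthetic libraries for two strains,
writes all artifacts under an output directory and returns a manifest with
a checksum per file.  Identical config and seed give identical checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .compare import (
    AnalysisConfig,
    ComparisonResult,
    median_track,
    positionwise_comparison,
    smoothed_profiles,
    spearman_concordance,
)
from .occupancy import track_from_reads
from .pauselogo import (
    build_matrix,
    call_pause_sites,
    diff_logo,
    extract_windows,
)
from .preprocess import preprocess_reads
from .simulate import (
    DEFAULT_REGION_LENGTHS,
    SPT4D_PARAMS,
    WT_PARAMS,
    StrainParams,
    TemplateLocus,
    generate_template,
    simulate_reads,
)

logger = logging.getLogger("netseq_rdna")
if not logger.handlers:
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("[%(levelname)s %(name)s] %(message)s"))
    logger.addHandler(_handler)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic analysis."""

    output_dir: Path = Path("netseq_out")
    seed: int = 0
    region_lengths: tuple[int, ...] = DEFAULT_REGION_LENGTHS
    n_reads: int = 20000
    n_replicates: int = 3
    wt_params: StrainParams = WT_PARAMS
    mut_params: StrainParams = SPT4D_PARAMS
    strains: tuple[str, str] = ("WT", "spt4d")
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["output_dir"] = str(self.output_dir)
        return payload


def replicate_seeds(seed: int, n: int) -> list[int]:
    """n deterministic child seeds (< 2**31) derived from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_library_tracks(
    locus: TemplateLocus,
    params: StrainParams,
    strain: str,
    n_replicates: int,
    n_reads: int,
    seed: int,
) -> list[pd.DataFrame]:
    """Simulate replicate libraries and push each through preprocessing,
    alignment and normalisation, returning normalised tracks."""
    tracks = []
    for rep, child_seed in enumerate(replicate_seeds(seed, n_replicates), start=1):
        raw, _truth = simulate_reads(locus, params, n_reads, child_seed)
        clean, _stats = preprocess_reads(raw)
        tracks.append(track_from_reads(clean, locus, strain, rep))
    return tracks


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return decorator


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write artifacts plus a checksum manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    # hash only the scientific parameters: where outputs land must not
    # change what they contain
    chash = nio.config_hash(
        {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    )
    seed = config.seed
    analysis = config.analysis

    @_stage("simulate")
    def stage_simulate():
        locus = generate_template(config.region_lengths, seed=seed)
        nio.write_fasta({locus.chrom: locus.genome_sequence}, outdir / "locus.fa")
        nio.locus_to_json(locus, outdir / "locus.json")
        strain_seeds = replicate_seeds(seed, 2)
        raw = {}
        for (strain, params), strain_seed in zip(
            [(config.strains[0], config.wt_params), (config.strains[1], config.mut_params)],
            strain_seeds,
        ):
            reads_by_rep = []
            truth_rows = []
            for rep, child in enumerate(
                replicate_seeds(strain_seed, config.n_replicates), start=1
            ):
                reads, truth = simulate_reads(locus, params, config.n_reads, child)
                nio.write_fastq(reads, outdir / f"reads_{strain}_rep{rep}.fastq")
                reads_by_rep.append(reads)
                if rep == 1:
                    truth_rows.append(
                        pd.DataFrame(
                            {
                                "coordinate": np.arange(1, locus.unit_length + 1),
                                "strain": strain,
                                "probability": truth.probabilities,
                            }
                        )
                    )
            raw[strain] = reads_by_rep
            nio.write_table(
                pd.concat(truth_rows, ignore_index=True),
                outdir / f"truth_{strain}.tsv",
                seed=seed,
                config_hash=chash,
            )
        (outdir / "params.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "n_reads": config.n_reads,
                    "n_replicates": config.n_replicates,
                    "wt_params": dataclasses.asdict(config.wt_params),
                    "mut_params": dataclasses.asdict(config.mut_params),
                },
                indent=2,
            )
            + "\n"
        )
        return locus, raw

    locus, raw_reads = stage_simulate()

    @_stage("preprocess")
    def stage_preprocess():
        clean = {}
        all_stats = {}
        for strain, reps in raw_reads.items():
            clean[strain] = []
            for rep, reads in enumerate(reps, start=1):
                trimmed, stats = preprocess_reads(reads)
                nio.write_fastq(trimmed, outdir / f"trimmed_{strain}_rep{rep}.fastq")
                clean[strain].append(trimmed)
                all_stats[f"{strain}_rep{rep}"] = stats.as_dict()
        (outdir / "preprocess_stats.json").write_text(
            json.dumps(all_stats, indent=2) + "\n"
        )
        return clean

    clean_reads = stage_preprocess()

    @_stage("occupancy")
    def stage_occupancy():
        tracks = {}
        for strain, reps in clean_reads.items():
            tracks[strain] = []
            for rep, reads in enumerate(reps, start=1):
                track = track_from_reads(reads, locus, strain, rep)
                nio.write_track(
                    track,
                    outdir / f"track_{strain}_rep{rep}.tsv",
                    seed=seed,
                    config_hash=chash,
                )
                tracks[strain].append(track)
        return tracks

    tracks = stage_occupancy()
    wt_name, mut_name = config.strains

    @_stage("compare")
    def stage_compare():
        concordance_rows = []
        for strain in config.strains:
            reps = tracks[strain]
            for i in range(len(reps)):
                for j in range(i + 1, len(reps)):
                    concordance_rows.append(
                        {
                            "strain": strain,
                            "replicate_a": i + 1,
                            "replicate_b": j + 1,
                            "spearman": spearman_concordance(reps[i], reps[j]),
                        }
                    )
        nio.write_table(
            pd.DataFrame(concordance_rows),
            outdir / "concordance.tsv",
            seed=seed,
            config_hash=chash,
        )
        result = positionwise_comparison(tracks[wt_name], tracks[mut_name], analysis)
        nio.write_table(
            result.positions, outdir / "comparison_positions.tsv", seed, chash
        )
        region_table = result.regions.copy()
        region_table.loc[len(region_table)] = {
            "region": "genome-wide",
            "ks_statistic": result.genomewide_ks[0],
            "ks_p_value": result.genomewide_ks[1],
        }
        nio.write_table(region_table, outdir / "comparison_regions.tsv", seed, chash)
        for strain in config.strains:
            for window, values in smoothed_profiles(
                tracks[strain], analysis.windows
            ).items():
                nio.write_table(
                    pd.DataFrame(
                        {
                            "window_start": np.arange(1, len(values) + 1),
                            "smoothed": values,
                        }
                    ),
                    outdir / f"smoothed_{strain}_w{window}.tsv",
                    seed,
                    chash,
                )
        return result

    comparison = stage_compare()

    @_stage("pauselogo")
    def stage_pauselogo():
        matrices = {}
        for strain in config.strains:
            med = median_track(tracks[strain])
            sites = call_pause_sites(
                med, analysis.top_fraction, analysis.flank, strain=strain
            )
            windows = extract_windows(sites, locus, analysis.flank)
            nio.write_windows_fasta(windows, outdir / f"pause_windows_{strain}.fa")
            matrices[strain] = (build_matrix(windows), windows.labels)
        (m_wt, labels), (m_mut, _) = matrices[wt_name], matrices[mut_name]
        result = diff_logo(
            m_wt,
            m_mut,
            n_permutations=analysis.n_permutations,
            seed=seed,
            alpha=analysis.alpha,
            labels=labels,
        )
        for strain in config.strains:
            nio.write_table(
                nio.matrix_to_frame(matrices[strain][0], labels),
                outdir / f"pause_matrix_{strain}.tsv",
                seed,
                chash,
            )
        nio.write_table(
            nio.difflogo_to_frame(result), outdir / "difference_logo.tsv", seed, chash
        )
        return result

    logo_result = stage_pauselogo()

    artifacts = {
        p.name: nio.sha256_file(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": nio.__version__,
        "seed": seed,
        "config_hash": chash,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
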