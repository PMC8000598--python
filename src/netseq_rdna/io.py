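"""Readers and writers for the pipeline's file formats.

FASTQ and FASTA go through Biopython; gzip is autodetected by the ``.gz``
extension.  Tabular outputs are tab-separated UTF-8 with ``.`` for missing
values and ``#``-prefixed header comments carrying the tool version, the
seed and a config hash, so every artifact records its provenance.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .occupancy import TRACK_COLUMNS, AlignedInterval
from .pauselogo import BASES, DiffLogoResult, PositionMatrix, SequenceWindowSet
from .preprocess import ReadRecord
from .simulate import TemplateLocus


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        for read in reads:
            quals = read.qualities or "I" * len(read.sequence)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    with _open_text(path, "r") as fh:
        return [
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities="".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                ),
            )
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------------------
# Locus JSON


def locus_to_json(locus: TemplateLocus, path: str | Path) -> None:
    """Persist the locus annotation (the sequence goes to FASTA)."""
    payload = {
        "chrom": locus.chrom,
        "copy_spans": [list(span) for span in locus.copy_spans],
        "region_bounds": list(locus.region_bounds),
        "gene_strand": locus.gene_strand,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def locus_from_files(fasta_path: str | Path, json_path: str | Path) -> TemplateLocus:
    meta = json.loads(Path(json_path).read_text())
    sequences = read_fasta(fasta_path)
    if meta["chrom"] not in sequences:
        raise ValueError(f"chromosome {meta['chrom']!r} not found in {fasta_path}")
    return TemplateLocus(
        genome_sequence=sequences[meta["chrom"]],
        copy_spans=tuple(tuple(span) for span in meta["copy_spans"]),
        region_bounds=tuple(meta["region_bounds"]),
        gene_strand=meta["gene_strand"],
        chrom=meta["chrom"],
    )


# ---------------------------------------------------------------------------
# Tracks and tables


def _header_lines(seed: int | None, config_hash: str | None) -> list[str]:
    lines = [f"# netseq-rdna version={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config={config_hash}")
    return lines


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """TSV with provenance header comments; NaN written as ``.``."""
    with _open_text(path, "w") as fh:
        for line in _header_lines(seed, config_hash):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, na_rep=".")


def write_track(
    track: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    write_table(track[TRACK_COLUMNS], path, seed=seed, config_hash=config_hash)


def read_track(path: str | Path) -> pd.DataFrame:
    """Read an occupancy track TSV, validating schema and coordinates."""
    with _open_text(path, "r") as fh:
        track = pd.read_csv(fh, sep="\t", comment="#", na_values=".")
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track {path} is missing columns: {missing}")
    coords = np.asarray(track["coordinate"])
    expected = np.arange(1, len(track) + 1)
    if not np.array_equal(coords, expected):
        raise ValueError(
            f"track {path} coordinates are not contiguous from 1"
        )
    return track[TRACK_COLUMNS]


def write_bed(intervals: Sequence[AlignedInterval], path: str | Path) -> None:
    """BED6 (name '.', score 0)."""
    with _open_text(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[AlignedInterval]:
    intervals = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, _name, _score, strand = line.rstrip("\n").split("\t")[:6]
            intervals.append(AlignedInterval(chrom, int(start), int(end), strand))
    return intervals


def write_windows_fasta(windows: SequenceWindowSet, path: str | Path) -> None:
    write_fasta(
        {f"window_{i:04d}": seq for i, seq in enumerate(windows.windows)}, path
    )


def matrix_to_frame(matrix: PositionMatrix, labels: np.ndarray) -> pd.DataFrame:
    frame = pd.DataFrame({"label": labels})
    for i, base in enumerate(BASES):
        frame[base] = matrix.probabilities[i]
    frame["n_sequences"] = matrix.n_sequences
    return frame


def difflogo_to_frame(result: DiffLogoResult) -> pd.DataFrame:
    frame = pd.DataFrame(
        {"label": result.labels if result.labels is not None else
         np.arange(result.heights.size)}
    )
    for i, base in enumerate(BASES):
        frame[base] = result.contributions[i]
    frame["height"] = result.heights
    frame["p_value"] = result.p_values
    frame["significant"] = result.significant
    return frame


# ---------------------------------------------------------------------------
# Checksums


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
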