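"""Genome sequence access (FASTA via pyfaidx) and small sequence helpers."""

from __future__ import annotations

from pathlib import Path

from pyfaidx import Fasta

from .regions import GenomicRegion

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def open_genome(path: str | Path) -> Fasta:
    """Open an (indexed) FASTA genome; the .fai index is built if absent."""
    return Fasta(str(path), sequence_always_upper=True)


def fetch_sequence(genome: Fasta, region: GenomicRegion, strand: str | None = None) -> str:
    """Fetch the uppercase sequence of ``region``.

    ``strand`` overrides the region's own strand.  Minus strand returns the
    reverse complement; unstranded (``"."``) returns the plus-strand
    sequence.  Missing chromosomes and out-of-bounds coordinates raise
    ``KeyError``/``ValueError`` rather than returning truncated sequence.
    """
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} not present in genome")
    chrom_len = len(genome[region.chrom])
    if region.end > chrom_len:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {chrom_len}"
        )
    seq = str(genome[region.chrom][region.start : region.end]).upper()
    effective = strand if strand is not None else region.strand
    if effective == "-":
        return reverse_complement(seq)
    return seq


def write_fasta(records: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
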