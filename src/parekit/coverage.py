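"""Strand-specific per-nucleotide 5'-end count tracks.

Degradome sequencing (PARE) ligates an adapter to free 5'-monophosphate RNA
ends, so each read begins exactly at the nucleotide left exposed by a
cleavage or decapping event.  The elementary data structure of the pipeline
is therefore a sparse, strand-specific map from genomic position to the
number of reads whose 5'-most aligned base falls there, optionally scaled to
counts per million (cpm).

Coordinates are 0-based half-open throughout; bedGraph output follows the
same convention, GFF3 input is converted from 1-based on read (see
:mod:`parekit.substrates`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Tuple

STRANDS = ("+", "-")

#: suffix conventions for per-strand bedGraph files
STRAND_SUFFIX = {"+": ".fwd.bedgraph", "-": ".rev.bedgraph"}


@dataclass(frozen=True)
class ReadStartRecord:
    """The 5'-most aligned genomic base of one read.

    For a minus-strand read the 5' end of the RNA corresponds to the
    *rightmost* aligned reference base, so ``five_prime_pos`` for a read
    aligned over the half-open interval [start, end) on the minus strand is
    ``end - 1``.
    """

    contig: str
    strand: str
    five_prime_pos: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.five_prime_pos < 0:
            raise ValueError(f"five_prime_pos must be >= 0, got {self.five_prime_pos}")


@dataclass
class EndCountTrack:
    """Sparse per-position read-end counts on one contig and strand.

    ``values`` maps position -> count (raw) or cpm; positions with value 0
    are absent.  ``library_size`` is the normalization denominator for cpm
    scaling (total primary aligned reads for the sample, falling back to
    the total number of counted ends).  ``end_type`` distinguishes PARE
    5'-end tracks from NET-seq 3'-end tracks.
    """

    contig: str
    strand: str
    values: Dict[int, float] = field(default_factory=dict)
    library_size: int = 0
    scale: str = "raw"  # "raw" | "cpm"
    end_type: str = "five_prime"  # "five_prime" | "three_prime"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if self.scale not in ("raw", "cpm"):
            raise ValueError(f"scale must be 'raw' or 'cpm', got {self.scale!r}")
        if self.end_type not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown end_type {self.end_type!r}")
        # drop explicit zeros so sparsity is canonical
        self.values = {int(p): float(v) for p, v in self.values.items() if v != 0}

    def get(self, pos: int) -> float:
        return self.values.get(pos, 0.0)

    def positions(self) -> List[int]:
        return sorted(self.values)

    def total(self) -> float:
        return float(sum(self.values.values()))

    def window_sum(self, start: int, end: int) -> float:
        """Sum of values on the half-open interval [start, end)."""
        if end - start < len(self.values):
            return float(sum(self.values.get(p, 0.0) for p in range(start, end)))
        return float(sum(v for p, v in self.values.items() if start <= p < end))


TrackSet = Dict[Tuple[str, str], EndCountTrack]
"""Genome-wide collection of tracks keyed by (contig, strand)."""


def count_five_prime_ends(
    records: Iterable[ReadStartRecord],
    contig_lengths: Mapping[str, int],
) -> TrackSet:
    """Tally read 5' ends into one raw track per (contig, strand).

    Every contig in ``contig_lengths`` gets a (possibly empty) track on each
    strand.  ``library_size`` on every track is the total number of records
    counted; pass the result through :func:`set_library_size` if the
    sample's total aligned-read count is known and differs.
    """
    counts: Dict[Tuple[str, str], Dict[int, float]] = {
        (c, s): {} for c in contig_lengths for s in STRANDS
    }
    n = 0
    for rec in records:
        if rec.contig not in contig_lengths:
            raise ValueError(f"record on unknown contig {rec.contig!r}")
        if rec.five_prime_pos >= contig_lengths[rec.contig]:
            raise ValueError(
                f"position {rec.five_prime_pos} beyond end of contig "
                f"{rec.contig!r} (length {contig_lengths[rec.contig]})"
            )
        d = counts[(rec.contig, rec.strand)]
        d[rec.five_prime_pos] = d.get(rec.five_prime_pos, 0.0) + 1.0
        n += 1
    if n == 0:
        warnings.warn("no read-start records supplied; all tracks empty", stacklevel=2)
    return {
        key: EndCountTrack(contig=key[0], strand=key[1], values=vals, library_size=n)
        for key, vals in counts.items()
    }


def set_library_size(tracks: TrackSet, library_size: int) -> TrackSet:
    """Override the cpm denominator on every track (total aligned reads)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    for t in tracks.values():
        t.library_size = int(library_size)
    return tracks


def cpm_normalize(track: EndCountTrack, library_size: int | None = None) -> EndCountTrack:
    """Return a new cpm-scaled track; the raw input is left untouched.

    ``library_size`` defaults to the track's own stored value.
    """
    if track.scale != "raw":
        raise ValueError("track is already cpm-scaled; refusing to scale twice")
    lib = track.library_size if library_size is None else library_size
    if lib is None or lib <= 0:
        raise ValueError(f"library_size must be positive, got {lib}")
    f = 1e6 / lib
    return EndCountTrack(
        contig=track.contig,
        strand=track.strand,
        values={p: v * f for p, v in track.values.items()},
        library_size=int(lib),
        scale="cpm",
        end_type=track.end_type,
    )


def cpm_normalize_all(tracks: TrackSet, library_size: int | None = None) -> TrackSet:
    return {k: cpm_normalize(t, library_size) for k, t in tracks.items()}


# ---------------------------------------------------------------------------
# bedGraph I/O (0-based half-open, one strand per file)
# ---------------------------------------------------------------------------

def write_bedgraph(track: EndCountTrack, path: str | Path) -> None:
    """Write a track as tab-delimited bedGraph, collapsing runs of equal values."""
    path = Path(path)
    with path.open("w") as fh:
        run_start = run_end = None
        run_val = None
        for pos in track.positions():
            val = track.values[pos]
            if run_start is not None and pos == run_end and val == run_val:
                run_end = pos + 1
                continue
            if run_start is not None:
                fh.write(_bg_line(track.contig, run_start, run_end, run_val))
            run_start, run_end, run_val = pos, pos + 1, val
        if run_start is not None:
            fh.write(_bg_line(track.contig, run_start, run_end, run_val))


def _bg_line(contig: str, start: int, end: int, val: float) -> str:
    v = int(val) if float(val).is_integer() else val
    return f"{contig}\t{start}\t{end}\t{v}\n"


def read_bedgraph(
    path: str | Path,
    strand: str | None = None,
    library_size: int = 0,
    scale: str = "raw",
    end_type: str = "five_prime",
) -> EndCountTrack:
    """Read a single-contig bedGraph file into a sparse track.

    The strand is taken from the filename suffix (``.fwd.bedgraph`` /
    ``.rev.bedgraph``) unless given explicitly.  Overlapping intervals and
    negative values are rejected.
    """
    path = Path(path)
    if strand is None:
        name = path.name
        if name.endswith(".fwd.bedgraph"):
            strand = "+"
        elif name.endswith(".rev.bedgraph"):
            strand = "-"
        else:
            raise ValueError(
                f"cannot infer strand from filename {name!r}; pass strand='+'/'-'"
            )
    values: Dict[int, float] = {}
    contig = None
    prev_end = -1
    prev_contig = None
    for ln, line in enumerate(path.open(), 1):
        line = line.strip()
        if not line or line.startswith(("track", "#")):
            continue
        c, s, e, v = line.split("\t")
        s, e, v = int(s), int(e), float(v)
        if v < 0:
            raise ValueError(f"{path}:{ln}: negative value {v}")
        if c == prev_contig and s < prev_end:
            raise ValueError(f"{path}:{ln}: overlapping interval [{s},{e})")
        if contig is None:
            contig = c
        elif c != contig:
            raise ValueError(
                f"{path} spans multiple contigs ({contig!r}, {c!r}); "
                "one contig per track"
            )
        for p in range(s, e):
            if v != 0:
                values[p] = v
        prev_end, prev_contig = e, c
    return EndCountTrack(
        contig=contig if contig is not None else "",
        strand=strand,
        values=values,
        library_size=library_size,
        scale=scale,
        end_type=end_type,
    )


def write_trackset(tracks: TrackSet, prefix: str | Path) -> List[Path]:
    """Write one bedGraph per strand (``<prefix>.fwd/.rev.bedgraph``).

    Multiple contigs on the same strand are concatenated into one file in
    contig order; :func:`read_bedgraph` reads single-contig files, so use
    this only for single-contig track sets when round-tripping.
    """
    prefix = Path(prefix)
    out = []
    for strand in STRANDS:
        p = prefix.parent / (prefix.name + STRAND_SUFFIX[strand])
        with p.open("w") as fh:
            for (contig, s), track in sorted(tracks.items()):
                if s != strand:
                    continue
                run_start = run_end = None
                run_val = None
                for pos in track.positions():
                    val = track.values[pos]
                    if run_start is not None and pos == run_end and val == run_val:
                        run_end = pos + 1
                        continue
                    if run_start is not None:
                        fh.write(_bg_line(contig, run_start, run_end, run_val))
                    run_start, run_end, run_val = pos, pos + 1, val
                if run_start is not None:
                    fh.write(_bg_line(contig, run_start, run_end, run_val))
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# input adapters
# ---------------------------------------------------------------------------

def reads_from_tsv(path: str | Path) -> Iterator[ReadStartRecord]:
    """Yield records from a TSV with columns contig, strand, five_prime_pos.

    A header line starting with 'contig' is skipped.
    """
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("contig"):
                continue
            contig, strand, pos = line.split("\t")[:3]
            yield ReadStartRecord(contig=contig, strand=strand, five_prime_pos=int(pos))


def reads_from_sam(path: str | Path) -> Iterator[ReadStartRecord]:
    """Yield 5'-end records from a SAM/BAM file of pre-filtered alignments.

    Secondary/supplementary/unmapped records are skipped; any further
    filtering (multi-mappers etc.) is the caller's responsibility, as
    alignment policy is upstream of this package.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse:
                yield ReadStartRecord(
                    contig=aln.reference_name,
                    strand="-",
                    five_prime_pos=aln.reference_end - 1,
                )
            else:
                yield ReadStartRecord(
                    contig=aln.reference_name,
                    strand="+",
                    five_prime_pos=aln.reference_start,
                )


def contig_lengths_from_fai(path: str | Path) -> Dict[str, int]:
    """Read contig lengths from a FASTA .fai-style TSV (name, length, ...)."""
    lengths: Dict[str, int] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.split("\t")
            lengths[parts[0]] = int(parts[1])
    return lengths
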