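"""comPARE scoring and replicate-consistent cleavage-site calling.

The comPARE score is a pseudocount-modified log2 fold change of per-position
5'-end coverage between a nuclease-proficient (WT) and nuclease-null (mut)
sample::

    score = log2((wt_cpm + c) / (mut_cpm + c))      c = 0.01 cpm

The pseudocount is added to both samples so the score stays finite when the
mutant has zero reads, which is exactly the expectation at a genuine
cleavage site.  A position is called a cleavage site when, in *every*
replicate pair, the WT signal is at least ``min_wt_cpm`` (default 1 cpm) and
the score is at least ``min_score`` (default 4, i.e. a 16-fold read ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .coverage import EndCountTrack, TrackSet


@dataclass(frozen=True)
class ComPAREParams:
    """Thresholds for site calling; defaults are the standard cutoffs."""

    pseudocount: float = 0.01  # cpm
    min_wt_cpm: float = 1.0
    min_score: float = 4.0
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not math.isfinite(self.min_score):
            raise ValueError("min_score must be finite")


@dataclass
class ComPARESite:
    """One genomic position with per-replicate WT/mut cpm and scores."""

    contig: str
    strand: str
    pos: int
    wt_cpm: List[float]
    mut_cpm: List[float]
    score: List[float]
    passed: bool

    @property
    def mean_wt_cpm(self) -> float:
        return sum(self.wt_cpm) / len(self.wt_cpm)

    @property
    def mean_score(self) -> float:
        return sum(self.score) / len(self.score)

    def key(self) -> Tuple[str, str, int]:
        return (self.contig, self.strand, self.pos)


@dataclass
class ScoreTrack:
    """Per-position comPARE scores on one contig/strand.

    Positions absent from both input tracks are implicitly 0 and omitted.
    """

    contig: str
    strand: str
    scores: Dict[int, float] = field(default_factory=dict)


def compare_score(wt_cpm: float, mut_cpm: float, pseudocount: float = 0.01) -> float:
    """Pseudocount-modified log2 fold change between WT and mutant cpm."""
    if wt_cpm < 0 or mut_cpm < 0:
        raise ValueError("cpm values must be nonnegative")
    if not (math.isfinite(wt_cpm) and math.isfinite(mut_cpm)):
        raise ValueError("cpm values must be finite")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((wt_cpm + pseudocount) / (mut_cpm + pseudocount))


def score_tracks(
    wt: EndCountTrack, mut: EndCountTrack, params: ComPAREParams = ComPAREParams()
) -> ScoreTrack:
    """comPARE score at every position where either cpm track is nonzero."""
    _check_compatible(wt, mut)
    scores = {
        pos: compare_score(wt.get(pos), mut.get(pos), params.pseudocount)
        for pos in set(wt.values) | set(mut.values)
    }
    return ScoreTrack(contig=wt.contig, strand=wt.strand, scores=scores)


def call_sites(
    wt_reps: Sequence[EndCountTrack],
    mut_reps: Sequence[EndCountTrack],
    params: ComPAREParams = ComPAREParams(),
) -> List[ComPARESite]:
    """Call positions passing both cutoffs in every index-paired replicate.

    WT replicate *i* is compared with mutant replicate *i*.  With
    ``require_all_replicates=False`` unequal replicate counts are tolerated
    by truncating to the shorter list (pairing remains by index).
    """
    if not wt_reps or not mut_reps:
        raise ValueError("need at least one replicate per genotype")
    if len(wt_reps) != len(mut_reps):
        if params.require_all_replicates:
            raise ValueError(
                f"unequal replicate counts ({len(wt_reps)} WT vs {len(mut_reps)} mut); "
                "set require_all_replicates=False to pair up to the shorter list"
            )
        n = min(len(wt_reps), len(mut_reps))
        wt_reps, mut_reps = wt_reps[:n], mut_reps[:n]
    for t in list(wt_reps) + list(mut_reps):
        _check_compatible(wt_reps[0], t)

    candidates = set()
    for t in list(wt_reps) + list(mut_reps):
        candidates.update(t.values)

    sites: List[ComPARESite] = []
    for pos in sorted(candidates):
        wt_vals = [t.get(pos) for t in wt_reps]
        mut_vals = [t.get(pos) for t in mut_reps]
        scores = [
            compare_score(w, m, params.pseudocount)
            for w, m in zip(wt_vals, mut_vals)
        ]
        passed = all(
            w >= params.min_wt_cpm and s >= params.min_score
            for w, s in zip(wt_vals, scores)
        )
        if passed:
            sites.append(
                ComPARESite(
                    contig=wt_reps[0].contig,
                    strand=wt_reps[0].strand,
                    pos=pos,
                    wt_cpm=wt_vals,
                    mut_cpm=mut_vals,
                    score=scores,
                    passed=True,
                )
            )
    return sites


def mutant_gain_sites(
    wt_reps: Sequence[EndCountTrack],
    mut_reps: Sequence[EndCountTrack],
    params: ComPAREParams = ComPAREParams(),
) -> List[ComPARESite]:
    """Diagnostic: positions with score <= -min_score in every replicate.

    Signal gained in the mutant is not a cleavage call; it is reported
    separately because an excess of such positions indicates a problem with
    normalization or sample identity.
    """
    flipped = call_sites(mut_reps, wt_reps, params=ComPAREParams(
        pseudocount=params.pseudocount,
        min_wt_cpm=0.0,
        min_score=params.min_score,
        require_all_replicates=params.require_all_replicates,
    ))
    for s in flipped:
        s.wt_cpm, s.mut_cpm = s.mut_cpm, s.wt_cpm
        s.score = [-x for x in s.score]
    return flipped


def call_sites_genomewide(
    wt_reps: Sequence[TrackSet],
    mut_reps: Sequence[TrackSet],
    params: ComPAREParams = ComPAREParams(),
) -> List[ComPARESite]:
    """Run :func:`call_sites` over every (contig, strand) in the track sets."""
    keys = set()
    for ts in list(wt_reps) + list(mut_reps):
        keys.update(ts)
    out: List[ComPARESite] = []
    for key in sorted(keys):
        contig, strand = key
        wt = [ts.get(key) or EndCountTrack(contig, strand, scale="cpm") for ts in wt_reps]
        mut = [ts.get(key) or EndCountTrack(contig, strand, scale="cpm") for ts in mut_reps]
        out.extend(call_sites(wt, mut, params))
    return out


def _check_compatible(a: EndCountTrack, b: EndCountTrack) -> None:
    if (a.contig, a.strand) != (b.contig, b.strand):
        raise ValueError(
            f"track mismatch: ({a.contig},{a.strand}) vs ({b.contig},{b.strand})"
        )
    if a.scale != "cpm" or b.scale != "cpm":
        raise ValueError("comPARE scoring requires cpm-scaled tracks")


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_sites_tsv(sites: Sequence[ComPARESite], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        n = len(sites[0].wt_cpm) if sites else 0
        cols = ["contig", "pos", "strand"]
        for i in range(n):
            cols += [f"wt_cpm_{i + 1}", f"mut_cpm_{i + 1}", f"score_{i + 1}"]
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [s.contig, str(s.pos), s.strand]
            for w, m, sc in zip(s.wt_cpm, s.mut_cpm, s.score):
                row += [f"{w:.6g}", f"{m:.6g}", f"{sc:.4f}"]
            fh.write("\t".join(row) + "\n")


def read_sites_tsv(path: str | Path) -> List[ComPARESite]:
    sites: List[ComPARESite] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n = sum(1 for c in header if c.startswith("wt_cpm_"))
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            wt = [float(parts[3 + 3 * i]) for i in range(n)]
            mut = [float(parts[4 + 3 * i]) for i in range(n)]
            sc = [float(parts[5 + 3 * i]) for i in range(n)]
            sites.append(
                ComPARESite(
                    contig=parts[0], pos=int(parts[1]), strand=parts[2],
                    wt_cpm=wt, mut_cpm=mut, score=sc, passed=True,
                )
            )
    return sites


def write_sites_bed(sites: Sequence[ComPARESite], path: str | Path) -> None:
    """BED6 of called positions; score column is mean comPARE capped at 1000."""
    with Path(path).open("w") as fh:
        for s in sites:
            score = min(1000, max(0, round(s.mean_score)))
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.pos + 1}\tsite\t{score}\t{s.strand}\n"
            )
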