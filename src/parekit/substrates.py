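"""From called positions to annotated RNA substrates.

Called cleavage positions are first merged into *events* (imprecise cleavage
or partial exonucleolytic nibbling spreads a single cut over 1-5 adjacent
positions), events are paired across the ~34-nt two-sided cleavage spacing
(14 nt + 4-nt loop + 16 nt), and events are clustered into *substrates*
anchored on annotated features, each labelled with a category (ncRNA, CDS,
intron, UTR, antisense, intergenic).  The module also provides the
degradome-fraction statistic (endonucleolytic cleavage reads relative to
cleavage-plus-decapping reads per transcript), tolerant comparison of two
site lists (known sites; in vitro vs in vivo), and the NET-seq cross-check
for co-transcriptional cleavage (a nascent 3'-end peak sits precisely 1 nt
upstream of the PARE 5'-end peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .compare import ComPARESite
from .coverage import EndCountTrack

CATEGORY_PRIORITY = ["ncRNA", "CDS", "intron", "five_prime_UTR", "three_prime_UTR"]
CATEGORIES = CATEGORY_PRIORITY + ["antisense", "intergenic"]

_GFF_KIND = {
    "gene": "gene",
    "CDS": "CDS",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "intron": "intron",
    "ncRNA": "ncRNA",
    "ncRNA_gene": "ncRNA",
    "snoRNA": "ncRNA",
    "snRNA": "ncRNA",
    "rRNA": "ncRNA",
    "tRNA": "ncRNA",
}


@dataclass(frozen=True)
class AnnotationFeature:
    """One annotated interval (0-based half-open span)."""

    feature_id: str
    contig: str
    strand: str
    kind: str  # gene | CDS | five_prime_UTR | three_prime_UTR | intron | ncRNA
    start: int
    end: int
    tss: Optional[int] = None  # transcript start (genes only)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty span for feature {self.feature_id}")
        if self.tss is not None and not (self.start <= self.tss < self.end):
            raise ValueError(f"tss outside span for feature {self.feature_id}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class AnnotationIndex:
    """Interval index over annotation features, per (contig, strand)."""

    def __init__(self, features: Iterable[AnnotationFeature]):
        self.features: List[AnnotationFeature] = list(features)
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for f in self.features:
            tree = self._trees.setdefault((f.contig, f.strand), IntervalTree())
            tree.addi(f.start, f.end, f)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationIndex":
        """Load a GFF3 file (1-based inclusive, converted to 0-based half-open)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        feats: List[AnnotationFeature] = []
        for f in db.all_features():
            kind = _GFF_KIND.get(f.featuretype)
            if kind is None:
                continue
            fid = f.attributes.get("ID", [f.id])[0]
            start, end = f.start - 1, f.end
            tss = None
            if kind in ("gene", "ncRNA"):
                tss = start if f.strand == "+" else end - 1
            feats.append(
                AnnotationFeature(
                    feature_id=fid, contig=f.seqid, strand=f.strand,
                    kind=kind, start=start, end=end, tss=tss,
                )
            )
        return cls(feats)

    def overlapping(self, contig: str, strand: str, pos: int) -> List[AnnotationFeature]:
        tree = self._trees.get((contig, strand))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda f: (f.start, f.feature_id))

    def genes(self) -> List[AnnotationFeature]:
        return [f for f in self.features if f.kind in ("gene", "ncRNA")]


@dataclass
class CleavageEvent:
    """A run of called positions merged into one cleavage event."""

    member_sites: List[ComPARESite]
    category: Optional[str] = None

    @property
    def contig(self) -> str:
        return self.member_sites[0].contig

    @property
    def strand(self) -> str:
        return self.member_sites[0].strand

    @property
    def anchor_pos(self) -> int:
        best = max(self.member_sites, key=lambda s: (s.mean_wt_cpm, -s.pos))
        return best.pos

    @property
    def total_wt_cpm(self) -> float:
        return sum(s.mean_wt_cpm for s in self.member_sites)

    @property
    def n_sites(self) -> int:
        return len(self.member_sites)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.member_sites[0].pos, self.member_sites[-1].pos + 1)


@dataclass
class SitePair:
    """Two events flanking one stem-loop (upstream then downstream in transcript order)."""

    upstream_event: CleavageEvent
    downstream_event: CleavageEvent
    spacing: int


@dataclass
class Substrate:
    """An annotation-anchored cluster of cleavage events."""

    feature_id: str
    events: List[CleavageEvent]
    pairs: List[SitePair] = field(default_factory=list)
    category: str = "intergenic"

    @property
    def n_sites(self) -> int:
        return sum(e.n_sites for e in self.events)

    @property
    def n_events(self) -> int:
        return len(self.events)


def merge_proximal(
    sites: Sequence[ComPARESite], max_gap: int = 5
) -> List[CleavageEvent]:
    """Single-linkage merge of called positions separated by <= max_gap nt.

    Input must be sorted by (contig, strand, pos); idempotent on anchors of
    its own output.
    """
    keys = [s.key() for s in sites]
    if keys != sorted(keys):
        raise ValueError("sites must be sorted by (contig, strand, pos)")
    events: List[CleavageEvent] = []
    current: List[ComPARESite] = []
    for s in sites:
        if current and (
            (s.contig, s.strand) == (current[-1].contig, current[-1].strand)
            and s.pos - current[-1].pos <= max_gap
        ):
            current.append(s)
        else:
            if current:
                events.append(CleavageEvent(member_sites=current))
            current = [s]
    if current:
        events.append(CleavageEvent(member_sites=current))
    return events


def pair_two_sided(
    events: Sequence[CleavageEvent],
    expected_spacing: int = 34,
    tolerance: int = 4,
) -> Tuple[List[SitePair], List[CleavageEvent]]:
    """Greedily pair events whose anchor spacing is within expected +/- tolerance.

    Candidate pairs are ranked by closeness to the expected spacing (ties by
    position); each event joins at most one pair.  Unpaired events are
    returned as well -- single-site substrates are legitimate.
    """
    ordered = sorted(events, key=lambda e: (e.contig, e.strand, e.anchor_pos))
    candidates = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if (a.contig, a.strand) != (b.contig, b.strand):
                continue
            spacing = abs(b.anchor_pos - a.anchor_pos)
            if abs(spacing - expected_spacing) <= tolerance:
                candidates.append((abs(spacing - expected_spacing), a.anchor_pos, i, j, spacing))
    candidates.sort()
    used = set()
    pairs: List[SitePair] = []
    for _, _, i, j, spacing in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = ordered[i], ordered[j]
        # upstream precedes downstream in transcript orientation
        if a.strand == "-":
            a, b = b, a
        pairs.append(SitePair(upstream_event=a, downstream_event=b, spacing=spacing))
    unpaired = [e for k, e in enumerate(ordered) if k not in used]
    return pairs, unpaired


def classify_event(event: CleavageEvent, annotation: AnnotationIndex) -> str:
    """Category of an event under the sense-feature priority rule.

    Sense-strand priority ncRNA > CDS > intron > 5'UTR > 3'UTR (so known
    ncRNA targets, e.g. intron-hosted snoRNAs, are never demoted); if no
    sense feature overlaps but an antisense gene does, 'antisense'; else
    'intergenic'.
    """
    pos = event.anchor_pos
    sense = annotation.overlapping(event.contig, event.strand, pos)
    kinds = {f.kind for f in sense}
    for kind in CATEGORY_PRIORITY:
        if kind in kinds:
            return kind
    other = "-" if event.strand == "+" else "+"
    anti = annotation.overlapping(event.contig, other, pos)
    if any(f.kind in ("gene", "ncRNA") for f in anti):
        return "antisense"
    return "intergenic"


def _anchor_feature(event: CleavageEvent, annotation: AnnotationIndex) -> Optional[str]:
    """Substrate-grouping key: the overlapping gene-level feature, if any."""
    sense = annotation.overlapping(event.contig, event.strand, event.anchor_pos)
    genes = [f for f in sense if f.kind in ("gene", "ncRNA")]
    if genes:
        return genes[0].feature_id
    other = "-" if event.strand == "+" else "+"
    anti = [
        f for f in annotation.overlapping(event.contig, other, event.anchor_pos)
        if f.kind in ("gene", "ncRNA")
    ]
    if anti:
        return f"antisense:{anti[0].feature_id}"
    return None


def cluster_to_substrates(
    events: Sequence[CleavageEvent],
    pairs: Sequence[SitePair],
    annotation: AnnotationIndex,
    orphan_window: int = 200,
) -> List[Substrate]:
    """Group events into substrates by shared annotated feature.

    Events overlapping the same gene-level feature (sense, or antisense via
    an ``antisense:`` key) form one substrate; unannotated events cluster by
    single-linkage distance <= orphan_window and get synthetic ids.  Every
    event lands in exactly one substrate.
    """
    for e in events:
        if e.category is None:
            e.category = classify_event(e, annotation)
    groups: Dict[str, List[CleavageEvent]] = {}
    orphans: List[CleavageEvent] = []
    for e in events:
        key = _anchor_feature(e, annotation)
        if key is None:
            orphans.append(e)
        else:
            groups.setdefault(key, []).append(e)
    # single-linkage clustering of intergenic orphans
    orphans.sort(key=lambda e: (e.contig, e.strand, e.anchor_pos))
    cluster: List[CleavageEvent] = []
    n_orphan = 0
    for e in orphans:
        if cluster and (
            (e.contig, e.strand) == (cluster[-1].contig, cluster[-1].strand)
            and e.anchor_pos - cluster[-1].anchor_pos <= orphan_window
        ):
            cluster.append(e)
        else:
            if cluster:
                n_orphan += 1
                groups[_orphan_id(cluster, n_orphan)] = list(cluster)
            cluster = [e]
    if cluster:
        n_orphan += 1
        groups[_orphan_id(cluster, n_orphan)] = list(cluster)

    event_ids = {id(e): key for key, evs in groups.items() for e in evs}
    substrates = []
    for key, evs in sorted(groups.items()):
        sub_pairs = [
            p for p in pairs
            if event_ids.get(id(p.upstream_event)) == key
            and event_ids.get(id(p.downstream_event)) == key
        ]
        cat = "intergenic"
        for kind in CATEGORY_PRIORITY + ["antisense", "intergenic"]:
            if any(e.category == kind for e in evs):
                cat = kind
                break
        substrates.append(
            Substrate(feature_id=key, events=list(evs), pairs=sub_pairs, category=cat)
        )
    return substrates


def _orphan_id(cluster: List[CleavageEvent], n: int) -> str:
    e = cluster[0]
    return f"intergenic:{e.contig}:{e.strand}:{e.anchor_pos}"


# ---------------------------------------------------------------------------
# site-list comparison
# ---------------------------------------------------------------------------

SiteKey = Tuple[str, str, int]


def _as_key(site) -> SiteKey:
    if isinstance(site, tuple):
        return site
    return (site.contig, site.strand, site.pos)


@dataclass
class SiteListComparison:
    matched: List[Tuple[SiteKey, SiteKey]]
    a_only: List[SiteKey]
    b_only: List[SiteKey]

    @property
    def jaccard(self) -> float:
        n = len(self.matched)
        union = n + len(self.a_only) + len(self.b_only)
        return n / union if union else 1.0


def compare_site_lists(a, b, tolerance: int = 1) -> SiteListComparison:
    """One-to-one nearest-first matching of two site lists within a tolerance.

    Sites match when they share contig and strand and differ by at most
    ``tolerance`` nt.  Accepts ComPARESite-like objects or
    (contig, strand, pos) tuples.
    """
    ka = sorted(_as_key(s) for s in a)
    kb = sorted(_as_key(s) for s in b)
    candidates = []
    for i, (ca, sa, pa) in enumerate(ka):
        for j, (cb, sb, pb) in enumerate(kb):
            if (ca, sa) == (cb, sb) and abs(pa - pb) <= tolerance:
                candidates.append((abs(pa - pb), pa, i, j))
    candidates.sort()
    used_a, used_b = set(), set()
    matched = []
    for _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((ka[i], kb[j]))
    return SiteListComparison(
        matched=matched,
        a_only=[k for i, k in enumerate(ka) if i not in used_a],
        b_only=[k for j, k in enumerate(kb) if j not in used_b],
    )


# ---------------------------------------------------------------------------
# degradome fraction and NET-seq
# ---------------------------------------------------------------------------

def degradome_fraction(cleavage_reads: float, decapping_reads: float) -> float:
    """Endonucleolytic share of the degradome: cleavage / (cleavage + decapping).

    Returns NaN (undefined, not zero) when both inputs are zero.
    """
    if cleavage_reads < 0 or decapping_reads < 0:
        raise ValueError("read counts must be nonnegative")
    total = cleavage_reads + decapping_reads
    if total == 0:
        return math.nan
    return cleavage_reads / total


def decapping_reads_at_tss(
    track: EndCountTrack, feature: AnnotationFeature, window: int = 25
) -> float:
    """Sum of sense-strand 5'-end signal within +/- window of the transcript start."""
    if feature.tss is None:
        raise ValueError(f"feature {feature.feature_id} has no transcript start")
    return track.window_sum(feature.tss - window, feature.tss + window + 1)


def gene_degradome_fraction(
    track: EndCountTrack,
    events: Sequence[CleavageEvent],
    feature: AnnotationFeature,
    tss_window: int = 25,
) -> float:
    """Per-gene degradome fraction from cleavage-event reads and TSS reads."""
    cleave = 0.0
    for e in events:
        if (e.contig, e.strand) != (feature.contig, feature.strand):
            continue
        cleave += sum(track.get(s.pos) for s in e.member_sites)
    decap = decapping_reads_at_tss(track, feature, window=tss_window)
    return degradome_fraction(cleave, decap)


@dataclass
class NetseqMatch:
    site: SiteKey
    netseq_pos: int
    netseq_value: float


def netseq_crosscheck(
    pare_sites: Sequence, netseq_3p_track: EndCountTrack, min_netseq: float = 1.0
) -> List[NetseqMatch]:
    """Match PARE 5'-end sites to NET-seq 3'-end peaks exactly 1 nt upstream.

    Co-transcriptional cleavage leaves the nascent-RNA 3' end (NET-seq peak)
    immediately transcript-upstream of the new 5' end (PARE peak): p-1 on
    the plus strand, p+1 on the minus strand.
    """
    if netseq_3p_track.end_type != "three_prime":
        raise ValueError("NET-seq track must have end_type='three_prime'")
    out: List[NetseqMatch] = []
    for s in pare_sites:
        contig, strand, pos = _as_key(s)
        if (contig, strand) != (netseq_3p_track.contig, netseq_3p_track.strand):
            continue
        q = pos - 1 if strand == "+" else pos + 1
        v = netseq_3p_track.get(q)
        if v >= min_netseq:
            out.append(NetseqMatch(site=(contig, strand, pos), netseq_pos=q, netseq_value=v))
    return out


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def write_substrate_table(substrates: Sequence[Substrate], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("feature_id\tcategory\tn_events\tn_sites\tn_pairs\n")
        for s in substrates:
            fh.write(
                f"{s.feature_id}\t{s.category}\t{s.n_events}\t{s.n_sites}\t{len(s.pairs)}\n"
            )


def write_pair_table(pairs: Sequence[SitePair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("contig\tstrand\tupstream_pos\tdownstream_pos\tspacing\n")
        for p in pairs:
            fh.write(
                f"{p.upstream_event.contig}\t{p.upstream_event.strand}\t"
                f"{p.upstream_event.anchor_pos}\t{p.downstream_event.anchor_pos}\t{p.spacing}\n"
            )


def write_events_bed(events: Sequence[CleavageEvent], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in sorted(events, key=lambda e: (e.contig, e.strand, e.anchor_pos)):
            start, end = e.span
            name = e.category or "event"
            fh.write(f"{e.contig}\t{start}\t{end}\t{name}\t0\t{e.strand}\n")
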