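"""Synthetic degradome generator with planted ground truth.

Builds a random genome carrying gene cassettes, a matching GFF3-style
annotation, and per-sample 5'-end count tracks whose statistical structure
mirrors a PARE experiment on a nuclease-proficient ("WT") versus
nuclease-null ("mut") strain:

* genotype-dependent cleavage peaks 14 nt upstream / 16 nt downstream of
  planted A/UGNN-tetraloop hairpins (the RNase III signature),
* genotype-independent decapping peaks at transcript starts,
* a sparse "decay hotspot" background: a small fraction of positions carry
  a Gamma-distributed Poisson rate shared between genotypes and replicates
  (degradome background consists of real decay intermediates present in
  both strains; only its sampling varies between libraries), with a
  negative-binomial marginal count distribution,
* an *in vitro* mode in which cleavage happens at every competent hairpin
  regardless of the nuclear-retention flag that gates *in vivo* cleavage,
* poly(A) selection weighting (plus mode up-weights cleavage products,
  minus mode up-weights decapping products),
* NET-seq 3'-end tracks with peaks precisely 1 nt transcript-upstream of
  co-transcriptional cleavage 5' ends.

All randomness flows from explicit integer seeds; outputs are reproducible
bit-for-bit for a fixed seed and version.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.constants import Avogadro

from .coverage import STRANDS, EndCountTrack, TrackSet
from .substrates import AnnotationFeature, AnnotationIndex, SiteKey, compare_site_lists

_DNA = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTU", "TGCAA")

GENOTYPES = ("WT", "mut")
MODES = ("in_vivo", "in_vitro")


def _revcomp_dna(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic degradome."""

    n_genes: int = 50
    gene_length_range: Tuple[int, int] = (400, 800)
    intergenic_spacer: int = 200
    utr_length: int = 50
    fraction_with_hairpins: float = 0.4
    fraction_ncrna: float = 0.1
    stem_pairs: int = 20
    loop_len: int = 4
    bulge_prob: float = 0.0
    cleavage_efficiency: float = 0.8
    decapping_rate: float = 0.9
    nuclear_retention_fraction: float = 1.0
    cotranscriptional_fraction: float = 0.3
    netseq_efficiency: float = 0.5
    expression_median: float = 400.0
    expression_sigma: float = 0.5
    background_mean: float = 0.2
    background_dispersion: float = 10.0
    hotspot_density: float = 0.02
    library_size: int = 2_000_000
    replicates: int = 2
    polyA_mode: str = "plus"  # "plus" | "minus"
    contig: str = "chrS"

    def __post_init__(self) -> None:
        for name in (
            "fraction_with_hairpins", "fraction_ncrna", "bulge_prob",
            "cleavage_efficiency", "nuclear_retention_fraction",
            "cotranscriptional_fraction", "hotspot_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.cleavage_efficiency <= 1.0:
            raise ValueError("cleavage_efficiency must be in (0, 1]")
        if self.polyA_mode not in ("plus", "minus"):
            raise ValueError(f"polyA_mode must be 'plus' or 'minus', got {self.polyA_mode!r}")
        if self.library_size <= 0 or self.replicates < 1:
            raise ValueError("library_size and replicates must be positive")

    @property
    def polyA_weights(self) -> Tuple[float, float]:
        """(cleavage, decapping) peak multipliers for the poly(A) selection mode."""
        return (1.0, 0.2) if self.polyA_mode == "plus" else (0.2, 1.0)


@dataclass
class GeneTruth:
    """Planted parameters of one simulated gene."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    kind: str  # "mRNA" | "ncRNA"
    tss: int
    depth: float
    has_hairpin: bool
    loop_start: Optional[int] = None  # genome coord of loop 5'-most base (transcript sense)
    loop_len: int = 4
    bulged: bool = False
    up_pos: Optional[int] = None  # genomic 5'-end of the downstream cleavage product
    down_pos: Optional[int] = None
    nuclear_retained: bool = True
    cotranscriptional: bool = False

    def cleavage_keys(self) -> List[SiteKey]:
        out = []
        for p in (self.up_pos, self.down_pos):
            if p is not None:
                out.append((self.contig, self.strand, p))
        return out

    def to_genome(self, t: int) -> int:
        """Transcript coordinate -> genome coordinate."""
        return self.start + t if self.strand == "+" else self.end - 1 - t


@dataclass
class SimTruth:
    """All planted positions and rates, for recovery evaluation."""

    contig: str
    genome_length: int
    seed: int
    genes: List[GeneTruth] = field(default_factory=list)

    def hairpin_genes(self) -> List[GeneTruth]:
        return [g for g in self.genes if g.has_hairpin]

    def active_genes(self, mode: str = "in_vivo") -> List[GeneTruth]:
        if mode == "in_vitro":
            return self.hairpin_genes()
        return [g for g in self.hairpin_genes() if g.nuclear_retained]

    def cleavage_positions(self, mode: str = "in_vivo") -> List[SiteKey]:
        out: List[SiteKey] = []
        for g in self.active_genes(mode):
            out.extend(g.cleavage_keys())
        return sorted(out)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"#contig={self.contig}\n#genome_length={self.genome_length}\n")
            fh.write(f"#seed={self.seed}\n")
            cols = [
                "gene_id", "contig", "strand", "start", "end", "kind", "tss",
                "depth", "has_hairpin", "loop_start", "loop_len", "bulged",
                "up_pos", "down_pos", "nuclear_retained", "cotranscriptional",
            ]
            fh.write("\t".join(cols) + "\n")
            for g in self.genes:
                fh.write(
                    "\t".join(
                        str(x) if x is not None else "NA"
                        for x in (
                            g.gene_id, g.contig, g.strand, g.start, g.end, g.kind,
                            g.tss, f"{g.depth:.4f}", int(g.has_hairpin), g.loop_start,
                            g.loop_len, int(g.bulged), g.up_pos, g.down_pos,
                            int(g.nuclear_retained), int(g.cotranscriptional),
                        )
                    )
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        meta: Dict[str, str] = {}
        genes: List[GeneTruth] = []
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, v = line[1:].split("=", 1)
                    meta[k] = v
                    continue
                if line.startswith("gene_id") or not line:
                    continue
                p = line.split("\t")
                opt = lambda x: None if x == "NA" else int(x)
                genes.append(
                    GeneTruth(
                        gene_id=p[0], contig=p[1], strand=p[2], start=int(p[3]),
                        end=int(p[4]), kind=p[5], tss=int(p[6]), depth=float(p[7]),
                        has_hairpin=bool(int(p[8])), loop_start=opt(p[9]),
                        loop_len=int(p[10]), bulged=bool(int(p[11])),
                        up_pos=opt(p[12]), down_pos=opt(p[13]),
                        nuclear_retained=bool(int(p[14])),
                        cotranscriptional=bool(int(p[15])),
                    )
                )
        return cls(
            contig=meta["contig"], genome_length=int(meta["genome_length"]),
            seed=int(meta.get("seed", 0)), genes=genes,
        )


@dataclass
class GenomeFixture:
    """A simulated genome, its annotation, and the planted truth."""

    sequence: str  # DNA, genome (+) strand
    features: List[AnnotationFeature]
    truth: SimTruth
    config: SimConfig

    @property
    def annotation(self) -> AnnotationIndex:
        return AnnotationIndex(self.features)

    def contig_lengths(self) -> Dict[str, int]:
        return {self.truth.contig: len(self.sequence)}

    def transcript_window(self, gene: GeneTruth, center_t: int, half: int = 30) -> Tuple[str, int]:
        """Transcript-sense sequence window around a transcript coordinate.

        Returns (sequence, transcript coordinate of window start).
        """
        t0 = max(0, center_t - half)
        t1 = min(gene.end - gene.start, center_t + half)
        if gene.strand == "+":
            seg = self.sequence[gene.start + t0 : gene.start + t1]
        else:
            seg = _revcomp_dna(self.sequence[gene.end - t1 : gene.end - t0])
        return seg, t0

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "annotation.gff3",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.json",
        }
        with paths["fasta"].open("w") as fh:
            fh.write(f">{self.truth.contig}\n")
            for i in range(0, len(self.sequence), 70):
                fh.write(self.sequence[i : i + 70] + "\n")
        write_gff3(self.features, paths["gff3"])
        self.truth.to_tsv(paths["truth"])
        cfg = asdict(self.config)
        cfg["seed"] = self.truth.seed
        paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
        return paths


def write_gff3(features: Sequence[AnnotationFeature], path: str | Path) -> None:
    kind_to_type = {"gene": "gene", "ncRNA": "ncRNA", "CDS": "CDS",
                    "five_prime_UTR": "five_prime_UTR",
                    "three_prime_UTR": "three_prime_UTR", "intron": "intron"}
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.contig}\tparekit_sim\t{kind_to_type[f.kind]}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\tID={f.feature_id}\n"
            )


def _make_cassette(rng: np.random.Generator, cfg: SimConfig, bulged: bool) -> Tuple[str, int, int]:
    """Build a hairpin cassette (DNA, transcript sense).

    Returns (cassette, loop offset within cassette, upstream linear distance).
    A bulged cassette carries one extra nucleotide in the 5' arm interior to
    the 14 stem steps nearest the loop, lengthening the upstream distance to 15.
    """
    while True:
        arm5 = "".join(rng.choice(_DNA, size=cfg.stem_pairs))
        # avoid an arm that itself ends in a loop-closing ambiguity: none needed;
        # any arm works because pairing is exact by construction
        loop = ("A" if rng.random() < 0.85 else "T") + "G" + "".join(rng.choice(_DNA, size=cfg.loop_len - 2))
        arm3 = _revcomp_dna(arm5)
        if not bulged:
            return arm5 + loop + arm3, cfg.stem_pairs, 14
        k = int(rng.integers(2, 14))  # bulge after k paired steps from the loop
        bulge_nt = str(rng.choice(_DNA))
        arm5b = arm5[: cfg.stem_pairs - k] + bulge_nt + arm5[cfg.stem_pairs - k :]
        return arm5b + loop + arm3, cfg.stem_pairs + 1, 15


def make_genome_fixture(config: SimConfig, seed: int) -> GenomeFixture:
    """Simulate a genome with hairpin cassettes and the matching annotation/truth."""
    cfg = config
    rng = np.random.default_rng([seed, 11])
    min_len = 2 * cfg.utr_length + 2 * (cfg.stem_pairs + 20)
    if cfg.gene_length_range[0] < min_len:
        raise ValueError(
            f"gene length {cfg.gene_length_range[0]} too short for a "
            f"{cfg.stem_pairs}-pair hairpin cassette (need >= {min_len})"
        )
    n = cfg.n_genes
    n_hairpin = round(cfg.fraction_with_hairpins * n)
    hairpin_idx = set(rng.choice(n, size=n_hairpin, replace=False).tolist()) if n_hairpin else set()
    h_list = sorted(hairpin_idx)
    n_ret = round(cfg.nuclear_retention_fraction * n_hairpin)
    retained = set(rng.choice(h_list, size=n_ret, replace=False).tolist()) if n_ret else set()
    n_cot = round(cfg.cotranscriptional_fraction * n_hairpin)
    cotrans = set(rng.choice(h_list, size=n_cot, replace=False).tolist()) if n_cot else set()

    chunks: List[str] = []
    cursor = 0
    genes: List[GeneTruth] = []
    features: List[AnnotationFeature] = []
    for gi in range(n):
        spacer = "".join(rng.choice(_DNA, size=cfg.intergenic_spacer))
        chunks.append(spacer)
        cursor += cfg.intergenic_spacer
        length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        kind = "ncRNA" if rng.random() < cfg.fraction_ncrna else "mRNA"
        tx = "".join(rng.choice(_DNA, size=length))  # transcript sense
        depth = float(rng.lognormal(mean=math.log(cfg.expression_median), sigma=cfg.expression_sigma))
        gid = f"g{gi + 1:03d}"
        gene = GeneTruth(
            gene_id=gid, contig=cfg.contig, strand=strand, start=cursor,
            end=cursor + length, kind=kind, tss=0, depth=depth,
            has_hairpin=gi in hairpin_idx,
            nuclear_retained=gi in retained, cotranscriptional=gi in cotrans,
        )
        if gene.has_hairpin:
            bulged = bool(rng.random() < cfg.bulge_prob)
            cassette, loop_off, up_dist = _make_cassette(rng, cfg, bulged)
            t_loop = length // 2  # loop start, transcript coords (mid-CDS)
            ins = t_loop - loop_off
            tx = tx[:ins] + cassette + tx[ins + len(cassette):]
            gene.bulged = bulged
            gene.loop_len = cfg.loop_len
            t_up = t_loop - up_dist
            t_down = t_loop + cfg.loop_len + 16
            gene.loop_start = gene.to_genome(t_loop) if strand == "+" else gene.to_genome(t_loop + cfg.loop_len - 1)
            gene.up_pos = gene.to_genome(t_up)
            gene.down_pos = gene.to_genome(t_down)
        gene.tss = gene.to_genome(0)
        genes.append(gene)
        chunks.append(tx if strand == "+" else _revcomp_dna(tx))
        cursor += length

        fkind = "ncRNA" if kind == "ncRNA" else "gene"
        features.append(
            AnnotationFeature(
                feature_id=gid, contig=cfg.contig, strand=strand, kind=fkind,
                start=gene.start, end=gene.end, tss=gene.tss,
            )
        )
        if kind == "mRNA":
            u = cfg.utr_length
            utr5 = (gene.start, gene.start + u) if strand == "+" else (gene.end - u, gene.end)
            utr3 = (gene.end - u, gene.end) if strand == "+" else (gene.start, gene.start + u)
            features.append(AnnotationFeature(f"{gid}_5utr", cfg.contig, strand,
                                              "five_prime_UTR", *utr5))
            features.append(AnnotationFeature(f"{gid}_cds", cfg.contig, strand,
                                              "CDS", gene.start + u, gene.end - u))
            features.append(AnnotationFeature(f"{gid}_3utr", cfg.contig, strand,
                                              "three_prime_UTR", *utr3))
    chunks.append("".join(rng.choice(_DNA, size=cfg.intergenic_spacer)))
    cursor += cfg.intergenic_spacer
    sequence = "".join(chunks)
    truth = SimTruth(contig=cfg.contig, genome_length=cursor, seed=seed, genes=genes)
    return GenomeFixture(sequence=sequence, features=features, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# count-track simulation
# ---------------------------------------------------------------------------

def _background_landscape(cfg: SimConfig, truth: SimTruth, seed: int, salt: int):
    """Per-strand decay hotspots: positions and Poisson rates, shared across samples."""
    rng = np.random.default_rng([seed, salt])
    L = truth.genome_length
    out = {}
    n_hot = int(round(cfg.hotspot_density * L))
    for strand in STRANDS:
        if n_hot == 0 or cfg.background_mean == 0:
            out[strand] = (np.array([], dtype=int), np.array([]))
            continue
        pos = np.sort(rng.choice(L, size=n_hot, replace=False))
        mean_rate = cfg.background_mean / cfg.hotspot_density
        lam = rng.gamma(
            shape=cfg.background_dispersion,
            scale=mean_rate / cfg.background_dispersion,
            size=n_hot,
        )
        out[strand] = (pos, lam)
    return out


def simulate_pare(
    config: SimConfig,
    truth: SimTruth,
    genotype: str = "WT",
    mode: str = "in_vivo",
    replicate: int = 0,
    seed: int = 0,
) -> TrackSet:
    """One PARE library as raw strand-specific 5'-end count tracks.

    Expected counts: shared hotspot background everywhere; decapping peaks
    at every transcript start in both genotypes; cleavage peaks at the
    planted positions only for genotype WT and, in vivo, only for
    nuclear-retained genes (in vitro ignores the retention gate, so the in
    vitro target set strictly contains the in vivo set whenever retention
    is < 1).  Sampling is Poisson around these expectations.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    cfg = config
    land = _background_landscape(cfg, truth, seed, salt=7919)
    rng = np.random.default_rng(
        [seed, 13, GENOTYPES.index(genotype), MODES.index(mode), replicate]
    )
    w_cleave, w_decap = cfg.polyA_weights
    tracks: TrackSet = {}
    for strand in STRANDS:
        values: Dict[int, float] = {}
        pos, lam = land[strand]
        if len(pos):
            counts = rng.poisson(lam)
            for p, c in zip(pos.tolist(), counts.tolist()):
                if c:
                    values[p] = values.get(p, 0.0) + c
        for g in truth.genes:
            if g.strand != strand:
                continue
            c = rng.poisson(g.depth * cfg.decapping_rate * w_decap)
            if c:
                values[g.tss] = values.get(g.tss, 0.0) + c
        active = {id(g) for g in truth.active_genes(mode)} if genotype == "WT" else set()
        for g in truth.genes:
            if g.strand != strand or id(g) not in active:
                continue
            for p in (g.up_pos, g.down_pos):
                if p is None:
                    continue
                c = rng.poisson(g.depth * cfg.cleavage_efficiency * w_cleave)
                if c:
                    values[p] = values.get(p, 0.0) + c
        tracks[(truth.contig, strand)] = EndCountTrack(
            contig=truth.contig, strand=strand, values=values,
            library_size=cfg.library_size, scale="raw", end_type="five_prime",
        )
    return tracks


def simulate_experiment(
    config: SimConfig,
    truth: SimTruth,
    mode: str = "in_vivo",
    seed: int = 0,
) -> Dict[str, List[TrackSet]]:
    """All replicates for both genotypes: {'WT': [...], 'mut': [...]} (raw tracks)."""
    return {
        g: [
            simulate_pare(config, truth, genotype=g, mode=mode, replicate=r, seed=seed)
            for r in range(config.replicates)
        ]
        for g in GENOTYPES
    }


def simulate_netseq(config: SimConfig, truth: SimTruth, seed: int = 0) -> TrackSet:
    """NET-seq 3'-end tracks: nascent-RNA 3' ends from co-transcriptional cleavage.

    For genes flagged co-transcriptional, a 3'-end peak is planted exactly
    1 nt transcript-upstream of each true cleavage 5' end (p-1 on +, p+1 on
    -); post-transcriptionally cleaved genes leave no NET-seq peak.
    """
    cfg = config
    land = _background_landscape(cfg, truth, seed, salt=104729)
    rng = np.random.default_rng([seed, 17])
    tracks: TrackSet = {}
    for strand in STRANDS:
        values: Dict[int, float] = {}
        pos, lam = land[strand]
        if len(pos):
            counts = rng.poisson(lam)
            for p, c in zip(pos.tolist(), counts.tolist()):
                if c:
                    values[p] = values.get(p, 0.0) + c
        for g in truth.genes:
            if g.strand != strand or not (g.has_hairpin and g.cotranscriptional):
                continue
            for p in (g.up_pos, g.down_pos):
                if p is None:
                    continue
                q = p - 1 if strand == "+" else p + 1
                c = rng.poisson(g.depth * cfg.cleavage_efficiency * cfg.netseq_efficiency)
                if c:
                    values[q] = values.get(q, 0.0) + c
        tracks[(truth.contig, strand)] = EndCountTrack(
            contig=truth.contig, strand=strand, values=values,
            library_size=cfg.library_size, scale="raw", end_type="three_prime",
        )
    return tracks


# ---------------------------------------------------------------------------
# recovery evaluation and the dosing helper
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    precision: float
    recall: float
    n_called: int
    n_truth: int
    n_matched: int
    position_errors: List[int]


def evaluate_recovery(
    called_sites: Sequence, truth_positions: Sequence[SiteKey], tolerance: int = 1
) -> RecoveryReport:
    """Precision/recall of called sites against planted positions.

    Matching is one-to-one, nearest-first, within ``tolerance`` nt on the
    same contig and strand.  Precision is 1 by convention when nothing is
    called; recall is 1 when no truth exists.
    """
    cmp = compare_site_lists(called_sites, truth_positions, tolerance=tolerance)
    n_called = len(cmp.matched) + len(cmp.a_only)
    n_truth = len(cmp.matched) + len(cmp.b_only)
    precision = len(cmp.matched) / n_called if n_called else 1.0
    recall = len(cmp.matched) / n_truth if n_truth else 1.0
    errors = [abs(a[2] - b[2]) for a, b in cmp.matched]
    return RecoveryReport(
        precision=precision, recall=recall, n_called=n_called,
        n_truth=n_truth, n_matched=len(cmp.matched), position_errors=errors,
    )


def molar_concentration(n_molecules: float, volume_fL: float) -> float:
    """Concentration in uM of n molecules uniformly distributed in a volume (fL).

    2,512 molecules in a 0.6-fL nucleolus come out at ~7 uM.
    """
    if n_molecules <= 0 or volume_fL <= 0:
        raise ValueError("molecule count and volume must be positive")
    molar = (n_molecules / Avogadro) / (volume_fL * 1e-15)
    return molar * 1e6
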