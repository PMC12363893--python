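"""Tetraloop-anchored stem-loop detection and RNase III cleavage geometry.

Yeast RNase III (Rnt1) recognizes double-stranded stems capped by a terminal
tetraloop with an A/UGNN consensus and cleaves 14 nt upstream and 16 nt
downstream of the loop, leaving the 2-nt 3' overhang characteristic of the
RNase III family.  This module finds such stems around candidate sites by
anchoring at loop-pattern occurrences and extending base pairing outward
from the loop-closing pair, allowing G.U wobble pairs and a limited number
of single-nucleotide bulges.  No free-energy model is used: the scanner
maximizes the number of nested pairs under the bulge budget, which is
deterministic, exactly testable, and sufficient to reproduce the cleavage
geometry (a thermodynamic folder is deliberately out of scope).

Coordinates are indices into the supplied sequence window (5'->3', i.e.
transcript sense).  For minus-strand loci pass the reverse-complemented
window and map coordinates back in the caller.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject characters outside ACGTU."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-ACGTU characters: {sorted(bad)}")
    return s


def _loop_regex(pattern: str) -> Tuple[re.Pattern, int]:
    """Compile a loop pattern like '[AU]GNN' to a regex; return (regex, loop length)."""
    out = []
    i = 0
    p = pattern.upper().replace("T", "U")
    while i < len(p):
        if p[i] == "[":
            j = p.index("]", i)
            out.append(p[i : j + 1])
            i = j + 1
        else:
            if p[i] not in _IUPAC:
                raise ValueError(f"unknown loop pattern symbol {p[i]!r}")
            out.append(_IUPAC[p[i]])
            i += 1
    return re.compile("(?=(" + "".join(out) + "))"), len(out)


def can_pair(a: str, b: str, allow_wobble: bool = True) -> bool:
    if (a, b) in WC_PAIRS:
        return True
    return allow_wobble and (a, b) in WOBBLE_PAIRS


@dataclass
class Hairpin:
    """A tetraloop-anchored stem-loop within a sequence window.

    ``pairs`` lists (i, j) index pairs ordered loop-proximal first, so
    ``pairs[0]`` is the loop-closing pair.  ``bulges_5p``/``bulges_3p`` are
    indices of unpaired nucleotides interior to the paired region on each
    arm.  ``arm5_steps``/``arm3_steps`` optionally override the number of
    paired stem steps each arm supports; this encodes variant structures
    (e.g. multibranch junctions that truncate one arm) which a two-arm
    nested scanner cannot derive from sequence alone.
    """

    seq: str
    loop_start: int
    loop_len: int
    pairs: List[Tuple[int, int]]
    bulges_5p: Tuple[int, ...] = ()
    bulges_3p: Tuple[int, ...] = ()
    arm5_steps: Optional[int] = None
    arm3_steps: Optional[int] = None

    @property
    def loop_end(self) -> int:
        return self.loop_start + self.loop_len

    @property
    def loop_seq(self) -> str:
        return self.seq[self.loop_start : self.loop_end]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def arm5(self) -> int:
        return self.arm5_steps if self.arm5_steps is not None else self.n_pairs

    @property
    def arm3(self) -> int:
        return self.arm3_steps if self.arm3_steps is not None else self.n_pairs

    @property
    def n_bulges(self) -> int:
        return len(self.bulges_5p) + len(self.bulges_3p)

    def dot_bracket(self) -> str:
        s = ["."] * len(self.seq)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def scan_hairpins(
    seq: str,
    loop_pattern: str = "[AU]GNN",
    min_arm_pairs: int = 8,
    max_bulges_per_arm: int = 2,
    allow_wobble: bool = True,
) -> List[Hairpin]:
    """Find stem-loops anchored at every loop-pattern occurrence.

    For each occurrence the stem is extended outward from the loop-closing
    pair, maximizing the number of nested pairs while permitting at most
    ``max_bulges_per_arm`` single-nucleotide bulges on each arm (adjacent
    bulges on the same arm, i.e. >=2-nt asymmetries, terminate the stem; a
    mismatch costs one bulge on each arm).  Among equal-pair extensions the
    tie-break is deterministic: pair > 5'-arm bulge > 3'-arm bulge.  Only
    hairpins with at least ``min_arm_pairs`` pairs are reported, in loop
    order (leftmost first).
    """
    s = normalize_rna(seq)
    rx, loop_len = _loop_regex(loop_pattern)
    if len(s) < 2 * min_arm_pairs + loop_len:
        return []
    out: List[Hairpin] = []
    for m in rx.finditer(s):
        l = m.start()
        h = _extend_stem(s, l, loop_len, max_bulges_per_arm, allow_wobble)
        if h is not None and h.n_pairs >= min_arm_pairs:
            out.append(h)
    return out


# moves: 0 = pair, 1 = 5'-arm bulge, 2 = 3'-arm bulge
def _extend_stem(
    s: str, loop_start: int, loop_len: int, max_bulges: int, allow_wobble: bool
) -> Optional[Hairpin]:
    n = len(s)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, b5: int, b3: int, last: int) -> int:
        """Maximum additional pairs reachable from state (i, j)."""
        m = 0
        if i >= 0 and j < n and can_pair(s[i], s[j], allow_wobble):
            m = max(m, 1 + best(i - 1, j + 1, b5, b3, 0))
        if i >= 0 and b5 < max_bulges and last != 1:
            m = max(m, best(i - 1, j, b5 + 1, b3, 1))
        if j < n and b3 < max_bulges and last != 2:
            m = max(m, best(i, j + 1, b5, b3 + 1, 2))
        return m

    i, j = loop_start - 1, loop_start + loop_len
    # the loop-closing pair must pair: a bulge against the loop would merely
    # enlarge the loop, which is the business of a longer loop pattern
    if i < 0 or j >= n or not can_pair(s[i], s[j], allow_wobble):
        return None
    pairs: List[Tuple[int, int]] = [(i, j)]
    bulges_5p: List[int] = []
    bulges_3p: List[int] = []
    i, j, b5, b3, last = i - 1, j + 1, 0, 0, 0
    while True:
        target = best(i, j, b5, b3, last)
        if target == 0:
            break
        if (
            i >= 0 and j < n and can_pair(s[i], s[j], allow_wobble)
            and 1 + best(i - 1, j + 1, b5, b3, 0) == target
        ):
            pairs.append((i, j))
            i, j, last = i - 1, j + 1, 0
        elif (
            i >= 0 and b5 < max_bulges and last != 1
            and best(i - 1, j, b5 + 1, b3, 1) == target
        ):
            bulges_5p.append(i)
            i, b5, last = i - 1, b5 + 1, 1
        else:
            bulges_3p.append(j)
            j, b3, last = j + 1, b3 + 1, 2
    return Hairpin(
        seq=s,
        loop_start=loop_start,
        loop_len=loop_len,
        pairs=pairs,
        bulges_5p=tuple(bulges_5p),
        bulges_3p=tuple(bulges_3p),
    )


@dataclass
class CleavageGeometry:
    """Predicted RNase III product 5'-end positions for a hairpin.

    The enzyme cuts after the 14th paired stem step on the 5' arm and after
    the 16th on the 3' arm (counting from the loop), so linear distances
    exceed 14/16 by the number of bulged nucleotides traversed, and the
    excised duplex carries a ``down_stem_steps - up_stem_steps`` = 2 nt 3'
    overhang.  Sides whose arm does not support the required steps are None.
    """

    up_stem_steps: int = 14
    down_stem_steps: int = 16
    predicted_up_pos: Optional[int] = None
    predicted_down_pos: Optional[int] = None
    up_linear_dist: Optional[int] = None
    down_linear_dist: Optional[int] = None
    overhang_nt: Optional[int] = None

    @property
    def spacing(self) -> Optional[int]:
        if self.predicted_up_pos is None or self.predicted_down_pos is None:
            return None
        return self.predicted_down_pos - self.predicted_up_pos

    @property
    def two_sided(self) -> bool:
        return self.predicted_up_pos is not None and self.predicted_down_pos is not None


def predict_cleavage(
    h: Hairpin, up_steps: int = 14, down_steps: int = 16
) -> Optional[CleavageGeometry]:
    """Map the 14/16 cleavage rule onto a hairpin's pairing register.

    Walks ``up_steps`` paired steps down the 5' arm and ``down_steps`` down
    the 3' arm; bulged nucleotides traversed on the way lengthen the linear
    distances (a single 5'-arm bulge within the first 14 steps gives a
    15-nt upstream distance).  Returns None when neither arm supports its
    side; a one-sided geometry is returned when only one does.
    """
    geo = CleavageGeometry(up_stem_steps=up_steps, down_stem_steps=down_steps)
    up_ok = h.arm5 >= up_steps and h.n_pairs >= up_steps
    down_ok = h.arm3 >= down_steps and h.n_pairs >= down_steps
    if not up_ok and not down_ok:
        return None
    if up_ok:
        geo.predicted_up_pos = h.pairs[up_steps - 1][0]
        geo.up_linear_dist = h.loop_start - geo.predicted_up_pos
    if down_ok:
        geo.predicted_down_pos = h.pairs[down_steps - 1][1] + 1
        geo.down_linear_dist = geo.predicted_down_pos - h.loop_end
    if up_ok and down_ok:
        geo.overhang_nt = down_steps - up_steps
    return geo


def stem_score(h: Hairpin) -> float:
    """Simple stem-stability score: WC pair = 2, G.U = 1, bulge = -2.

    A deliberately coarse stand-in for folding free energy: enough to rank
    a stem against a point-mutated variant (a broken pair both removes its
    weight and adds two bulges, so the mutant always scores strictly lower).
    """
    score = 0.0
    for i, j in h.pairs:
        score += 2.0 if (h.seq[i], h.seq[j]) in WC_PAIRS else 1.0
    score -= 2.0 * h.n_bulges
    return score


@dataclass
class LoopConsensus:
    """Base-frequency matrix over loop positions plus flanking nucleotides."""

    counts: pd.DataFrame  # rows A/C/G/U, columns -flank..L1..Ln..+flank
    n_loops: int
    loop_len: int
    flank: int

    def fraction(self) -> pd.DataFrame:
        return self.counts / self.n_loops

    def dominant(self, position: int | str) -> Tuple[str, float]:
        """Modal base and its fraction at a column (1-based loop position or label)."""
        col = f"L{position}" if isinstance(position, int) else position
        c = self.counts[col]
        base = c.idxmax()
        return base, float(c[base] / self.n_loops)


def loop_consensus(hairpins: Sequence[Hairpin], flank: int = 3) -> LoopConsensus:
    """Tabulate loop (and flanking) base frequencies, aligned on loop position 1."""
    if not hairpins:
        raise ValueError("no hairpins supplied")
    loop_lens = {h.loop_len for h in hairpins}
    if len(loop_lens) != 1:
        raise ValueError(f"mixed loop lengths {sorted(loop_lens)}; align per length")
    L = loop_lens.pop()
    cols = (
        [f"-{k}" for k in range(flank, 0, -1)]
        + [f"L{k}" for k in range(1, L + 1)]
        + [f"+{k}" for k in range(1, flank + 1)]
    )
    counts = pd.DataFrame(0, index=list("ACGU"), columns=cols)
    for h in hairpins:
        lo, hi = h.loop_start - flank, h.loop_end + flank
        if lo < 0 or hi > len(h.seq):
            raise ValueError("window too small to extract flanking nucleotides")
        for col, base in zip(cols, h.seq[lo:hi]):
            counts.loc[base, col] += 1
    return LoopConsensus(counts=counts, n_loops=len(hairpins), loop_len=L, flank=flank)


@dataclass
class StructureValidation:
    """Outcome of checking observed cleavage positions against a scanned stem."""

    hairpin: Optional[Hairpin]
    geometry: Optional[CleavageGeometry]
    up_matched: Optional[bool]  # None = side not supported by the stem
    down_matched: Optional[bool]
    verdict: str  # no_hairpin | two_sided | upstream_only | downstream_only | geometry_mismatch

    @property
    def hairpin_found(self) -> bool:
        return self.hairpin is not None


def validate_sites_against_structure(
    observed_positions: Sequence[int],
    window_seq: str,
    window_offset: int = 0,
    tolerance: int = 1,
    hairpin: Optional[Hairpin] = None,
    **scan_kwargs,
) -> StructureValidation:
    """Check whether observed product 5'-ends match a stem's predicted geometry.

    ``observed_positions`` are genomic (transcript-sense) coordinates;
    ``window_offset`` is the genomic coordinate of ``window_seq[0]``.  The
    hairpin is scanned from the window unless supplied (variant structures
    with asymmetric arm support can be passed in explicitly).  The best
    candidate is the one matching the most observed sides, breaking ties by
    stem score.
    """
    candidates = [hairpin] if hairpin is not None else scan_hairpins(window_seq, **scan_kwargs)
    best_result: Optional[StructureValidation] = None
    best_rank = (-1, float("-inf"))
    for h in candidates:
        geo = predict_cleavage(h)
        if geo is None:
            continue
        up = down = None
        if geo.predicted_up_pos is not None:
            up = any(
                abs(p - (window_offset + geo.predicted_up_pos)) <= tolerance
                for p in observed_positions
            )
        if geo.predicted_down_pos is not None:
            down = any(
                abs(p - (window_offset + geo.predicted_down_pos)) <= tolerance
                for p in observed_positions
            )
        n_matched = int(bool(up)) + int(bool(down))
        rank = (n_matched, stem_score(h))
        if rank > best_rank:
            best_rank = rank
            if up and down:
                verdict = "two_sided"
            elif up and not down:
                verdict = "upstream_only"
            elif down and not up:
                verdict = "downstream_only"
            else:
                verdict = "geometry_mismatch"
            best_result = StructureValidation(
                hairpin=h, geometry=geo, up_matched=up, down_matched=down, verdict=verdict
            )
    if best_result is None:
        return StructureValidation(
            hairpin=None, geometry=None, up_matched=None, down_matched=None,
            verdict="no_hairpin",
        )
    return best_result
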