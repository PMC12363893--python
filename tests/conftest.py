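"""Shared helpers: constructed hairpins and small simulated experiments."""

import numpy as np
import pytest

from parekit import compare, coverage as cov
from parekit import simulate as sim

RNA_COMP = str.maketrans("ACGU", "UGCA")


def revcomp_rna(s: str) -> str:
    return s.translate(RNA_COMP)[::-1]


def make_stem_seq(
    n_pairs: int = 20,
    loop: str = "AGGA",
    arm: str | None = None,
    arm_seed: int = 7,
    flank: str = "AAA",
) -> str:
    """A perfect hairpin: flank + arm + loop + revcomp(arm) + flank.

    The A-run flanks cannot pair with each other (A.A is neither WC nor
    wobble), so the stem has exactly ``n_pairs`` pairs.
    """
    if arm is None:
        rng = np.random.default_rng(arm_seed)
        arm = "".join(rng.choice(list("ACGU"), n_pairs))
    return flank + arm + loop + revcomp_rna(arm) + flank


def nonpairing_base(partner: str) -> str:
    """A base that can pair with ``partner`` neither WC nor wobble."""
    return "A" if partner == "G" else "C"


def make_bulged_stem_seq(
    n_pairs: int = 20, loop: str = "AGGA", k: int = 7, arm_seed: int = 7, flank: str = "AAA"
):
    """Perfect stem with one 5'-arm bulge after ``k`` paired steps from the loop.

    Returns (sequence, loop_start).  The bulged nucleotide is chosen so it
    cannot pair with the 3'-arm base it faces.
    """
    rng = np.random.default_rng(arm_seed)
    arm = "".join(rng.choice(list("ACGU"), n_pairs))
    partner = arm[n_pairs - k - 1].translate(RNA_COMP)  # base the bulge faces on the 3' arm
    bulge = nonpairing_base(partner)
    arm5 = arm[: n_pairs - k] + bulge + arm[n_pairs - k :]
    seq = flank + arm5 + loop + revcomp_rna(arm) + flank
    loop_start = len(flank) + len(arm5)
    return seq, loop_start


def cpm_experiment(cfg: sim.SimConfig, seed: int, mode: str = "in_vivo"):
    """Simulate and cpm-normalize a full WT/mut replicate experiment."""
    fx = sim.make_genome_fixture(cfg, seed=seed)
    exp = sim.simulate_experiment(cfg, fx.truth, mode=mode, seed=seed)
    wt = [cov.cpm_normalize_all(ts) for ts in exp["WT"]]
    mut = [cov.cpm_normalize_all(ts) for ts in exp["mut"]]
    return fx, wt, mut


def call_experiment(cfg: sim.SimConfig, seed: int, mode: str = "in_vivo"):
    fx, wt, mut = cpm_experiment(cfg, seed, mode)
    sites = compare.call_sites_genomewide(wt, mut)
    return fx, sites


@pytest.fixture(scope="session")
def default_fixture():
    """One default-condition simulated dataset shared across read-only tests."""
    cfg = sim.SimConfig()
    fx, sites = call_experiment(cfg, seed=1)
    return cfg, fx, sites
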