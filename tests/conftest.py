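import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spikecal import simulate as sim

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chip_config():
    return sim.SimConfig(seed=1)


@pytest.fixture(scope="session")
def null_chip(chip_config):
    return sim.simulate_chip_experiment(chip_config, sim.Scenario("null"))


@pytest.fixture(scope="session")
def blanket_loss_chip(chip_config):
    """Uniform genome-wide depletion, punctate pool untouched."""
    return sim.simulate_chip_experiment(
        chip_config, sim.Scenario("blanket_loss", blanket_scale=0.2))


@pytest.fixture(scope="session")
def peak_loss_chip(chip_config):
    """Punctate depletion at every peak, blanket untouched."""
    return sim.simulate_chip_experiment(
        chip_config, sim.Scenario("peak_loss", peak_scale=0.2))


@pytest.fixture(scope="session")
def allelic_run():
    return sim.simulate_allelic_silencing(seed=3)


def brute_force_counts(fragments: pd.DataFrame,
                       intervals: pd.DataFrame) -> np.ndarray:
    """O(n*m) midpoint-containment counting, first-containing-interval rule.

    Mirrors the production assignment contract (at most one interval per
    fragment; for non-overlapping intervals the containing one) without
    sharing any code with it.
    """
    counts = np.zeros(len(intervals), np.int64)
    iv = intervals.reset_index(drop=True)
    for chrom, pos in zip(fragments["chrom"], fragments["pos"]):
        best = None
        for i in range(len(iv)):
            if (iv.at[i, "chrom"] == chrom and iv.at[i, "start"] <= pos
                    < iv.at[i, "end"]):
                if best is None or iv.at[i, "start"] > iv.at[best, "start"]:
                    best = i
        if best is not None:
            counts[best] += 1
    return counts


def brute_force_overlaps(query: pd.DataFrame, subject: pd.DataFrame
                         ) -> np.ndarray:
    """All-pairs >=1 bp overlap test."""
    out = np.zeros(len(query), bool)
    q = query.reset_index(drop=True)
    s = subject.reset_index(drop=True)
    for i in range(len(q)):
        for j in range(len(s)):
            if (q.at[i, "chrom"] == s.at[j, "chrom"]
                    and max(q.at[i, "start"], s.at[j, "start"])
                    < min(q.at[i, "end"], s.at[j, "end"])):
                out[i] = True
                break
    return out


def brute_force_merge(intervals: pd.DataFrame) -> pd.DataFrame:
    """Fixpoint pairwise merging of overlapping/bookended intervals."""
    items = [tuple(r) for r in
             intervals[["chrom", "start", "end"]].itertuples(index=False)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and max(si, sj) <= min(ei, ej):
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return (pd.DataFrame(items, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"]).reset_index(drop=True))


def random_interval_set(rng, n, genome=("chrA", "chrB"), size=100_000,
                        max_len=2_000) -> pd.DataFrame:
    chrom = rng.choice(list(genome), size=n)
    start = rng.integers(0, size - max_len, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": start + length})
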