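import numpy as np
import pytest

from mitopunct import synthetic


@pytest.fixture(scope="session")
def toy():
    """Default toy mitogenome: (sequence, truth)."""
    return synthetic.build_toy_mitogenome()


@pytest.fixture(scope="session")
def toy_cohort():
    """Four annotated genomes diverged from one ancestor by 0/60/120/180
    substitutions (no in-frame stops introduced)."""
    from mitopunct.compara import AnnotatedGenome

    seq, truth = synthetic.build_toy_mitogenome(
        synthetic.ToyGenomeSpec(seed=11))
    genomes = []
    for i, nsub in enumerate((0, 60, 120, 180)):
        mutated = synthetic.mutate_genome(seq, truth, nsub, seed=100 + i)
        genomes.append(AnnotatedGenome(f"taxon{i}", mutated, truth.features))
    return genomes, truth


def random_profile(seed: int, length: int = 1000):
    """Random base-count profile with sites straddling the caller thresholds."""
    from mitopunct.depthmap import BaseCountProfile

    rng = np.random.default_rng(seed)
    counts = np.zeros((length, 4), dtype=np.int64)
    ref = rng.integers(0, 4, size=length)
    depth = rng.integers(50, 400, size=length)
    counts[np.arange(length), ref] = depth
    # straddle the three conditions: depths around 100, minor counts around
    # the 10% frequency bar, plus unambiguous deep sites
    n_hot = min(60, length // 2)
    hot = rng.choice(length, size=n_hot, replace=False)
    for p in hot[:2 * n_hot // 3]:
        d = int(rng.choice([99, 100, 101, 102, 110, 150, 200]))
        m = int(rng.choice([0, 1, 9, 10, 11, 12, 15, 20, 21]))
        m = min(m, d // 2)
        alt = (ref[p] + 1 + rng.integers(3)) % 4
        counts[p] = 0
        counts[p, ref[p]] = d - m
        counts[p, alt] = m
    for p in hot[2 * n_hot // 3:]:
        counts[p] = 0
        counts[p, ref[p]] = 400
        counts[p, (ref[p] + 1) % 4] = 100
    return BaseCountProfile(counts)
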