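import numpy as np
import pytest

import sibmap as sm
from sibmap.markers import MarkerGenotypes


@pytest.fixture(scope="session")
def small_true_map():
    return sm.simulate_true_map(3, [80.0, 60.0, 70.0], 20, seed=11)


@pytest.fixture(scope="session")
def small_family(small_true_map):
    fam, truth = sm.simulate_family(
        small_true_map, sm.CrossSpec(n_offspring=120, seed=42)
    )
    return fam, truth


@pytest.fixture(scope="session")
def clean_family(small_true_map):
    """Noise-free family on the same map."""
    fam, truth = sm.simulate_family(
        small_true_map,
        sm.CrossSpec(n_offspring=120, error_rate=0.0, missing_rate=0.0, seed=42),
    )
    return fam, truth


def fully_informative_pair(n_offspring, recombinants, locus_ids=("A", "B")):
    """Phase-known AB x CD pair with a given number of *paired* recombinant
    offspring (each recombinant offspring flips both meioses is avoided:
    recombination is put on the maternal meiosis only would halve N, so we
    flip whole offspring on one parent each)."""
    mo, fa = ("a", "b"), ("c", "d")
    calls_a = [("a", "c")] * n_offspring
    calls_b = []
    half = recombinants // 2
    for i in range(n_offspring):
        # first `half` offspring: maternal recombinant; next `recombinants-half`: paternal
        if i < half:
            calls_b.append(tuple(sorted(("b", "c"))))
        elif i < recombinants:
            calls_b.append(tuple(sorted(("a", "d"))))
        else:
            calls_b.append(("a", "c"))
    a = MarkerGenotypes(locus_ids[0], "cA", "fam", mo, fa, calls_a)
    b = MarkerGenotypes(locus_ids[1], "cB", "fam", mo, fa, calls_b)
    return a, b


def maternal_pair(n_meioses, recombinants):
    """LM x LL pair: n_meioses maternal meioses, given recombinant count."""
    mo, fa = ("l", "m"), ("l", "l")
    calls_a = [("l", "l")] * n_meioses
    calls_b = [("l", "m")] * recombinants + [("l", "l")] * (n_meioses - recombinants)
    a = MarkerGenotypes("A", "cA", "fam", mo, fa, calls_a)
    b = MarkerGenotypes("B", "cB", "fam", mo, fa, calls_b)
    return a, b
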