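import random

import pytest

from glub1typer.pcr import revcomp


@pytest.fixture(scope="session")
def panel():
    from glub1typer.panel import load_panel

    return load_panel()


@pytest.fixture(scope="session")
def panel_map(panel):
    return {ps.id: ps for ps in panel}


def rand_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def naive_binding_sites(primer: str, template: str, policy, strand: str):
    """Exhaustive sliding-window reference scan (independent of the package's
    vectorized implementation)."""
    probe = primer if strand == "plus" else revcomp(primer)
    w = len(probe)
    if strand == "plus":
        exact = range(w - policy.three_prime_exact_len, w)
    else:
        exact = range(policy.three_prime_exact_len)
    sites = []
    for pos in range(len(template) - w + 1):
        window = template[pos : pos + w]
        mism = [
            i
            for i in range(w)
            if window[i] != probe[i]
            or (window[i] == "N" and policy.n_matches == "never")
        ]
        if policy.n_matches == "wildcard":
            mism = [i for i in mism if window[i] != "N"]
        if any(i in mism for i in exact):
            continue
        if len(mism) <= policy.max_internal_mismatches:
            sites.append((pos, len(mism)))
    return sites
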