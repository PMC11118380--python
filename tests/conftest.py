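import numpy as np
import pytest

import phdecon


@pytest.fixture(scope="session")
def kernel():
    return phdecon.make_kernel()


@pytest.fixture(scope="session")
def fixtures():
    """Packaged toy fixtures (12-gene matrix, 5-protein proteome)."""
    return phdecon.fixture_tables()


@pytest.fixture()
def toy_matrix():
    """Tiny handmade 2-replicate-set matrix for validation tests."""
    import pandas as pd

    design = pd.DataFrame({
        "sample_id": [f"{c}_r{r}" for r in (1, 2) for c in phdecon.CONDITIONS],
        "condition": [c for _ in (1, 2) for c in phdecon.CONDITIONS],
        "replicate_set": [r for r in (1, 2) for _ in phdecon.CONDITIONS],
    })
    counts = pd.DataFrame(
        {s: [100.0, 50.0, 10.0] for s in design["sample_id"]},
        index=["g1", "g2", "g3"],
    )
    return phdecon.ExpressionMatrix(counts, design)


def brute_force_profile(sequence: str, kernel) -> np.ndarray:
    """Independent O(n * span) histidine profile: direct weight summation."""
    n = len(sequence)
    half = kernel.span // 2
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for k in range(-half, half + 1):
            j = i + k
            if 0 <= j < n and sequence[j] == "H":
                total += np.exp(-(k**2) / (2.0 * kernel.sigma**2))
        out[i] = total
    return out


def brute_force_peaks(profile, threshold, min_sep):
    """Independent naive peak caller mirroring the documented contract."""
    cands = []
    n = len(profile)
    for i in range(n):
        if profile[i] <= threshold:
            continue
        left = profile[i - 1] if i > 0 else float("-inf")
        right = profile[i + 1] if i < n - 1 else float("-inf")
        if profile[i] >= left and profile[i] >= right:
            cands.append(i)
    merged = []
    for i in cands:
        if merged and i - merged[-1] < min_sep:
            if profile[i] > profile[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return [i + 1 for i in merged]


def max_his_in_window(sequence: str, span: int) -> int:
    """Brute-force max histidine count over any window of `span` residues."""
    best = 0
    n = len(sequence)
    for i in range(n):
        window = sequence[i : i + span]
        best = max(best, window.count("H"))
    return best


def random_protein(rng, length, p_his=0.05):
    aas = list("ACDEFGQLMNPKRSTVWY")
    seq = rng.choice(aas, size=length)
    his = rng.random(length) < p_his
    seq[his] = "H"
    return "".join(seq)
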