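import warnings

import numpy as np
import pytest

import lovkit as lk
from lovkit.simulate import gen_decay_histogram


@pytest.fixture(scope="session")
def table3_decay_fit():
    """One 5e6-count three-component reconvolution fit, shared by the
    fluorescence tests and the acceptance suite (it is the slowest fit)."""
    hist, truth = gen_decay_histogram(
        tau=[0.05, 1.2, 3.37],
        f=[0.52, 0.097, 0.383],
        irf_fwhm=0.8,
        total_counts=5e6,
        seed=21,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = lk.fit_decay(hist, 3)
    return fit, truth


def brute_force_motif_hits(seq: str, tolerate: bool) -> list[int]:
    """Position-by-position motif oracle, independent of the scanner."""
    pos4 = "CP" if tolerate else "C"
    pos6 = "FY" if tolerate else "F"
    hits = []
    for i in range(len(seq) - 8):
        w = seq[i : i + 9]
        if (
            w[0] == "G"
            and w[2] == "N"
            and w[3] in pos4
            and w[4] == "R"
            and w[5] in pos6
            and w[6] == "L"
            and w[7] == "Q"
            and w[8] == "G"
        ):
            hits.append(i + 1)
    return hits


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
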