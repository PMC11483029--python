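import numpy as np
import pandas as pd
import pytest

from bpcompete.io_formats import ClassedCountMatrix, GenomeSequence, IntronAnnotation

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def random_window_set(
    rng: np.random.Generator, n: int, dual_prevalence: float, length: int = 80
) -> list[str]:
    """80-nt windows; a fraction carry two independent planted ACTAA cores."""
    out = []
    for _ in range(n):
        seq = random_dna(rng, length)
        if rng.random() < dual_prevalence:
            p1 = int(rng.integers(0, length // 2 - 5))
            p2 = int(rng.integers(length // 2, length - 5))
            seq = seq[:p1] + "ACTAA" + seq[p1 + 5 :]
            seq = seq[:p2] + "ACTAA" + seq[p2 + 5 :]
        out.append(seq)
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240617)


@pytest.fixture
def toy_matrix() -> ClassedCountMatrix:
    """Two intron-containing genes + one intronless gene, 3v3 samples."""
    samples = ["c1", "c2", "c3", "i1", "i2", "i3"]
    data = pd.DataFrame(
        {
            "gA_pre": [10, 12, 11, 40, 42, 41],
            "gA_m": [95, 93, 94, 65, 63, 64],
            "gB_pre": [20, 22, 21, 20, 21, 22],
            "gB_m": [180, 178, 179, 180, 179, 178],
            "gC_m": [500, 510, 505, 495, 505, 500],
        },
        index=samples,
    ).T
    classes = pd.Series(
        {
            "gA_pre": "unspliced",
            "gA_m": "spliced",
            "gB_pre": "unspliced",
            "gB_m": "spliced",
            "gC_m": "intronless",
        }
    )
    genes = pd.Series(
        {"gA_pre": "gA", "gA_m": "gA", "gB_pre": "gB", "gB_m": "gB", "gC_m": "gC"}
    )
    conditions = pd.Series(
        {s: ("control" if s.startswith("c") else "induced") for s in samples}
    )
    return ClassedCountMatrix(data, classes, genes, conditions)


@pytest.fixture
def plus_intron() -> tuple[GenomeSequence, IntronAnnotation]:
    rng = np.random.default_rng(7)
    seq = random_dna(rng, 400)
    genome = GenomeSequence("chrT", seq)
    intron = IntronAnnotation("t1.intron1", "t1", "chrT", 100, 300, "+")
    return genome, intron
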