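import numpy as np
import pytest

from kincompare.pedigree import Record, Studbook


@pytest.fixture
def trio_studbook() -> Studbook:
    """Two unrelated wild founders and one offspring."""
    return Studbook(
        [
            Record("A", None, None, "M", 2000, True, "wild"),
            Record("B", None, None, "F", 2000, True, "wild"),
            Record("C", "A", "B", "F", 2001, True, "captive"),
        ]
    )


@pytest.fixture
def family_studbook() -> Studbook:
    """Founder pair, two full sibs, and an inbred full-sib-mating child."""
    return Studbook(
        [
            Record("A", None, None, "M", 2000, True, "wild"),
            Record("B", None, None, "F", 2000, True, "wild"),
            Record("C", "A", "B", "M", 2001, True, "captive"),
            Record("D", "A", "B", "F", 2001, True, "captive"),
            Record("E", "C", "D", "M", 2003, True, "captive"),
        ]
    )


def random_studbook(rng: np.random.Generator, n_extra: int = 12) -> Studbook:
    """A random valid pedigree: 4 founders plus n_extra descendants."""
    records = [
        Record("F0", None, None, "M", 2000, True, "wild"),
        Record("F1", None, None, "F", 2000, True, "wild"),
        Record("F2", None, None, "M", 2000, True, "wild"),
        Record("F3", None, None, "F", 2000, True, "wild"),
    ]
    males = ["F0", "F2"]
    females = ["F1", "F3"]
    for k in range(n_extra):
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        sex = "M" if rng.random() < 0.5 else "F"
        i = f"I{k:02d}"
        records.append(Record(i, sire, dam, sex, 2001 + k, True, "captive"))
        (males if sex == "M" else females).append(i)
    return Studbook(records)
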