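import numpy as np
import pytest

from hwturnover import DEFAULT_CURVE, PeptideChemistry

STUDY_DAYS = np.array([0.0, 1.0, 3.0, 6.0, 15.0, 31.0, 63.0, 127.0])


@pytest.fixture(scope="session")
def curve():
    """The default body-water enrichment curve (kp=0.7913/day, pss=0.0558)."""
    return DEFAULT_CURVE


@pytest.fixture(scope="session")
def comp_chem():
    """Chemistry of a real matrix-protein peptide (COMP)."""
    return PeptideChemistry.from_sequence("QMEQTYWQANPFR")


@pytest.fixture(scope="session")
def study_days():
    return STUDY_DAYS.copy()


def integer_n_chem(a: float = 0.9, n: int = 12) -> PeptideChemistry:
    """A synthetic peptide chemistry with an exactly integer site count."""
    from hwturnover.chem import ElementComposition

    return PeptideChemistry(
        sequence="SYNTHETIC", composition=ElementComposition({"C": 1}), a=a, n_sites=float(n)
    )
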