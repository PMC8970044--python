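import numpy as np
import pytest

from glycoprm.chem import GlycanComposition, Glycopeptide
from glycoprm.io import Spectrum, default_target_list


@pytest.fixture(scope="session")
def targets():
    return default_target_list()


@pytest.fixture()
def headline_gp():
    """The site-762 bi-fucosylated tri-antennary target."""
    return Glycopeptide(
        sequence="ELHHLQEQNVSNAFLDK",
        glycosite=762,
        glycan=GlycanComposition.parse("HexNAc(5)Hex(6)Fuc(2)NeuAc(3)"),
    )


def spectrum_from_peaks(peaks, scan_id="s1", precursor_mz=1000.0, charge=3, rt=30.0):
    mz, inten = zip(*peaks) if peaks else ((), ())
    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        retention_time_min=rt,
        mz=np.array(mz, dtype=float),
        intensity=np.array(inten, dtype=float),
    )


@pytest.fixture()
def make_spectrum():
    return spectrum_from_peaks
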