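import pytest

from driftccs.io import CalibrantIon, TargetMolecule
from driftccs.physics import NITROGEN, PROTON_MASS_DA
from driftccs.synth import SyntheticIon, TUNE_MIX_LIKE_IONS
from driftccs.targets import AdductSpec, TargetIon


@pytest.fixture
def tune_mix_ions() -> list[SyntheticIon]:
    """Phosphazine-like singly-charged calibrant series with nitrogen CCS."""
    return list(TUNE_MIX_LIKE_IONS)


@pytest.fixture
def tune_mix_calibrants(tune_mix_ions) -> list[CalibrantIon]:
    return [
        CalibrantIon(t.name, t.mz, t.charge_z, t.ccs, t.polarity)
        for t in tune_mix_ions
    ]


@pytest.fixture
def protonated_322_target() -> TargetIon:
    """[M+H]+ target whose expected m/z is the 322.0481 calibrant ion."""
    mol = TargetMolecule("cal322", 322.0481 - PROTON_MASS_DA)
    return TargetIon(mol, AdductSpec("[M+H]+", PROTON_MASS_DA, 1, "positive"))


@pytest.fixture
def nitrogen():
    return NITROGEN
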