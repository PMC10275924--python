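import pytest

from aedes_gss.genetics import StrainSpec, parse_genotype
from aedes_gss.sorting import CalibrationPoint


@pytest.fixture
def aal_strains():
    """An M-linked (YFP) and an m-linked (GFP) strain pair with the m strain
    recombining at 0.1% — the configuration used for crossing-scheme sorts."""
    M_strain = StrainSpec(
        name="M-linked",
        male_genotype=parse_genotype("m/M[YFP]"),
        female_genotype=parse_genotype("m/m"),
        recomb_rate=0.0,
    )
    m_strain = StrainSpec(
        name="m-linked",
        male_genotype=parse_genotype("m[GFP]/M"),
        female_genotype=parse_genotype("m[GFP]/m[GFP]"),
        recomb_rate=0.001,
    )
    return M_strain, m_strain


@pytest.fixture
def printed_calibration_means():
    """The three measured mean calibration points (fractions): recovery falls
    from 91.5% at 6 larvae/s to 26.9% at 300 larvae/s, contamination absent."""
    return [
        CalibrationPoint(speed=6.0, recovery=0.915, contamination=0.0, replicate_id=0),
        CalibrationPoint(speed=60.0, recovery=0.696, contamination=0.0, replicate_id=0),
        CalibrationPoint(speed=300.0, recovery=0.269, contamination=0.0, replicate_id=0),
    ]
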