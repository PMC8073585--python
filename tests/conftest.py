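import pytest
from hypothesis import settings

from prmkit.assay import load_bundled_panel
from prmkit.simulate import make_study_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# Printed reference values for the bundled 18-peptide panel:
# peptide -> (charge, light m/z, heavy m/z).  Frozen from the published
# target list; every value is recomputed by the package and compared
# within 0.005 Th.
PRINTED_PANEL_MZ = {
    "ALNSIIDVYHK": (3, 424.903, 427.574),
    "GADVWFK": (2, 411.710, 415.718),
    "DLYNFLK": (2, 456.744, 460.752),
    "LLGDFFR": (2, 434.239, 439.243),
    "ENAGEDPGLAR": (2, 564.767, 569.771),
    "IQGTCYR": (2, 449.216, 454.220),
    "GIGDPVTCLK": (2, 530.278, 534.285),
    "GIINTLQK": (2, 443.771, 447.778),
    "ICGYGTAR": (2, 449.216, 454.220),
    "QELNPLK": (2, 421.242, 425.249),
    "SILLTEQALAK": (2, 593.855, 597.862),
    "VPLQQNFQDNQFQGK": (2, 895.944, 899.951),
    "SYNVTSVLFR": (2, 593.316, 598.320),
    "TFVPGCQPGEFTLGNIK": (2, 932.966, 936.973),
    "GISLANWMCLAK": (2, 682.346, 686.353),
    "WESGYNTR": (2, 506.727, 511.731),
    "SIIGMIDMFHK": (2, 646.330, 650.337),
    "CLEQVSQLQGLWR": (2, 808.914, 813.918),
}


@pytest.fixture(scope="session")
def bundled_panel():
    return load_bundled_panel()


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture()
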