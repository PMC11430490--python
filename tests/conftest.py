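import pytest

from mitoprofile.layouts import reference_annotation
from mitoprofile.synth import default_layout, generate_genome

# Printed reference-table values for the 37-gene fixture, frozen as
# (length bp, gap to next feature in bp or None where the table leaves the
# final cell blank).  Genome order.
PRINTED_TABLE = {
    "trnF(ttc)": (71, 0),
    "rrnS": (949, 0),
    "trnV(gta)": (66, -2),
    "rrnL": (1565, 0),
    "trnL2(tta)": (75, 2),
    "nad1": (951, 4),
    "trnI(atc)": (70, -3),
    "trnQ(caa)": (72, 0),
    "trnM(atg)": (68, 0),
    "nad2": (1038, 4),
    "trnW(tga)": (67, 7),
    "trnA(gca)": (69, 1),
    "trnN(aac)": (73, 32),
    "trnC(tgc)": (66, 0),
    "trnY(tac)": (65, 1),
    "cox1": (1542, 0),
    "trnS2(tca)": (69, 3),
    "trnD(gac)": (69, 1),
    "cox2": (660, 68),
    "trnK(aaa)": (68, 1),
    "atp8": (183, -22),
    "atp6": (675, 5),
    "cox3": (783, 1),
    "trnG(gga)": (67, 0),
    "nad3": (345, 1),
    "trnR(cga)": (65, 0),
    "nad4l": (294, -4),
    "nad4": (1368, 10),
    "trnH(cac)": (69, 0),
    "trnS1(agc)": (59, 0),
    "trnL1(cta)": (71, 3),
    "nad5": (1800, 15),
    "nad6": (519, 0),
    "trnE(gaa)": (69, 4),
    "cob": (1134, 7),
    "trnT(aca)": (65, 2),
    "trnP(cca)": (67, None),
}


@pytest.fixture(scope="session")
def genes_only_annotation():
    """The 37-gene reference annotation without the control region row."""
    return reference_annotation(include_control_region=False)


@pytest.fixture(scope="session")
def full_annotation():
    """The reference annotation including the origin-spanning control region."""
    return reference_annotation(include_control_region=True)


@pytest.fixture(scope="session")
def default_genome():
    """Deterministic synthetic genome realizing the default layout."""
    return generate_genome(default_layout(), at_target=0.614, seed=42)
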