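import pytest

from atcmap import (
    AtcDictionary,
    RadKind,
    RadTarget,
    RegimenDictionary,
    SyntheticConfig,
    build_fixture_set,
    default_stoplist,
)


@pytest.fixture(scope="session")
def mini_atc() -> AtcDictionary:
    """Hand-built ATC dictionary covering the worked examples.

    METHOTREXAT maps to two codes (one antineoplastic, one not) to exercise
    multi-code resolution; M01CX0 is deliberately the six-character form and
    is structurally invalid, which the loader policy tolerates.
    """
    atc = AtcDictionary()
    atc.add("Methotrexat", "L01BA01", name="Methotrexat")
    atc.add("Methotrexat", "M01CX0")
    atc.add("Cisplatin", "L01XA01", name="Cisplatin")
    atc.add("Fluorouracil", "L01BC02", name="Fluorouracil")
    atc.add("Etoposid", "L01CB01", name="Etoposid")
    atc.add("Calciumfolinat", "V03AF03", name="Calciumfolinat")
    atc.add("Oxaliplatin", "L01XA03", name="Oxaliplatin")
    atc.add("Ondansetron", "A04AA01", name="Ondansetron")
    atc.add("Mitomyc*", "L01DC03", name="Mitomycin")
    return atc


@pytest.fixture(scope="session")
def mini_rad() -> RegimenDictionary:
    rad = RegimenDictionary()
    rad.add("5-FU", RadTarget(kind=RadKind.EXPANSION, names=("FLUOROURACIL",)))
    rad.add(
        "FOLFOX",
        RadTarget(
            kind=RadKind.EXPANSION,
            names=("FLUOROURACIL", "CALCIUMFOLINAT", "OXALIPLATIN"),
        ),
    )
    rad.add("Studie", RadTarget(kind=RadKind.STUDY, term="Studie"))
    rad.add("TACE", RadTarget(kind=RadKind.INFO, term="TACE"))
    rad.add(
        "Best supportive care",
        RadTarget(kind=RadKind.INFO, term="best supportive care"),
    )
    rad.add("Placebomycin", RadTarget(kind=RadKind.MEDICATION, term="Placebomycin"))
    return rad


@pytest.fixture(scope="session")
def stoplist():
    return default_stoplist()


@pytest.fixture(scope="session")
def fixture_set():
    """Deterministic synthetic fixture set (toy ATC, RAD, stoplist, corpus)."""
    return build_fixture_set(SyntheticConfig(n_entries=200))
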