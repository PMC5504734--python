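import pytest

from acescan.profile import MutationRecord
from acescan.fragments import build_fragment_index, build_site_fragments
from acescan.reference import AceReference
from acescan.simulate import synthetic_reference

TOY_SPECIES = "Synthetica exempli"


@pytest.fixture(scope="session")
def toy_reference() -> AceReference:
    """1803-nt synthetic ace1-like CDS with both conserved motifs and a
    wild-type glycine at residue 119."""
    return synthetic_reference(seed=7, required_residues={119: "G"})


@pytest.fixture(scope="session")
def toy_record() -> MutationRecord:
    """A G119S-style site on the synthetic reference (native == torpedo)."""
    return MutationRecord(
        species=TOY_SPECIES,
        gene="ace1",
        wild_type_aa="G",
        mutant_aa="S",
        torpedo_position=119,
        native_position=119,
        source="synthetic",
    )


@pytest.fixture(scope="session")
def toy_fragments(toy_reference, toy_record):
    return build_site_fragments(toy_reference, toy_record)


@pytest.fixture(scope="session")
def toy_index(toy_fragments):
    return build_fragment_index([toy_fragments])


# the worked toy from the fragment-window definition: codons K P G F K
MINI_CDS = "AAACCCGGGTTTAAA"


@pytest.fixture(scope="session")
def mini_reference() -> AceReference:
    return AceReference(
        species="Minimus toyi",
        gene="ace1",
        accession="MINI1",
        cds=MINI_CDS,
        protein="KPGFK",
    )


@pytest.fixture(scope="session")
def mini_record() -> MutationRecord:
    return MutationRecord(
        species="Minimus toyi",
        gene="ace1",
        wild_type_aa="G",
        mutant_aa="S",
        torpedo_position=3,
        native_position=3,
        source="toy",
    )
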