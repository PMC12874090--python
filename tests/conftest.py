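import numpy as np
import pytest

from hgscan.core_align import AA_LETTERS, ProteinRecord
from hgscan.motif_screen import default_rulesets
from hgscan.profile_hmm import build_profile
from hgscan.synthetic_data import build_default_families


def random_protein(rng: np.random.Generator, length: int, alphabet: str = AA_LETTERS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_record(seq: str, rid: str = "r", sample: str = "s") -> ProteinRecord:
    return ProteinRecord(rid, sample, seq)


@pytest.fixture(scope="session")
def rulesets():
    return default_rulesets()


@pytest.fixture(scope="session")
def families(rulesets):
    """Default synthetic reference families, shared across the suite."""
    return build_default_families(seed=1, rulesets=rulesets)


@pytest.fixture(scope="session")
def hgca_profile(families):
    return build_profile(families["hgcA"].msa, "hgcA")


@pytest.fixture(scope="session")
def profiles(families):
    return {fam: build_profile(build.msa, fam) for fam, build in families.items()}
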