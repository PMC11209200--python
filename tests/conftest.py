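import pytest

from nemascreen.fugacity import default_environment
from nemascreen.registry import bundled_paper_dataset, bundled_ped_reference


@pytest.fixture(scope="session")
def dataset():
    return bundled_paper_dataset()


@pytest.fixture(scope="session")
def ped_reference():
    return bundled_ped_reference()


@pytest.fixture()
def env():
    return default_environment()


# frequently used CAS numbers
OXAMYL = "23135-22-0"
METAM = "137-42-8"
FLUAZAINDOLIZINE = "1254304-22-7"
FLUENSULFONE = "318290-98-1"
FLUOPYRAM = "658066-35-4"
CARVACROL = "499-75-2"
THYMOL = "89-83-8"
CARVONE = "99-49-0"
DODECANOL = "6175-49-1"
OCTANOL3 = "589-98-0"
DECANONE2 = "693-54-9"
UNDECANONE2 = "112-12-9"
ALLICIN = "539-86-6"
GERANIOL = "106-24-1"
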