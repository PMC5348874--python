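import hashlib
from pathlib import Path

import pytest

from ldscape.synthetic_data import SyntheticConfig, generate, table1_scenario


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One seeded synthetic bundle shared by read-only tests."""
    d = tmp_path_factory.mktemp("bundle")
    return generate(SyntheticConfig(seed=11), d)


@pytest.fixture(scope="session")
def table1_bundle(tmp_path_factory):
    """The packaged risk-locus table realized as BED files."""
    d = tmp_path_factory.mktemp("table1")
    return table1_scenario(d)


def tree_digest(root: Path) -> str:
    """Order-stable digest of every file under a directory."""
    h = hashlib.sha256()
    for p in sorted(Path(root).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(root)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
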