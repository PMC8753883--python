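import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromocanvas.io_formats import Annotation, ChromosomeSpec

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture
def chr1():
    return ChromosomeSpec("chr1", 1, 1000)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_annotation(eid="a1", chrom="chr1", start=10, end=50, value=None,
                    hyperlink=None):
    return Annotation(eid, chrom, start, end, value, hyperlink)


@pytest.fixture
def write_tsv(tmp_path):
    """Write rows (lists of str) as a TSV file under tmp_path."""
    def _write(name, rows):
        path = tmp_path / name
        path.write_text(
            "\n".join("\t".join(str(f) for f in row) for row in rows) + "\n",
            encoding="utf-8")
        return path
    return _write
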