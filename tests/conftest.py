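import pysam
import pytest

from strandtracks import synthetic_fixtures as sf
from strandtracks.alignment_core import AlignedRead


def sam_to_bam(sam_path: str) -> str:
    """Sort + index a generated SAM into a queryable BAM next to it."""
    bam = sam_path[:-4] + ".bam"
    pysam.sort("-o", bam, sam_path)
    pysam.index(bam)
    return bam


def load_reads(bam_path: str) -> list[AlignedRead]:
    with pysam.AlignmentFile(bam_path) as fh:
        return [AlignedRead.from_pysam(r) for r in fh
                if not r.is_unmapped and r.cigarstring]


@pytest.fixture(scope="session")
def basic_bundle(tmp_path_factory):
    b = sf.basic_scenario(str(tmp_path_factory.mktemp("basic")), seed=11)
    b.bam = sam_to_bam(b.sam)
    return b


@pytest.fixture(scope="session")
def null_bundle(tmp_path_factory):
    b = sf.null_scenario(str(tmp_path_factory.mktemp("null")), seed=11)
    b.bam = sam_to_bam(b.sam)
    return b


@pytest.fixture(scope="session")
def chimera_bundle(tmp_path_factory):
    b = sf.chimera_scenario(str(tmp_path_factory.mktemp("chimera")), seed=11)
    b.bam = sam_to_bam(b.sam)
    return b


@pytest.fixture(scope="session")
def isoform_bundle(tmp_path_factory):
    b = sf.isoform_scenario(str(tmp_path_factory.mktemp("isoform")), seed=11)
    b.bam = sam_to_bam(b.sam)
    return b


@pytest.fixture(scope="session")
def overlay_bundle(tmp_path_factory):
    b = sf.overlay_scenario(str(tmp_path_factory.mktemp("overlay")), seed=11)
    b.bams = {name: sam_to_bam(p) for name, p in b.sams.items()}
    return b


@pytest.fixture(scope="session")
def basic_reads(basic_bundle):
    return load_reads(basic_bundle.bam)
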