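import pytest

from cismodules.model import MotifModel, UpstreamRegion


@pytest.fixture
def pac():
    return MotifModel("PAC", "GATGAG", 0)


@pytest.fixture
def pac2():
    return MotifModel("PAC2", "GATAAG", 0)


@pytest.fixture
def rrpe():
    return MotifModel("RRPE", "AAAAWTTTT", 1)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="regions.fasta"):
        path = tmp_path / name
        with open(path, "w") as handle:
            for gene_id, seq in records:
                handle.write(f">{gene_id}\n{seq}\n")
        return path
    return _write


@pytest.fixture
def toy_regions():
    return [
        UpstreamRegion("g1", "TTGATGAGCC"),
        UpstreamRegion("g2", "GGCTCATCAA"),
        UpstreamRegion("g3", "ACGTACGTAC"),
    ]
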