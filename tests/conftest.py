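import pytest

from viromehost.synthio import SynthConfig, gen_community


@pytest.fixture(scope="session")
def small_comm():
    """A small community exercised by several suites (cheap to generate)."""
    return gen_community(SynthConfig(
        n_viruses=12, n_hosts=8, n_samples=4, reads_per_sample=800, seed=11))


@pytest.fixture(scope="session")
def small_spacer_db(small_comm):
    from viromehost.crisprdb import build_spacer_db

    lineages = dict(zip(small_comm.host_lineages["genome_id"],
                        small_comm.host_lineages["lineage"]))
    return build_spacer_db(small_comm.hosts, lineages)
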