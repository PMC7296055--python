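import numpy as np
import pytest

from plasmidhost.records import GenomeRecord

BASES = np.array(list("ACGT"))


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, length)])


def write_fasta_text(path, entries):
    """entries: iterable of (header, sequence) pairs."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")
    return path


@pytest.fixture
def fasta_factory(tmp_path):
    def make(name, entries):
        return write_fasta_text(tmp_path / name, entries)

    return make


@pytest.fixture(scope="session")
def small_bundle():
    """3+3 hosts, 120 kb chromosomes: enough for k=2 screens, fast."""
    from plasmidhost.simulate import build_scenario

    return build_scenario(
        n_transconjugant_hosts=3,
        n_other_hosts=3,
        chrom_length=120_000,
        plasmid_length=20_000,
        alpha=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_screen_results(small_bundle):
    from plasmidhost.screen import PlasmidHostScreen

    screen = PlasmidHostScreen(
        small_bundle.plasmid_record,
        small_bundle.host_records,
        small_bundle.metadata.set_index("accession", drop=False),
        ks=(2,),
    )
    return screen.fit()
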