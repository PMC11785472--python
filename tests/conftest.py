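import numpy as np
import pytest

from longamp.reference_data import mini_reference
from longamp.taxonomy import ReferenceEntry, _parse_lineage


@pytest.fixture(scope="session")
def reference_entries() -> list[ReferenceEntry]:
    return [ReferenceEntry(rid, _parse_lineage(lin), seq)
            for rid, lin, seq in mini_reference()]


@pytest.fixture(scope="session")
def reference_fasta_path(tmp_path_factory):
    from longamp.reference_data import reference_fasta
    path = tmp_path_factory.mktemp("ref") / "mini_ref.fasta"
    reference_fasta(path)
    return path


@pytest.fixture(scope="session")
def noise_free_experiment():
    """2 strains x 2 runs x 2000 reads, no errors, no chimeras."""
    from longamp.simulate import simulate_experiment
    return simulate_experiment(strains=2, runs_per_strain=2, n_reads=2000,
                               error_rate=0.0, chimera_rate=0.0, master_seed=11)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
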