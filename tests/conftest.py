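import numpy as np
import pytest

from heliscan.helend import Hairpin, HelendCandidate
from heliscan.sequence import GenomeSequence, Interval
from heliscan.simulate import default_simspec, simulate


def make_candidate(
    end30: str,
    scaffold: str = "s",
    end3: int = 1000,
    strand: str = "+",
    cid: str | None = None,
) -> HelendCandidate:
    """Fabricate a minimal helend candidate for classification tests."""
    motif_iv = (
        Interval(scaffold, end3 - 3, end3, strand)
        if strand == "+"
        else Interval(scaffold, end3, end3 + 3, strand)
    )
    arm = Interval(scaffold, max(1, end3 - 40), max(1, end3 - 31), strand)
    hp = Hairpin(arm, arm, loop_len=3, stem_pairs=10, mismatches=0, spacer=6)
    return HelendCandidate(
        candidate_id=cid or f"{scaffold}:{end3}:{strand}",
        motif_interval=motif_iv,
        hairpin=hp,
        terminal_motif=end30[-4:],
        end30=end30,
        strand=strand,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-kb two-scaffold simulated genome with 30 planted elements."""
    spec = default_simspec(7)
    spec.genome_length = 300_000
    spec.n_scaffolds = 2
    return simulate(spec)


@pytest.fixture(scope="session")
def small_genome_map(small_sim):
    return {g.id: g for g in small_sim.genome}
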