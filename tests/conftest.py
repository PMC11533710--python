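import pytest

from blockgraph import MSA, running_example
from blockgraph.instance_builder import MWBCInstance, build_window_candidates


@pytest.fixture(scope="session")
def example():
    """The fixed 5x9 worked-example alignment."""
    return running_example()


def msa_from_rows(*rows: str) -> MSA:
    return MSA(tuple(f"r{i}" for i in range(1, len(rows) + 1)), tuple(rows))


def single_window_instance(msa: MSA, strategy: str = "complete") -> MWBCInstance:
    """Full-pipeline candidate set as one instance spanning the whole MSA."""
    cands = build_window_candidates(msa, strategy)
    return MWBCInstance(msa, offset=0, candidates=tuple(cands))
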