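import pytest

from plastdiverge.io import MultipleAlignment
from plastdiverge.synthetic import (AncestralSpec, EvolutionModel,
                                    simulate_dataset)

SMALL_SPEC = dict(lsc_len=5000, ssc_len=2200, ir_len=1600, n_genes=6,
                  ssr_seed_loci=[("A", 12, "LSC"), ("T", 11, "LSC"),
                                 ("AT", 6, "SSC"), ("A", 10, "IR")])


def make_aln(rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(list(rows), list(rows.values()))


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down study-condition simulation shared across tests."""
    spec = AncestralSpec(**SMALL_SPEC)
    return simulate_dataset(spec=spec, seed=11)


@pytest.fixture(scope="session")
def small_sim_subs_only():
    spec = AncestralSpec(**SMALL_SPEC)
    model = EvolutionModel(indel_rate=0.0, ssr_slippage_rate=0.0)
    return simulate_dataset(spec=spec, model=model, seed=11)
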