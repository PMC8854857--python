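import numpy as np
import pytest
from hypothesis import settings

from plastidcomp.simulate import (
    GeneModel,
    PlantedSSR,
    PlastomeSpec,
    default_gene_models,
    generate_plastome,
)

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


def small_spec(seed: int = 0, lsc: int = 9000, ir: int = 2500, ssc: int = 900) -> PlastomeSpec:
    return PlastomeSpec(
        lsc_len=lsc,
        ir_len=ir,
        ssc_len=ssc,
        genes=default_gene_models(lsc, ssc, ir),
        ssrs=(
            PlantedSSR("A", 10, "LSC", lsc - 400),
            PlantedSSR("AT", 6, "SSC", ssc // 2),
            PlantedSSR("AAG", 5, "IRb", ir // 2),
            PlantedSSR("AATT", 4, "LSC", lsc - 900),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle():
    """One synthetic plastome with annotations and planted SSRs."""
    spec = small_spec(seed=42)
    genome, table, planted = generate_plastome(spec)
    return spec, genome, table, planted


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.4) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("AGCT"), size=n, p=p))
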