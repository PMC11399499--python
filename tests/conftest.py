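import numpy as np
import pandas as pd
import pytest

from inferreg import synthetic
from inferreg.io_formats import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(
        n_tfs=8, n_genes=80, n_tissues=3, samples_per_tissue=10, seed=7
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """A complete small synthetic world: truth, expression, genome, peaks."""
    truth = synthetic.generate_grn(small_config)
    expr = synthetic.simulate_expression(truth, small_config)
    genome, motifs, annotations = synthetic.emit_genome_and_motifs(
        truth, small_config
    )
    peaks = synthetic.emit_chip_peaks(truth, small_config)
    return {
        "config": small_config,
        "truth": truth,
        "expr": expr,
        "genome": genome,
        "motifs": motifs,
        "annotations": annotations,
        "peaks": peaks,
    }


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(3)
    values = rng.poisson(50.0, size=(6, 8)).astype(float)
    samples = [f"s{i}" for i in range(8)]
    tissues = {s: ("A" if i < 4 else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], samples, values, tissues
    )


@pytest.fixture
def edge_frame():
    def make(pairs, **cols):
        df = pd.DataFrame(pairs, columns=["tf", "target"])
        for k, v in cols.items():
            df[k] = v
        return df

    return make
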