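import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plastisel import (
    ExpressionSimConfig,
    GenotypeMatrix,
    GenotypeSimConfig,
    sim_expression,
    sim_snp_genotypes,
)
from plastisel.containers import MISSING


def genotype_matrix_from_dosages(dosages, clusters=None, populations=None, qual=None, gq=None):
    """Small-fixture helper: dosage rows = individuals, columns = loci."""
    dos = np.asarray(dosages, dtype=np.int16)
    n, L = dos.shape
    calls = np.empty((n, L, 2), dtype=np.int16)
    calls[:, :, 0] = (dos == 2).astype(np.int16)
    calls[:, :, 1] = (dos >= 1).astype(np.int16)
    calls[dos == MISSING] = MISSING
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n)],
        loci=[f"L{j}" for j in range(L)],
        calls=calls,
        clusters=np.asarray(clusters, dtype=object) if clusters is not None else np.asarray(["c0"] * L, dtype=object),
        alleles=[("A", "G")] * L,
        qual=None if qual is None else np.asarray(qual, dtype=float),
        gq=None if gq is None else np.asarray(gq, dtype=float),
        populations=None if populations is None else np.asarray(populations, dtype=object),
    )


@pytest.fixture(scope="session")
def two_pop_snps():
    """Moderately diverged two-population SNP panel with truth."""
    cfg = GenotypeSimConfig(n_loci=1200, theta_background=0.02, theta_selected=0.45, n_selected=40, seed=101)
    return sim_snp_genotypes(cfg)


@pytest.fixture(scope="session")
def null_expression():
    """Expression data with no planted effects."""
    return sim_expression(ExpressionSimConfig(n_genes=800, seed=202))
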