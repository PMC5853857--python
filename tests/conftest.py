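"""Shared fixtures: small synthetic panels, kinships and phenotypes."""

import numpy as np
import pandas as pd
import pytest

from wheatmt.containers import GenotypeMatrix, KinshipMatrix
from wheatmt.genostats import kinship_from_genotypes
from wheatmt.synthetic_data import SimPopulationSpec, simulate_genotypes


def make_geno(dosages, chrom=None, pos=None):
    """GenotypeMatrix from a raw dosage array with an auto-generated map."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        marker_ids=[f"m{j}" for j in range(m)],
        chromosome=np.array(["1"] * m) if chrom is None else np.asarray(chrom),
        position_cM=np.arange(m, dtype=float) if pos is None else np.asarray(pos),
        genotype_ids=[f"g{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def small_panel():
    """150 genotypes x 3 chromosomes x 80 markers with LD structure."""
    spec = SimPopulationSpec(
        n_genotypes=150,
        n_markers_per_chrom=80,
        n_chromosomes=3,
        ld_decay_cM=3.0,
        seed=11,
    )
    return simulate_genotypes(spec)


@pytest.fixture(scope="session")
def small_kinship(small_panel):
    return kinship_from_genotypes(small_panel)


@pytest.fixture(scope="session")
def structured_A():
    """A PSD relationship matrix with diagonal 2 for 200 genotypes."""
    rng = np.random.default_rng(5)
    B = rng.normal(size=(200, 30))
    A = B @ B.T / 30 + 0.3 * np.eye(200)
    A *= 2.0 / np.mean(np.diag(A))
    ids = [f"g{i}" for i in range(200)]
    RD = 1.0 - A / 2.0
    return KinshipMatrix(A=A, RD=RD, genotype_ids=ids)


def bivariate_blues(A_kin, G0, R0, rng, markers=None, alphas=None):
    """Draw one bivariate BLUE table y = alpha*m + g + e with g ~ N(0, G0 x A)."""
    n = A_kin.n
    lam, U = A_kin.eig()
    L_A = U * np.sqrt(lam)[None, :]
    g = L_A @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(
        G0 + 1e-10 * np.eye(2)
    ).T
    e = rng.standard_normal((n, 2)) @ np.linalg.cholesky(R0).T
    y = g + e
    if markers is not None:
        for k in range(2):
            y[:, k] += alphas[k] * markers[k]
    return pd.DataFrame(
        y,
        index=pd.Index(A_kin.genotype_ids, name="genotype"),
        columns=["T1", "T2"],
    )


def blues_to_long(blues):
    return blues.reset_index().melt(
        id_vars="genotype", var_name="trait", value_name="value"
    )
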