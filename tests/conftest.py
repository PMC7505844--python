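import numpy as np
import pytest

from synovitcr import synthetic_data, vdj_io

_NT = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
       "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
       "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
       "W": "TGG", "Y": "TAT"}


def nt_of(aa: str) -> str:
    """Deterministic back-translation for fixture chains."""
    return "".join(_NT[x] for x in aa)


def make_chain(barcode, locus, cdr3_aa, *, patient="P01", sample="P01_SFMC",
               v_gene=None, j_gene=None, umis=5):
    if v_gene is None:
        v_gene = "TRAV1-2" if locus == "TRA" else "TRBV28"
    if j_gene is None:
        j_gene = "TRAJ33" if locus == "TRA" else "TRBJ1-1"
    return vdj_io.ContigRecord(barcode, sample, patient, locus, v_gene, "",
                               j_gene, nt_of(cdr3_aa), cdr3_aa, True, umis)


def make_partition(barcode, alpha_aas, beta_aas, *, patient="P01",
                   sample="P01_SFMC"):
    chains = [make_chain(barcode, "TRA", aa, patient=patient, sample=sample)
              for aa in alpha_aas]
    chains += [make_chain(barcode, "TRB", aa, patient=patient, sample=sample)
               for aa in beta_aas]
    (part,) = vdj_io.build_cell_partitions(chains)
    return part


@pytest.fixture
def chain_factory():
    return make_chain


@pytest.fixture
def partition_factory():
    return make_partition


@pytest.fixture(scope="session")
def small_repertoire():
    """One shared small simulated cohort for I/O and conservation tests."""
    cfg = synthetic_data.RepertoireConfig(
        n_patients=2,
        cells_per_sample={"PBMC": 200, "SFMC": 200},
        n_clones=30,
        n_planted_enriched=2,
        planted_groups=synthetic_data.DEFAULT_PLANTED_GROUPS[:2],
        nonproductive_rate=0.05,
        seed=20200921,
    )
    return cfg, synthetic_data.simulate_repertoire(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20200921)
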