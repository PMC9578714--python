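import pytest

from trnacharge.demux import BarcodeTable, SampleRow
from trnacharge.pipeline import design_frame, run_stages, simulate_scenario, PipelineConfig
from trnacharge.reference import build_reference, parse_gene_fasta

TINY_GENES = """\
>tRNA-His-GTG-1-1
GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACCTCGGTTCGAATCCGAGTCACGGCA
>tRNA-His-GTG-1-2
GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACCTCGGTTCGAATCCGAGTCACGGCA
>tRNA-His-GTG-2-1
GCCGTGATCGTATAGTGGTTAGTACTCTGCGTTGTGGCCGCAGCAACCTCGGTTCGAATCCGAGTCACGGCG
>tRNA-Leu-CAA-1-1
GTCAGGATGGCCGAGTGGTCTAAGGCGCCAGACTCAAGTTCTGGTCTCCGTATGGAGGCGTGGGTTCGAATCCCAC
>tRNA-Ala-AGC-1-1
GGGGGTGTAGCTCAGTGGTAGAGCGCGTGCTTAGCATGCACGAGGTCCTGGGTTCGATCCCCAGCACCTCCA
"""


@pytest.fixture(scope="session")
def tiny_genes_fasta():
    return TINY_GENES


@pytest.fixture(scope="session")
def tiny_reference(tiny_genes_fasta):
    return build_reference(parse_gene_fasta(tiny_genes_fasta))


@pytest.fixture
def barcode_table():
    return BarcodeTable(
        [
            SampleRow("s1", "ACGTA", "ctrl", 1),
            SampleRow("s2", "TTGCA", "ctrl", 2),
            SampleRow("s3", "GGATC", "treat", 1),
            SampleRow("s4", "CATGG", "treat", 2),
        ]
    )


@pytest.fixture(scope="session")
def default_run():
    """One full default-scenario run (3 conditions x 4 replicates, 5,000
    pairs/sample, seed 42): simulation, truth, and all pipeline stages."""
    cfg = PipelineConfig(seed=42, simulate={})
    scenario, library = simulate_scenario(cfg)
    result = run_stages(
        scenario.genes_fasta,
        library.pairs,
        scenario.barcode_table,
        design_frame(scenario.barcode_table),
        contrasts=[("GCN2iB", "vehicle"), ("GCN2iB_EAA", "GCN2iB")],
    )
    return scenario, library, result
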